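import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from sdrscan.io_formats import Genotype, SexLabel, SexTable


@pytest.fixture
def sex_table_4() -> SexTable:
    """Two females, two males."""
    return SexTable(
        {
            "F1": SexLabel.FEMALE,
            "F2": SexLabel.FEMALE,
            "M1": SexLabel.MALE,
            "M2": SexLabel.MALE,
        }
    )


@pytest.fixture
def cohort_200() -> SexTable:
    """The balanced 100+100 study design."""
    sexes = {f"F{i:03d}": SexLabel.FEMALE for i in range(1, 101)}
    sexes.update({f"M{i:03d}": SexLabel.MALE for i in range(1, 101)})
    return SexTable(sexes)


def genotypes_from_counts(sex_table, female_codes, male_codes):
    """Build a genotype dict assigning listed codes to cohort samples."""
    females = sex_table.of_sex(SexLabel.FEMALE)
    males = sex_table.of_sex(SexLabel.MALE)
    assert len(female_codes) == len(females) and len(male_codes) == len(males)
    out = {}
    out.update(dict(zip(females, female_codes)))
    out.update(dict(zip(males, male_codes)))
    return out


@pytest.fixture
def uniform_xy_genotypes(cohort_200):
    """All 100 females hom_ref, all 100 males het: a fully sex-linked SNP."""
    return genotypes_from_counts(
        cohort_200, [Genotype.HOM_REF] * 100, [Genotype.HET] * 100
    )
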