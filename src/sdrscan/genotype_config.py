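"""Genotype-configuration analysis of sex-associated markers.

A fully sex-linked marker in an XY (male-heterogametic) system shows females
homozygous for the X allele and males uniformly heterozygous (X/Y); a marker
inside the male-limited (hemizygous) core shows a preponderance of female
null alleles because the underlying sequence is absent from female genomes.
The ZW mirror swaps the sexes.  Majority vote over marker classes infers the
heterogamety system, and the span of non-unlinked markers estimates the SDR.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import GenomicInterval, Genotype, SexLabel, SexTable


class UndefinedMarkerError(ValueError):
    """All genotypes missing in both sexes."""


@dataclass
class MarkerConfig:
    chrom: str
    pos: int
    counts: dict[str, dict[str, int]]  # sex -> genotype code -> count
    config_class: str  # xy_linked | zw_linked | female_null | male_null | unlinked
    conformity: float


@dataclass
class SystemCall:
    system: str  # XY | ZW | ambiguous
    class_counts: dict[str, int]
    sdr_span: GenomicInterval | None


def _sex_counts(genotypes: dict[str, Genotype], sex_table: SexTable, sex: SexLabel):
    counts = Counter(
        genotypes[s].value for s in sex_table.of_sex(sex) if s in genotypes
    )
    total = sum(counts.values())
    missing = counts.get("missing", 0)
    called = total - missing
    return counts, total, called


def classify_marker(
    genotypes: dict[str, Genotype],
    sex_table: SexTable,
    conformity_min: float = 0.9,
    null_min: float = 0.5,
) -> MarkerConfig:
    """Assign one marker its configuration class.

    Null classes (missing-genotype excess in exactly one sex) take precedence
    over linked classes: a hemizygous marker's few spurious calls must not be
    read as a linkage pattern.  ``xy_linked`` requires >= ``conformity_min``
    of called females homozygous for one allele AND the same fraction of
    called males heterozygous; ``zw_linked`` is the mirror.  Conformity is
    the mean of the two sexes' conforming fractions.
    """
    fc, f_total, f_called = _sex_counts(genotypes, sex_table, SexLabel.FEMALE)
    mc, m_total, m_called = _sex_counts(genotypes, sex_table, SexLabel.MALE)
    if f_called == 0 and m_called == 0:
        raise UndefinedMarkerError("all genotypes missing")

    counts = {
        "female": {k.value: fc.get(k.value, 0) for k in Genotype},
        "male": {k.value: mc.get(k.value, 0) for k in Genotype},
    }
    f_missing_frac = fc.get("missing", 0) / f_total if f_total else 0.0
    m_missing_frac = mc.get("missing", 0) / m_total if m_total else 0.0

    def result(cls: str, conf: float) -> MarkerConfig:
        return MarkerConfig("", 0, counts, cls, round(conf, 6))

    # null classes first
    if f_missing_frac >= null_min and m_missing_frac < null_min:
        return result("female_null", f_missing_frac)
    if m_missing_frac >= null_min and f_missing_frac < null_min:
        return result("male_null", m_missing_frac)

    def hom_frac(c: Counter, called: int) -> float:
        if called == 0:
            return 0.0
        return max(c.get("hom_ref", 0), c.get("hom_alt", 0)) / called

    def het_frac(c: Counter, called: int) -> float:
        return c.get("het", 0) / called if called else 0.0

    f_hom, f_het = hom_frac(fc, f_called), het_frac(fc, f_called)
    m_hom, m_het = hom_frac(mc, m_called), het_frac(mc, m_called)
    if f_hom >= conformity_min and m_het >= conformity_min:
        return result("xy_linked", (f_hom + m_het) / 2)
    if m_hom >= conformity_min and f_het >= conformity_min:
        return result("zw_linked", (m_hom + f_het) / 2)
    return result("unlinked", 0.0)


def classify_markers(
    records,
    sex_table: SexTable,
    conformity_min: float = 0.9,
    null_min: float = 0.5,
) -> list[MarkerConfig]:
    out = []
    for rec in records:
        try:
            cfg = classify_marker(rec.genotypes, sex_table, conformity_min, null_min)
        except UndefinedMarkerError:
            continue
        cfg.chrom, cfg.pos = rec.chrom, rec.pos
        out.append(cfg)
    return out


def infer_system(marker_configs: list[MarkerConfig]) -> SystemCall:
    """Majority vote of non-unlinked marker classes.

    XY requires xy_linked + female_null to strictly outnumber
    zw_linked + male_null (ZW mirrored); equality is ambiguous.  The SDR span
    estimate is the minimal interval covering all non-unlinked markers on the
    contig carrying the most of them.
    """
    if not marker_configs:
        raise ValueError("no classified markers")
    class_counts = Counter(m.config_class for m in marker_configs)
    xy_votes = class_counts["xy_linked"] + class_counts["female_null"]
    zw_votes = class_counts["zw_linked"] + class_counts["male_null"]
    if xy_votes > zw_votes:
        system = "XY"
    elif zw_votes > xy_votes:
        system = "ZW"
    else:
        system = "ambiguous"

    linked = [m for m in marker_configs if m.config_class != "unlinked"]
    span = None
    if linked:
        modal_chrom = Counter(m.chrom for m in linked).most_common(1)[0][0]
        on_modal = [m for m in linked if m.chrom == modal_chrom]
        span = GenomicInterval(
            modal_chrom,
            min(m.pos for m in on_modal) - 1,
            max(m.pos for m in on_modal),
        )
    return SystemCall(system=system, class_counts=dict(class_counts), sdr_span=span)
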