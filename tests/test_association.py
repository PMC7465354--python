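import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sdrscan.association import (
    AssociationResult,
    FilterRuleSet,
    UndefinedTestError,
    allele_table,
    associate,
    bonferroni_threshold,
    cluster_significant,
    fisher_sex_test,
    hard_filter,
)
from sdrscan.io_formats import Genotype, SexLabel, SexTable, VariantRecord

from conftest import genotypes_from_counts
from oracles import fisher_two_sided

PASSING_INFO = {"AF": 0.3, "QD": 20.0, "ExcessHet": 1.0, "FS": 1.0, "MQ": 59.0}


def record(info, genotypes=None):
    return VariantRecord(
        chrom="tig", pos=100, ref="A", alt="G",
        info_metrics=info,
        genotypes=genotypes or {},
    )


class TestHardFilter:
    def test_single_violation_reports_its_rule(self):
        ok, reasons = hard_filter(record({**PASSING_INFO, "QD": 9.0}))
        assert not ok and reasons == ["QD"]

    def test_boundaries_are_not_violations(self):
        info = {"AF": 0.01, "QD": 10.0, "ExcessHet": 20.0, "FS": 10.0, "MQ": 58.0}
        ok, reasons = hard_filter(record(info))
        assert ok and reasons == []

    def test_missing_metric_fails_conservatively(self):
        info = dict(PASSING_INFO)
        del info["MQ"]
        ok, reasons = hard_filter(record(info))
        assert not ok and reasons == ["metric_absent:MQ"]

    def test_survivor_count_on_toy_set(self):
        records = [record(dict(PASSING_INFO)) for _ in range(4)]
        records.append(record({**PASSING_INFO, "AF": 0.005}))
        records.append(record({**PASSING_INFO, "FS": 30.0}))
        survivors = [r for r in records if hard_filter(r)[0]]
        assert len(survivors) == 4


class TestFisher:
    def test_small_table_matches_hand_enumeration(self, sex_table_4):
        # females hom_alt, males hom_ref -> allele table [[0,4],[4,0]]; with
        # one sample per cell-pair of 2 alleles the canonical [[2,0],[0,2]]
        # arises from 1 female + 1 male cohorts
        table = SexTable({"F1": SexLabel.FEMALE, "M1": SexLabel.MALE})
        gts = {"F1": Genotype.HOM_REF, "M1": Genotype.HOM_ALT}
        res = fisher_sex_test(gts, table)
        assert res.table == ((2, 0), (0, 2))
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_allele_counts_give_p_one(self, sex_table_4):
        gts = genotypes_from_counts(
            sex_table_4,
            [Genotype.HET, Genotype.HOM_REF],
            [Genotype.HET, Genotype.HOM_REF],
        )
        assert fisher_sex_test(gts, sex_table_4).p_value == pytest.approx(1.0)

    def test_fully_sex_linked_snp_clears_genomewide_cutoff(
        self, cohort_200, uniform_xy_genotypes
    ):
        res = fisher_sex_test(uniform_xy_genotypes, cohort_200)
        assert res.table == ((200, 0), (100, 100))
        assert res.p_value < 1.09e-8
        assert res.p_value == pytest.approx(
            fisher_two_sided(200, 0, 100, 100), abs=1e-12
        )

    def test_missing_genotypes_contribute_nothing(self, sex_table_4):
        gts = genotypes_from_counts(
            sex_table_4,
            [Genotype.HOM_REF, Genotype.MISSING],
            [Genotype.HET, Genotype.MISSING],
        )
        assert allele_table(gts, sex_table_4) == ((2, 0), (1, 1))

    def test_sex_with_no_calls_is_undefined(self, sex_table_4):
        gts = genotypes_from_counts(
            sex_table_4,
            [Genotype.MISSING, Genotype.MISSING],
            [Genotype.HET, Genotype.HET],
        )
        with pytest.raises(UndefinedTestError):
            fisher_sex_test(gts, sex_table_4)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_enumeration_oracle(self, a, b, c, d):
        """Spot agreement with the exact rational enumeration (the full
        total<=30 sweep runs in the acceptance suite)."""
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided(a, b, c, d), abs=1e-12)

    @given(
        n_f_hom=st.integers(0, 8), n_f_het=st.integers(0, 8),
        n_m_hom=st.integers(0, 8), n_m_het=st.integers(0, 8),
    )
    def test_invariant_under_joint_sex_and_allele_swap(
        self, n_f_hom, n_f_het, n_m_hom, n_m_het
    ):
        if n_f_hom + n_f_het == 0 or n_m_hom + n_m_het == 0:
            return
        sexes = {f"F{i}": SexLabel.FEMALE for i in range(n_f_hom + n_f_het)}
        sexes.update({f"M{i}": SexLabel.MALE for i in range(n_m_hom + n_m_het)})
        table = SexTable(sexes)
        gts = genotypes_from_counts(
            table,
            [Genotype.HOM_REF] * n_f_hom + [Genotype.HET] * n_f_het,
            [Genotype.HOM_REF] * n_m_hom + [Genotype.HET] * n_m_het,
        )
        flipped_sexes = {
            s: (SexLabel.MALE if lab is SexLabel.FEMALE else SexLabel.FEMALE)
            for s, lab in table.sexes.items()
        }
        swap = {Genotype.HOM_REF: Genotype.HOM_ALT, Genotype.HOM_ALT: Genotype.HOM_REF}
        flipped_gts = {s: swap.get(g, g) for s, g in gts.items()}
        p1 = fisher_sex_test(gts, table).p_value
        p2 = fisher_sex_test(flipped_gts, SexTable(flipped_sexes)).p_value
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected",
        [(4_586_112, 1.09e-8), (3_017_607, 1.66e-8), (5, 0.01)],
        ids=["main-genome", "alt-haplotypes", "tiny"],
    )
    def test_threshold(self, n, expected):
        got = bonferroni_threshold(n, 0.05)
        assert float(f"{got:.3g}") == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestClustering:
    @staticmethod
    def results(positions, chrom="tig"):
        return [
            AssociationResult(chrom, p, ((1, 1), (1, 1)), 1e-12, significant=True)
            for p in positions
        ]

    def test_no_significant_snps(self):
        assert cluster_significant([]) == []

    def test_dense_cluster_merges_into_one_interval(self):
        positions = list(range(10_000, 10_000 + 119 * 2500, 2500))  # 119 SNPs, <300 kb
        clusters = cluster_significant(self.results(positions), max_gap_bp=50_000)
        assert len(clusters) == 1
        assert clusters[0].n_snps == 119

    def test_distant_clusters_stay_separate(self):
        positions = [1000, 2000, 3000, 1_003_000, 1_004_000]
        clusters = cluster_significant(self.results(positions), max_gap_bp=50_000)
        assert [c.n_snps for c in clusters] == [3, 2]


def test_null_simulation_yields_no_significant_snps(cohort_200):
    """10,000 sex-independent Hardy-Weinberg SNPs: Bonferroni keeps the
    familywise false-positive count at zero (expectation <= alpha)."""
    rng = np.random.default_rng(42)
    samples = cohort_200.samples
    results = []
    code = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT]
    for i in range(10_000):
        maf = rng.uniform(0.05, 0.5)
        alt = rng.binomial(2, maf, size=200)
        gts = {s: code[k] for s, k in zip(samples, alt)}
        results.append(fisher_sex_test(gts, cohort_200, "tig", i + 1))
    cutoff = bonferroni_threshold(len(results), 0.05)
    assert sum(r.p_value < cutoff for r in results) == 0


def test_associate_stage_counts(sex_table_4):
    recs = [
        record(dict(PASSING_INFO), genotypes_from_counts(
            sex_table_4, [Genotype.HOM_REF] * 2, [Genotype.HET] * 2)),
        record({**PASSING_INFO, "QD": 1.0}, genotypes_from_counts(
            sex_table_4, [Genotype.HOM_REF] * 2, [Genotype.HET] * 2)),
        # MAF 0 -> excluded by the strict floor
        record(dict(PASSING_INFO), genotypes_from_counts(
            sex_table_4, [Genotype.HOM_REF] * 2, [Genotype.HOM_REF] * 2)),
    ]
    results, clusters, stats = associate(recs, sex_table_4)
    assert stats == {
        "n_input": 3, "n_filtered": 1, "n_low_maf": 1, "n_untestable": 0,
        "n_tested": 1, "n_significant": 0,
    }
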