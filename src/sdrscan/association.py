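"""Sex-association scan: hard filtering, Fisher's exact test per SNP with
Bonferroni familywise control, and clustering of significant markers into
candidate sex-determination-region (SDR) intervals.

The allelic test follows the plink ``--assoc --fisher`` convention: each
non-missing diploid genotype contributes two allele observations to a
2x2 (sex x allele) table; the two-sided p-value sums hypergeometric
probabilities of all tables at fixed margins whose probability does not
exceed the observed table's (minimum-likelihood rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .io_formats import GenomicInterval, Genotype, SexLabel, SexTable, VariantRecord


class UndefinedTestError(ValueError):
    """Raised when one sex has no non-missing genotype at a site."""


@dataclass(frozen=True)
class FilterRuleSet:
    """GATK-style hard-filter thresholds plus the association-stage knobs.

    A record *fails* iff any disjunct holds, with strict inequalities:
    AF < af_lower, AF > af_upper, QD < qd_min, ExcessHet > excess_het_max,
    FS > fs_max, MQ < mq_min.
    """

    af_lower: float = 0.01
    af_upper: float = 0.99
    qd_min: float = 10.0
    excess_het_max: float = 20.0
    fs_max: float = 10.0
    mq_min: float = 58.0
    maf_floor: float = 0.05  # strict: MAF must exceed this
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.af_lower <= self.af_upper <= 1):
            raise ValueError("AF bounds must satisfy 0 <= lower <= upper <= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class AssociationResult:
    chrom: str
    pos: int
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: (F, M); cols: (ref, alt)
    p_value: float
    significant: bool = False
    threshold: float | None = None
    cluster_id: int | None = None


def hard_filter(
    record: VariantRecord, rules: FilterRuleSet = FilterRuleSet()
) -> tuple[bool, list[str]]:
    """(passes, reasons).  A missing INFO metric fails the rule that needs it
    with reason ``metric_absent:<name>`` (conservative, mirrors flagging
    behaviour of upstream variant filtration)."""
    info = record.info_metrics
    reasons: list[str] = []
    checks = [
        ("AF", lambda v: v < rules.af_lower or v > rules.af_upper, "AF"),
        ("QD", lambda v: v < rules.qd_min, "QD"),
        ("ExcessHet", lambda v: v > rules.excess_het_max, "ExcessHet"),
        ("FS", lambda v: v > rules.fs_max, "FS"),
        ("MQ", lambda v: v < rules.mq_min, "MQ"),
    ]
    for key, violates, name in checks:
        if key not in info:
            reasons.append(f"metric_absent:{name}")
        elif violates(info[key]):
            reasons.append(name)
    return (not reasons, reasons)


_ALT_COPIES = {Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2}


def allele_table(
    genotypes: dict[str, Genotype], sex_table: SexTable
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 allele-count table, rows (female, male), columns (ref, alt).
    Missing genotypes contribute nothing."""
    counts = {SexLabel.FEMALE: [0, 0], SexLabel.MALE: [0, 0]}
    for sample, gt in genotypes.items():
        if gt is Genotype.MISSING:
            continue
        sex = sex_table.sexes[sample]
        k = _ALT_COPIES[gt]
        counts[sex][0] += 2 - k
        counts[sex][1] += k
    return (tuple(counts[SexLabel.FEMALE]), tuple(counts[SexLabel.MALE]))


def minor_allele_frequency(genotypes: dict[str, Genotype], sex_table: SexTable) -> float:
    """MAF across all non-missing samples, both sexes pooled."""
    (fr, fa), (mr, ma) = allele_table(genotypes, sex_table)
    ref, alt = fr + mr, fa + ma
    total = ref + alt
    if total == 0:
        raise UndefinedTestError("no non-missing genotypes")
    return min(ref, alt) / total


def fisher_sex_test(
    genotypes: dict[str, Genotype],
    sex_table: SexTable,
    chrom: str = "",
    pos: int = 0,
) -> AssociationResult:
    """Two-sided Fisher's exact test of allele counts against sex."""
    table = allele_table(genotypes, sex_table)
    (fr, fa), (mr, ma) = table
    if fr + fa == 0 or mr + ma == 0:
        raise UndefinedTestError(
            f"{chrom}:{pos}: a sex has zero non-missing genotypes"
        )
    _, p = fisher_exact([[fr, fa], [mr, ma]], alternative="two-sided")
    return AssociationResult(chrom=chrom, pos=pos, table=table, p_value=float(min(p, 1.0)))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Familywise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class SdrCandidate:
    interval: GenomicInterval
    n_snps: int
    min_p: float
    cluster_id: int


def cluster_significant(
    results: list[AssociationResult], max_gap_bp: int = 50_000
) -> list[SdrCandidate]:
    """Merge significant SNPs on the same contig when consecutive gaps are at
    most ``max_gap_bp``; input must be sorted by (chrom, pos)."""
    sig = [r for r in results if r.significant]
    clusters: list[SdrCandidate] = []
    current: list[AssociationResult] = []

    def flush():
        if not current:
            return
        cid = len(clusters) + 1
        iv = GenomicInterval(
            current[0].chrom, current[0].pos - 1, current[-1].pos
        )
        clusters.append(
            SdrCandidate(
                interval=iv,
                n_snps=len(current),
                min_p=min(r.p_value for r in current),
                cluster_id=cid,
            )
        )
        for r in current:
            r.cluster_id = cid

    for r in sig:
        if current and (
            r.chrom != current[-1].chrom or r.pos - current[-1].pos > max_gap_bp
        ):
            flush()
            current = []
        current.append(r)
    flush()
    return clusters


def associate(
    records,
    sex_table: SexTable,
    rules: FilterRuleSet = FilterRuleSet(),
    max_gap_bp: int = 50_000,
):
    """Full association stage over a variant stream.

    Hard-filters records, applies the strict MAF floor, tests the survivors,
    Bonferroni-corrects over the number of tests actually performed, and
    clusters significant SNPs.  Returns ``(results, clusters, stage_stats)``.
    Sites where one sex has no callable genotype are tallied, not tested.
    """
    results: list[AssociationResult] = []
    stats = {"n_input": 0, "n_filtered": 0, "n_low_maf": 0, "n_untestable": 0}
    for rec in records:
        stats["n_input"] += 1
        ok, _ = hard_filter(rec, rules)
        if not ok:
            stats["n_filtered"] += 1
            continue
        try:
            if minor_allele_frequency(rec.genotypes, sex_table) <= rules.maf_floor:
                stats["n_low_maf"] += 1
                continue
            res = fisher_sex_test(rec.genotypes, sex_table, rec.chrom, rec.pos)
        except UndefinedTestError:
            stats["n_untestable"] += 1
            continue
        results.append(res)
    n_tests = len(results)
    if n_tests:
        cutoff = bonferroni_threshold(n_tests, rules.alpha)
        for r in results:
            r.threshold = cutoff
            r.significant = r.p_value < cutoff
    results.sort(key=lambda r: (r.chrom, r.pos))
    clusters = cluster_significant(results, max_gap_bp)
    stats["n_tested"] = n_tests
    stats["n_significant"] = sum(r.significant for r in results)
    return results, clusters, stats
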