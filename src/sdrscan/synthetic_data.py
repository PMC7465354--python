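"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a dioecious-plant resequencing study design: two
balanced sex cohorts (100 females + 100 males at ~11x per sample), one contig
carrying a ~115 kb sex-determination region (SDR) in XY configuration with a
~45 kb male-specific (hemizygous) core, a background of autosomal SNPs in
Hardy-Weinberg proportions, diverged 5'/3' LTR terminal-repeat pairs, a
tandem telomeric array and a multi-arm inverted-repeat cluster.

Everything is a pure function of (config, seed): the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    GenomicInterval,
    Genotype,
    SexLabel,
    SexTable,
    write_fasta,
    write_sex_table,
)

BASES = np.array(["A", "C", "G", "T"])
TELOMERE_MOTIF = "TTTAGGG"

_CODES = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]


@dataclass
class RepeatConfig:
    """Layout of the repeat-bearing contig.

    Defaults mimic the published SDR geometry: five inverted-repeat arms of
    1.6-3.8 kb with 2-2.7 kb spacers at ~93.3% arm-to-arm identity, and a
    ~7.8 kb telomeric (TTTAGGG)n array at the contig end.
    """

    arm_lengths: tuple[int, ...] = (1624, 3819, 3836, 2761, 1428)
    arm_forward: tuple[bool, ...] = (True, True, False, True, False)
    spacer_lengths: tuple[int, ...] = (30, 2190, 2660, 30)
    arm_divergence: float = 0.067  # expected pairwise difference between arms
    telomere_copies: int = 1114
    left_pad: int = 2000
    right_pad: int = 2000


@dataclass
class SimConfig:
    """Study-design parameters of the simulated population."""

    n_females: int = 100
    n_males: int = 100
    n_autosomal_snps: int = 5000
    n_lowqual_snps: int = 20
    sdr_span: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chrSDR", 40_000, 155_000)
    )
    male_specific_span: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chrSDR", 60_000, 105_000)
    )
    sdr_contig_length: int = 200_000
    autosome_name: str = "chrA"
    autosome_length: int = 5_000_000
    mean_depth: float = 11.0  # reads per sample
    depth_dispersion: float = 10.0  # negative-binomial size; Poisson as limit
    core_noise_fraction: float = 0.02  # female coverage over male-only sequence
    genotype_error: float = 0.02
    linked_marker_spacing: int = 400
    maf_beta: tuple[float, float] = (1.0, 3.0)  # MAF ~ 0.5*Beta(a,b)
    system: str = "XY"  # or "ZW" mirror mode
    seed: int = 0
    repeats: RepeatConfig = field(default_factory=RepeatConfig)

    def __post_init__(self) -> None:
        if not self.sdr_span.contains(self.male_specific_span):
            raise ValueError("male_specific_span must lie within sdr_span")
        if min(self.n_females, self.n_males, self.n_autosomal_snps) < 1:
            raise ValueError("cohort sizes and SNP count must be >= 1")
        if self.system not in ("XY", "ZW"):
            raise ValueError(f"unknown system {self.system!r}")


@dataclass
class GroundTruth:
    """Planted features, for recovery scoring."""

    system: str = "XY"
    sdr_interval: GenomicInterval | None = None
    core_interval: GenomicInterval | None = None
    marker_classes: dict[str, str] = field(default_factory=dict)  # "chrom:pos" -> class
    ltr_ages: dict[str, float] = field(default_factory=dict)
    telomere_intervals: list[GenomicInterval] = field(default_factory=list)
    arm_intervals: list[GenomicInterval] = field(default_factory=list)
    arm_identity_pct: float | None = None
    tree_newick: str | None = None

    def to_json(self, path: str | Path) -> None:
        def enc(iv: GenomicInterval | None):
            if iv is None:
                return None
            return {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "reverse": iv.reverse}

        payload = {
            "system": self.system,
            "sdr_interval": enc(self.sdr_interval),
            "core_interval": enc(self.core_interval),
            "marker_classes": self.marker_classes,
            "ltr_ages": self.ltr_ages,
            "telomere_intervals": [enc(iv) for iv in self.telomere_intervals],
            "arm_intervals": [enc(iv) for iv in self.arm_intervals],
            "arm_identity_pct": self.arm_identity_pct,
            "tree_newick": self.tree_newick,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())

        def dec(d):
            if d is None:
                return None
            return GenomicInterval(d["chrom"], d["start"], d["end"], d["reverse"])

        return cls(
            system=raw["system"],
            sdr_interval=dec(raw["sdr_interval"]),
            core_interval=dec(raw["core_interval"]),
            marker_classes=raw["marker_classes"],
            ltr_ages=raw["ltr_ages"],
            telomere_intervals=[dec(d) for d in raw["telomere_intervals"]],
            arm_intervals=[dec(d) for d in raw["arm_intervals"]],
            arm_identity_pct=raw["arm_identity_pct"],
            tree_newick=raw["tree_newick"],
        )


def _apply_errors(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric miscall: with prob ``rate`` replace a code by a uniformly
    random *other* code (of hom_ref/het/hom_alt/missing)."""
    if rate <= 0:
        return codes
    flip = rng.random(codes.shape) < rate
    # offset 1..3 from the true code, mod 4, is uniform over the other codes
    offset = rng.integers(1, 4, size=codes.shape)
    return np.where(flip, (codes + offset) % 4, codes)


def simulate_population(config: SimConfig):
    """Genotypes for a sexed cohort: (variant table, SexTable, GroundTruth).

    Variant table rows are dicts ready for :func:`write_vcf`.  Marker classes:

    * autosomal SNPs: Hardy-Weinberg at a sampled MAF, independent of sex;
    * fully sex-linked (X-degenerate) SNPs: homogametic sex homozygous
      reference, heterogametic sex uniformly heterozygous;
    * male-specific-core SNPs: homogametic sex missing (null allele),
      heterogametic sex het or hom for the hemizygous allele.

    In ZW mirror mode the sex roles swap exactly.
    """
    rng = np.random.default_rng(config.seed)
    nf, nm = config.n_females, config.n_males
    n = nf + nm
    samples = [f"F{i:03d}" for i in range(1, nf + 1)] + [
        f"M{i:03d}" for i in range(1, nm + 1)
    ]
    sex_table = SexTable(
        {s: (SexLabel.FEMALE if s.startswith("F") else SexLabel.MALE) for s in samples}
    )
    female_mask = np.array([s.startswith("F") for s in samples])
    # the heterogametic cohort carries the sex-limited haplotype
    hetero_mask = ~female_mask if config.system == "XY" else female_mask

    truth = GroundTruth(
        system=config.system,
        sdr_interval=config.sdr_span,
        core_interval=config.male_specific_span,
    )
    rows = []

    # --- autosomal background, HWE, sex-independent ---
    pos_auto = np.sort(
        rng.choice(
            np.arange(1, config.autosome_length + 1),
            size=config.n_autosomal_snps + config.n_lowqual_snps,
            replace=False,
        )
    )
    a, b = config.maf_beta
    for j, pos in enumerate(pos_auto):
        maf = 0.5 * rng.beta(a, b)
        alt_alleles = rng.binomial(2, maf, size=n)  # 0/1/2 alt copies
        codes = np.select([alt_alleles == 0, alt_alleles == 1], [0, 1], default=2)
        codes = _apply_errors(codes, config.genotype_error, rng)
        lowqual = j >= config.n_autosomal_snps
        rows.append(
            _variant_row(config.autosome_name, int(pos), codes, samples, rng,
                         lowqual=lowqual)
        )
        key = f"{config.autosome_name}:{int(pos)}"
        truth.marker_classes[key] = "lowqual" if lowqual else "unlinked"

    # --- SDR markers on a deterministic grid ---
    sdr, core = config.sdr_span, config.male_specific_span
    step = config.linked_marker_spacing
    linked_class = "xy_linked" if config.system == "XY" else "zw_linked"
    null_class = "female_null" if config.system == "XY" else "male_null"
    for start0 in range(sdr.start + step // 2, sdr.end, step):
        pos = start0 + 1  # 1-based
        in_core = core.start <= start0 < core.end
        codes = np.zeros(n, dtype=int)
        if in_core:
            # hemizygous sex-limited sequence: homogametic sex has no allele
            codes[:] = 3
            codes[hetero_mask] = rng.choice([1, 2], size=hetero_mask.sum())
            cls = null_class
        else:
            # X-degenerate: fully sex-linked heterozygosity
            codes[hetero_mask] = 1
            cls = linked_class
        codes = _apply_errors(codes, config.genotype_error, rng)
        rows.append(_variant_row(sdr.chrom, pos, codes, samples, rng))
        truth.marker_classes[f"{sdr.chrom}:{pos}"] = cls

    rows.sort(key=lambda r: (r["chrom"], r["pos"]))
    return rows, sex_table, truth


def _variant_row(chrom, pos, codes, samples, rng, lowqual: bool = False) -> dict:
    ref, alt = rng.choice(4, size=2, replace=False)
    called = codes != 3
    af = (
        (codes[called] == 1).sum() + 2 * (codes[called] == 2).sum()
    ) / max(2 * called.sum(), 1)
    info = {
        "AF": round(float(af), 4),
        "QD": round(float(rng.uniform(15, 30)), 2),
        "ExcessHet": round(float(rng.uniform(0, 3)), 3),
        "FS": round(float(rng.uniform(0, 3)), 3),
        "MQ": round(float(rng.uniform(58.5, 60.0)), 2),
    }
    if lowqual:  # breach exactly one hard-filter rule
        key = ["QD", "ExcessHet", "FS", "MQ"][int(rng.integers(0, 4))]
        info[key] = {"QD": 5.0, "ExcessHet": 25.0, "FS": 15.0, "MQ": 50.0}[key]
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": BASES[ref],
        "alt": BASES[alt],
        "info": info,
        "codes": codes,
        "samples": samples,
    }


_GT = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}


def write_vcf(rows: list[dict], path: str | Path, contigs: dict[str, int]) -> None:
    """Emit a minimal VCF v4.2 (text, deterministic byte layout)."""
    if not rows:
        raise ValueError("no variant rows to write")
    samples = rows[0]["samples"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrscan-simulate\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key, number, desc in [
            ("AF", "A", "Allele Frequency"),
            ("QD", "1", "Quality by Depth"),
            ("ExcessHet", "1", "Phred-scaled excess heterozygosity"),
            ("FS", "1", "Phred-scaled strand bias"),
            ("MQ", "1", "RMS Mapping Quality"),
        ]:
            fh.write(
                f'##INFO=<ID={key},Number={number},Type=Float,Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in rows:
            info = ";".join(f"{k}={v}" for k, v in r["info"].items())
            gts = "\t".join(_GT[int(c)] for c in r["codes"])
            fh.write(
                f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t100\t.\t"
                f"{info}\tGT\t{gts}\n"
            )


def simulate_depth(config: SimConfig):
    """Per-position pooled cohort depth along the SDR contig.

    Returns ``(positions, depth_f, depth_m, truth)`` with 1-based positions.
    Cohort depth is negative-binomial with mean ``n_samples * mean_depth``
    (overdispersion ``depth_dispersion``; Poisson recovered as the size ->
    infinity limit).  Over the male-specific core the homogametic cohort's
    mean drops to ``core_noise_fraction`` of the heterogametic cohort's.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.sdr_contig_length
    positions = np.arange(1, L + 1)
    mean_f = np.full(L, config.n_females * config.mean_depth)
    mean_m = np.full(L, config.n_males * config.mean_depth)
    core = config.male_specific_span
    core_slice = slice(core.start, core.end)
    if config.system == "XY":
        mean_f[core_slice] = config.core_noise_fraction * mean_m[core_slice]
    else:
        mean_m[core_slice] = config.core_noise_fraction * mean_f[core_slice]

    def draw(mean):
        size = config.depth_dispersion
        out = np.zeros(L, dtype=int)
        nz = mean > 0
        p = size / (size + mean[nz])
        out[nz] = rng.negative_binomial(size, p)
        return out

    truth = GroundTruth(
        system=config.system,
        sdr_interval=config.sdr_span,
        core_interval=core,
    )
    return positions, draw(mean_f), draw(mean_m), truth


def write_depth_table(positions, depths, chrom: str, path: str | Path) -> None:
    """samtools-depth dialect: contig, 1-based position, depth."""
    with open(path, "w") as fh:
        for pos, d in zip(positions, depths):
            fh.write(f"{chrom}\t{pos}\t{d}\n")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with prob ``rate`` to a uniformly random other base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    lut = {b"A": b"CGT", b"C": b"AGT", b"G": b"ACT", b"T": b"ACG"}
    for i in hit:
        k = int(rng.integers(0, 3))
        arr[i] = lut[bytes(arr[i])][k : k + 1]
    return arr.tobytes().decode()


def simulate_ltr_pair(
    length: int,
    age_years: float,
    mu: float = 2.5e-9,
    seed: int = 0,
    convention: str = "direct",
):
    """A diverged 5'/3' terminal-repeat pair of known insertion age.

    The two repeats start identical at insertion; substitutions accumulate so
    that the expected *observed* pairwise divergence matches the dating
    convention in force: ``d = mu * age`` under the ``"direct"`` convention
    (age = d/mu), ``d = 2 * mu * age`` under ``"standard"`` (each repeat
    mutates independently; age = d/(2 mu)).  No indels.
    """
    if length < 50:
        raise ValueError("length must be >= 50")
    if age_years < 0 or mu <= 0:
        raise ValueError("need age >= 0 and mu > 0")
    factor = {"direct": 1.0, "standard": 2.0}[convention]
    d_expected = factor * mu * age_years
    if d_expected >= 0.75:
        raise ValueError("requested age saturates the observable divergence")
    rng = np.random.default_rng(seed)
    seq5 = random_sequence(length, rng)
    seq3 = _mutate(seq5, d_expected, rng)
    return seq5, seq3, age_years


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_repeat_sequence(config: SimConfig):
    """A contig carrying a tandem telomeric array and a multi-arm IR cluster.

    Arms are diverged copies of one template laid out in the configured
    orientations with random spacers; per-copy substitution rate is chosen so
    the expected arm-to-arm difference equals ``arm_divergence`` (identity
    93.3% at the default 0.067).  Returns ``(sequence, truth)`` with every
    planted feature's coordinates in the ground truth.
    """
    rc = config.repeats
    rng = np.random.default_rng(config.seed + 2)
    # pairwise difference between two copies mutated at rate e:
    # p = 2e - (4/3)e^2  ->  solve for e
    p = rc.arm_divergence
    eps = (2 - np.sqrt(4 - 16 * p / 3)) / (8 / 3)
    template = random_sequence(max(rc.arm_lengths), rng)

    truth = GroundTruth(system=config.system)
    parts: list[str] = [random_sequence(rc.left_pad, rng)]
    cursor = rc.left_pad
    n_arms = len(rc.arm_lengths)
    for i, (alen, fwd) in enumerate(zip(rc.arm_lengths, rc.arm_forward)):
        arm = _mutate(template[:alen], eps, rng)
        if not fwd:
            arm = reverse_complement(arm)
        parts.append(arm)
        truth.arm_intervals.append(
            GenomicInterval("ir_contig", cursor, cursor + alen, reverse=not fwd)
        )
        cursor += alen
        if i < n_arms - 1:
            slen = rc.spacer_lengths[i] if i < len(rc.spacer_lengths) else 30
            parts.append(random_sequence(slen, rng))
            cursor += slen
    truth.arm_identity_pct = 100.0 * (1.0 - rc.arm_divergence)

    telo = TELOMERE_MOTIF * rc.telomere_copies
    parts.append(random_sequence(200, rng))
    cursor += 200
    truth.telomere_intervals.append(
        GenomicInterval("ir_contig", cursor, cursor + len(telo))
    )
    parts.append(telo)
    cursor += len(telo)
    parts.append(random_sequence(rc.right_pad, rng))
    return "".join(parts), truth


_SAFE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def simulate_codon_pair(n_codons: int, divergence: float, seed: int = 0):
    """An in-frame coding pair: random stop-free codons, one copy mutated at
    per-site rate ``divergence`` (substitutions creating stops are redrawn)."""
    rng = np.random.default_rng(seed)
    codons = [str(x) for x in rng.choice(_SAFE_CODONS, size=n_codons)]
    seq_a = "".join(codons)
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for codon in codons:
        mutant = _mutate(codon, divergence, rng)
        while mutant in stops:
            mutant = _mutate(codon, divergence, rng)
        out.append(mutant)
    return seq_a, "".join(out)


def simulate_clade_alignment(
    n_per_clade: int = 3,
    length: int = 2000,
    within: float = 0.01,
    between: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, str], str]:
    """Two well-separated clades of aligned sequences (no indels).

    Returns ``(alignment, true_newick_topology)``; the separating split is
    what a tree builder must recover with high bootstrap support.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_sequence(length, rng)
    roots = {"X": _mutate(ancestor, between / 2, rng),
             "Y": _mutate(ancestor, between / 2, rng)}
    aln = {
        f"{clade}{i}": _mutate(root, within, rng)
        for clade, root in roots.items()
        for i in range(1, n_per_clade + 1)
    }
    topo = (
        "(" + ",".join(f"X{i}" for i in range(1, n_per_clade + 1)) + "),("
        + ",".join(f"Y{i}" for i in range(1, n_per_clade + 1)) + ");"
    )
    return aln, topo


def write_all(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "sex": outdir / "sex.tsv",
        "depth_f": outdir / "depth_f.tsv",
        "depth_m": outdir / "depth_m.tsv",
        "fasta": outdir / "contig.fasta",
        "truth": outdir / "truth.json",
    }
    rows, sex_table, truth = simulate_population(config)
    contigs = {
        config.autosome_name: config.autosome_length,
        config.sdr_span.chrom: config.sdr_contig_length,
    }
    write_vcf(rows, paths["vcf"], contigs)
    write_sex_table(sex_table, paths["sex"])
    positions, depth_f, depth_m, _ = simulate_depth(config)
    write_depth_table(positions, depth_f, config.sdr_span.chrom, paths["depth_f"])
    write_depth_table(positions, depth_m, config.sdr_span.chrom, paths["depth_m"])
    seq, repeat_truth = simulate_repeat_sequence(config)
    write_fasta({"ir_contig": seq}, paths["fasta"])
    truth.telomere_intervals = repeat_truth.telomere_intervals
    truth.arm_intervals = repeat_truth.arm_intervals
    truth.arm_identity_pct = repeat_truth.arm_identity_pct
    truth.to_json(paths["truth"])
    return paths
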