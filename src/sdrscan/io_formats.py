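"""Readers/writers for the standard formats the pipeline touches.

Coordinate bookkeeping convention: every :class:`GenomicInterval` is stored
0-based half-open (BED-style).  User-facing report tables render intervals
1-based inclusive, the convention genome browsers and the field's supplementary
tables use.  The two renderings are exact bijections of one another.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Phylo, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: INFO annotations the hard filter references.
INFO_KEYS = ("AF", "QD", "ExcessHet", "FS", "MQ")


class Genotype(Enum):
    """Diploid genotype call of a biallelic SNP."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class SexLabel(Enum):
    FEMALE = "female"
    MALE = "male"


class VcfConfigError(ValueError):
    """Sample/sex-table mismatch or other configuration problem."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``start < end``.

    ``report_start``/``report_end`` give the 1-based inclusive rendering used
    in output tables.
    """

    chrom: str
    start: int
    end: int
    reverse: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @classmethod
    def from_1based(
        cls, chrom: str, start1: int, end1: int, reverse: bool = False
    ) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates as printed in reports."""
        return cls(chrom, start1 - 1, end1, reverse=reverse)

    @property
    def report_start(self) -> int:
        return self.start + 1

    @property
    def report_end(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def interval_length(interval: GenomicInterval) -> int:
    """Base-pair span: ``end - start`` under the half-open convention.

    Equals (1-based end − 1-based start + 1) of the report rendering, e.g. a
    row printed as 25,381–29,199 spans 3,819 bp.
    """
    return len(interval)


@dataclass
class VariantRecord:
    """One biallelic SNP with per-sample genotype codes and INFO metrics."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    info_metrics: dict[str, float]
    genotypes: dict[str, Genotype]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class SexTable:
    """Mapping sample identifier -> sex label; duplicates rejected."""

    sexes: dict[str, SexLabel]

    @property
    def samples(self) -> list[str]:
        return list(self.sexes)

    def of_sex(self, sex: SexLabel) -> list[str]:
        return [s for s, lab in self.sexes.items() if lab is sex]

    @property
    def n_females(self) -> int:
        return len(self.of_sex(SexLabel.FEMALE))

    @property
    def n_males(self) -> int:
        return len(self.of_sex(SexLabel.MALE))


_SEX_ALIASES = {
    "f": SexLabel.FEMALE,
    "female": SexLabel.FEMALE,
    "m": SexLabel.MALE,
    "male": SexLabel.MALE,
}


def read_sex_table(path: str | Path) -> SexTable:
    """Read a 2-column TSV (sample, F/M); header optional."""
    sexes: dict[str, SexLabel] = {}
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sample, label = row[0].strip(), row[1].strip().lower()
            if lineno == 1 and sample.lower() in ("sample", "id", "name"):
                continue  # header line
            if label not in _SEX_ALIASES:
                raise ValueError(f"{path}:{lineno}: unknown sex label {row[1]!r}")
            if sample in sexes:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            sexes[sample] = _SEX_ALIASES[label]
    if not sexes:
        raise ValueError(f"{path}: empty sex table")
    return SexTable(sexes)


def write_sex_table(table: SexTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tsex\n")
        for sample, lab in table.sexes.items():
            fh.write(f"{sample}\t{'F' if lab is SexLabel.FEMALE else 'M'}\n")


@dataclass
class VcfParseStats:
    """Tally of records skipped during parsing."""

    n_records: int = 0
    n_kept: int = 0
    n_multiallelic: int = 0
    n_non_snp: int = 0


def read_vcf(
    path: str | Path,
    sex_table: SexTable,
    stats: VcfParseStats | None = None,
) -> Iterator[VariantRecord]:
    """Stream biallelic SNP records from a VCF, genotypes keyed by sample.

    Multi-allelic and non-SNP records are skipped and tallied in ``stats``
    rather than split.  Samples in the VCF header must be a superset of the
    sex table's samples; genotypes are returned for the sex-table samples only.
    """
    from cyvcf2 import VCF  # deferred: import cost

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s for s in sex_table.samples if s not in header_samples]
    if missing:
        raise VcfConfigError(
            f"samples in sex table absent from VCF header: {missing[:5]}"
        )
    idx = {s: header_samples.index(s) for s in sex_table.samples}
    # cyvcf2 gt_types (gts012=False): 0=hom_ref 1=het 2=unknown 3=hom_alt
    code = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.MISSING, 3: Genotype.HOM_ALT}
    for v in vcf:
        if stats is not None:
            stats.n_records += 1
        if len(v.ALT) != 1:
            if stats is not None:
                stats.n_multiallelic += 1
            continue
        if not v.is_snp:
            if stats is not None:
                stats.n_non_snp += 1
            continue
        gt_types = v.gt_types
        info = {}
        for key in INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        yield VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            info_metrics=info,
            genotypes={s: code[int(gt_types[i])] for s, i in idx.items()},
        )
        if stats is not None:
            stats.n_kept += 1


def write_bed(features: Iterable, path: str | Path) -> None:
    """Write BED (0-based half-open).  Features carry ``.interval`` or are
    intervals themselves; an optional ``.name`` becomes column 4."""
    with open(path, "w") as fh:
        for feat in features:
            iv = feat.interval if hasattr(feat, "interval") else feat
            name = getattr(feat, "name", None)
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None:
                cols.append(str(name))
            fh.write("\t".join(cols) + "\n")


def write_tsv(rows: Iterable[dict], path: str | Path, comment: str | None = None) -> None:
    """Write a report TSV; interval columns must already be 1-based inclusive.

    ``comment`` lines (prefixed '#') state the coordinate convention.
    """
    rows = list(rows)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        if not rows:
            return
        header = list(rows[0])
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in header) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {identifier: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path):
    """Parse a newick tree (Bio.Phylo tree object)."""
    return Phylo.read(str(path), "newick")


def write_newick(tree, path: str | Path) -> None:
    """Write a tree to newick.  Accepts a Bio.Phylo tree or any object with a
    ``to_newick()`` method (e.g. :class:`sdrscan.phylo_divergence.PhyloTree`)."""
    if hasattr(tree, "to_newick"):
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    else:
        Phylo.write(tree, str(path), "newick", format_branch_length="%g")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
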