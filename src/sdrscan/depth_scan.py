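"""Hemizygosity scan from per-sex pooled coverage.

Median read depth of 1 kb non-overlapping windows is computed separately for
the female and male cohorts; a window with total median depth >= 400 is
classified by the log2 depth ratio log2((F+1)/(M+1)): below -1 male-biased
(present in males only, i.e. Y-hemizygous under XY), above +1 female-biased.
Boundaries are strict; windows below the depth floor are left unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io_formats import GenomicInterval

DEPTH_CAP = 80_000  # per-position pooled depth ceiling applied upstream


class BiasClass(Enum):
    MALE_BIASED = "male_biased"
    FEMALE_BIASED = "female_biased"
    UNBIASED = "unbiased"
    LOW_DEPTH = "low_depth"


@dataclass
class DepthWindow:
    interval: GenomicInterval
    median_f: float
    median_m: float
    log2_ratio: float | None
    bias_class: BiasClass
    partial: bool = False

    @property
    def total(self) -> float:
        return self.median_f + self.median_m


@dataclass
class DepthTrack:
    """Contiguous per-position coverage of one cohort (absent positions = 0)."""

    chrom: str
    depths_f: np.ndarray
    depths_m: np.ndarray

    def __post_init__(self) -> None:
        self.depths_f = np.minimum(np.asarray(self.depths_f), DEPTH_CAP)
        self.depths_m = np.minimum(np.asarray(self.depths_m), DEPTH_CAP)
        if self.depths_f.shape != self.depths_m.shape:
            raise ValueError("cohort tracks must cover the same positions")
        if (self.depths_f < 0).any() or (self.depths_m < 0).any():
            raise ValueError("negative depth")


def classify_window(
    median_f: float, median_m: float, min_total: float = 400.0
) -> tuple[BiasClass, float | None]:
    """(bias class, log2 ratio); ratio is None below the depth floor."""
    if median_f < 0 or median_m < 0:
        raise ValueError("negative depth")
    if median_f + median_m < min_total:
        return BiasClass.LOW_DEPTH, None
    ratio = float(np.log2((median_f + 1.0) / (median_m + 1.0)))
    if ratio < -1.0:
        return BiasClass.MALE_BIASED, ratio
    if ratio > 1.0:
        return BiasClass.FEMALE_BIASED, ratio
    return BiasClass.UNBIASED, ratio


def window_medians(
    track: DepthTrack, width: int = 1000, min_total: float = 400.0
) -> list[DepthWindow]:
    """Tile the track with non-overlapping windows from position 1.

    Median over all positions in the window (even count: mean of the two
    central order statistics).  A terminal partial window is retained and
    flagged.
    """
    n = len(track.depths_f)
    windows: list[DepthWindow] = []
    for start in range(0, n, width):
        end = min(start + width, n)
        mf = float(np.median(track.depths_f[start:end]))
        mm = float(np.median(track.depths_m[start:end]))
        cls, ratio = classify_window(mf, mm, min_total)
        windows.append(
            DepthWindow(
                interval=GenomicInterval(track.chrom, start, end),
                median_f=mf,
                median_m=mm,
                log2_ratio=ratio,
                bias_class=cls,
                partial=(end - start) < width,
            )
        )
    return windows


@dataclass
class SexSpecificRegion:
    interval: GenomicInterval
    bias_class: BiasClass
    n_windows: int
    mean_log2_ratio: float


def call_sex_specific_regions(
    windows: list[DepthWindow], min_consecutive: int = 3
) -> list[SexSpecificRegion]:
    """Merge runs of >= ``min_consecutive`` consecutive same-class biased
    windows into candidate sex-specific regions."""
    regions: list[SexSpecificRegion] = []
    run: list[DepthWindow] = []

    def flush():
        if len(run) >= min_consecutive:
            regions.append(
                SexSpecificRegion(
                    interval=GenomicInterval(
                        run[0].interval.chrom,
                        run[0].interval.start,
                        run[-1].interval.end,
                    ),
                    bias_class=run[0].bias_class,
                    n_windows=len(run),
                    mean_log2_ratio=float(
                        np.mean([w.log2_ratio for w in run])
                    ),
                )
            )

    for w in windows:
        biased = w.bias_class in (BiasClass.MALE_BIASED, BiasClass.FEMALE_BIASED)
        if run and (
            not biased
            or w.bias_class is not run[-1].bias_class
            or w.interval.chrom != run[-1].interval.chrom
            or w.interval.start != run[-1].interval.end
        ):
            flush()
            run = []
        if biased:
            run.append(w)
    flush()
    return regions


def read_depth_tsv(path) -> tuple[str, np.ndarray]:
    """Read a samtools-depth dialect TSV (contig, 1-based pos, depth) for a
    single contig into a dense array (absent positions = 0)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    if df.empty:
        raise ValueError(f"{path}: empty depth table")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected a single contig, got {len(chroms)}")
    dense = np.zeros(int(df["pos"].max()), dtype=np.int64)
    dense[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return str(chroms[0]), dense
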