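"""Telomere-array and inverted-repeat detection.

Telomeric regions are maximal chains of exact (TTTAGGG)n / (CCCTAAA)n motif
copies with short interruptions allowed; a chain is designated telomeric when
it contains at least 1000 bp of motif-matched sequence.

Inverted repeats are found the way one reads a self-alignment dotplot: all
shared k-mers between the sequence and itself (forward off-diagonal and
reverse-complement) are chained into collinear runs; compatible
reverse-complement runs are clustered into candidate arm pairs, each pair is
re-aligned globally, and arms are kept by length and percent identity
(identical columns / alignment columns, gap columns included in the
denominator).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io_formats import GenomicInterval
from .ltr_dating import _make_aligner

TELOMERE_MOTIFS = ("TTTAGGG", "CCCTAAA")

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class TelomereRun:
    interval: GenomicInterval
    motif: str
    copy_count: int
    matched_bases: int

    @property
    def name(self) -> str:  # BED column 4
        return f"telomere_{self.motif}_{self.copy_count}x"


def scan_telomere(
    sequence: str,
    motifs: tuple[str, ...] = TELOMERE_MOTIFS,
    min_total: int = 1000,
    max_interruption: int = 7,
    chrom: str = "seq",
) -> list[TelomereRun]:
    """Maximal motif-copy chains with inter-copy gaps <= ``max_interruption``
    bp, designated telomeric iff motif-matched bases >= ``min_total``."""
    sequence = sequence.upper()
    runs: list[TelomereRun] = []
    for motif in motifs:
        m = len(motif)
        hits = []
        start = sequence.find(motif)
        while start != -1:
            hits.append(start)
            start = sequence.find(motif, start + m)  # non-overlapping copies
        chain: list[int] = []
        for pos in hits + [None]:
            if chain and (pos is None or pos - (chain[-1] + m) > max_interruption):
                total = len(chain) * m
                if total >= min_total:
                    runs.append(
                        TelomereRun(
                            interval=GenomicInterval(chrom, chain[0], chain[-1] + m),
                            motif=motif,
                            copy_count=len(chain),
                            matched_bases=total,
                        )
                    )
                chain = []
            if pos is not None:
                chain.append(pos)
    runs.sort(key=lambda r: r.interval.start)
    return runs


@dataclass
class DotplotMatch:
    query: GenomicInterval
    subject: GenomicInterval
    orientation: str  # "forward" | "reverse-complement"
    n_kmers: int


def _chain_pairs(pairs_by_key, k, step_j, chrom, orientation, min_run):
    """Chain (i, j) seed pairs sharing a (anti)diagonal into maximal runs of
    consecutive k-mers; step_j is +1 (forward) or -1 (reverse-complement)."""
    matches = []
    for _, pairs in pairs_by_key.items():
        pairs.sort()
        run: list[tuple[int, int]] = []
        for pair in pairs + [None]:
            if run and (pair is None or pair[0] != run[-1][0] + 1):
                if len(run) >= min_run:
                    i0, j0 = run[0]
                    i1, j1 = run[-1]
                    js = sorted((j0, j1))
                    matches.append(
                        DotplotMatch(
                            query=GenomicInterval(chrom, i0, i1 + k),
                            subject=GenomicInterval(chrom, js[0], js[1] + k),
                            orientation=orientation,
                            n_kmers=len(run),
                        )
                    )
                run = []
            if pair is not None:
                # grouping by (anti)diagonal already forces the j-step to
                # match step_j whenever i advances by 1
                run.append(pair)
    return matches


def self_dotplot(
    sequence: str,
    k: int = 15,
    min_run: int = 3,
    chrom: str = "seq",
    max_kmer_freq: int = 50,
) -> list[DotplotMatch]:
    """Shared-k-mer self-comparison.

    Reports maximal collinear runs of >= ``min_run`` consecutive shared
    k-mers, forward (off-diagonal; the trivial self-diagonal is suppressed)
    and reverse-complement.  Each pair is reported once with
    query.start <= subject.start.  K-mers occurring more than
    ``max_kmer_freq`` times are masked (standard seed masking: keeps dense
    satellite arrays such as telomeres from flooding the plot with
    quadratically many short-period seeds).
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < k:
        return []
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        index[sequence[i : i + k]].append(i)
    index = {
        kmer: pos for kmer, pos in index.items() if len(pos) <= max_kmer_freq
    }

    fwd = defaultdict(list)  # diag j-i -> [(i, j)]
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                fwd[j - i].append((i, j))

    rev = defaultdict(list)  # antidiag i+j -> [(i, j)]
    for kmer, positions in index.items():
        partners = index.get(revcomp(kmer))
        if not partners:
            continue
        for i in positions:
            for j in partners:
                if i < j:  # canonical orientation; i == j only for palindromes
                    rev[i + j].append((i, j))

    matches = _chain_pairs(fwd, k, +1, chrom, "forward", min_run)
    matches += _chain_pairs(rev, k, -1, chrom, "reverse-complement", min_run)
    matches.sort(key=lambda m: (m.query.start, m.subject.start))
    return matches


@dataclass
class IRArm:
    interval: GenomicInterval
    arm_id: str
    partner_id: str
    inverted: bool  # orientation relative to partner
    identity_pct: float
    spacer: GenomicInterval | None

    @property
    def name(self) -> str:
        return self.arm_id


def _cluster_rc_matches(matches: list[DotplotMatch], max_gap: int):
    """Cluster reverse-complement matches into candidate arm pairs.

    All seeds of one inverted-repeat pair lie on a common anti-diagonal of
    the dotplot (query.start + subject.end is constant up to indel drift), so
    matches are first banded by that coordinate (tolerance ``max_gap``) and
    each band is then split where consecutive seeds are separated by more
    than ``max_gap`` bp along the query."""
    def antidiag(m: DotplotMatch) -> int:
        return m.query.start + m.subject.end

    bands: list[list[DotplotMatch]] = []
    for m in sorted(matches, key=antidiag):
        if bands and antidiag(m) - antidiag(bands[-1][-1]) <= max_gap:
            bands[-1].append(m)
        else:
            bands.append([m])

    clusters: list[list[DotplotMatch]] = []
    for band in bands:
        band.sort(key=lambda m: m.query.start)
        current = [band[0]]
        for m in band[1:]:
            if m.query.start - max(x.query.end for x in current) > max_gap:
                clusters.append(current)
                current = [m]
            else:
                current.append(m)
        clusters.append(current)
    return clusters


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _extend_rc_pair(
    sequence: str, qs: int, qe: int, ss: int, se: int, x_drop: int = 10
) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a reverse-complement pair envelope.

    Query base i pairs with subject base (ss + se - 1) - (i - qs + offset);
    extending the query leftwards extends the subject rightwards and vice
    versa.  Each side extends while the running score (+1 match, -2 mismatch
    against the complemented partner base) stays within ``x_drop`` of its
    maximum, and stops at the maximum — a few bases past the true homology
    boundary the random flank decays the score."""
    n = len(sequence)

    def extend(q: int, s: int, dq: int, ds: int) -> int:
        score = best = best_steps = 0
        steps = 0
        while 0 <= q < n and 0 <= s < n and score > best - x_drop:
            steps += 1
            match = sequence[q] == _COMP.get(sequence[s], "N")
            score += 1 if match else -2
            if score > best:
                best, best_steps = score, steps
            q += dq
            s += ds
        return best_steps

    left = extend(qs - 1, se, -1, +1)
    right = extend(qe, ss - 1, +1, -1)
    return qs - left, qe + right, ss - right, se + left


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: identical columns / alignment columns x 100
    (gap columns count in the denominator)."""
    aln = _make_aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ident = sum(x == y for x, y in zip(s1, s2))
    return 100.0 * ident / len(s1)


def call_ir_arms(
    matches: list[DotplotMatch],
    sequence: str,
    min_arm: int = 500,
    min_identity: float = 85.0,
    max_chain_gap: int = 300,
    chrom: str = "seq",
) -> list[IRArm]:
    """Candidate inverted-repeat arm pairs from chained reverse-complement
    dotplot matches, validated by global re-alignment.

    Arm pairs may overlap other calls (nested/partial homologies are real
    features of IR clusters).  Each retained pair yields two IRArm records
    with symmetric partner references and the spacer between them.
    """
    sequence = sequence.upper()
    rc_matches = [m for m in matches if m.orientation == "reverse-complement"]
    arms: list[IRArm] = []
    pair_no = 0
    for cl in _cluster_rc_matches(rc_matches, max_chain_gap):
        qs = min(m.query.start for m in cl)
        qe = max(m.query.end for m in cl)
        ss = min(m.subject.start for m in cl)
        se = max(m.subject.end for m in cl)
        qs, qe, ss, se = _extend_rc_pair(sequence, qs, qe, ss, se)
        if min(qe - qs, se - ss) < min_arm:
            continue
        ident = percent_identity(sequence[qs:qe], revcomp(sequence[ss:se]))
        if ident < min_identity:
            continue
        pair_no += 1
        spacer = None
        if qe < ss:
            spacer = GenomicInterval(chrom, qe, ss) if ss > qe else None
        a_id, b_id = f"pair{pair_no}_arm_a", f"pair{pair_no}_arm_b"
        arms.append(
            IRArm(GenomicInterval(chrom, qs, qe), a_id, b_id, True, ident, spacer)
        )
        arms.append(
            IRArm(GenomicInterval(chrom, ss, se), b_id, a_id, True, ident, spacer)
        )
    arms.sort(key=lambda a: a.interval.start)
    return arms


def arm_report_rows(arms: list[IRArm]) -> list[dict]:
    """Rows rendering arm/spacer geometry 1-based inclusive."""
    rows = []
    seen_spacers = set()
    for arm in arms:
        rows.append(
            {
                "start": arm.interval.report_start,
                "end": arm.interval.report_end,
                "size": len(arm.interval),
                "label": arm.arm_id,
                "partner": arm.partner_id,
                "identity_pct": f"{arm.identity_pct:.1f}",
            }
        )
        sp = arm.spacer
        if sp is not None and (sp.start, sp.end) not in seen_spacers:
            seen_spacers.add((sp.start, sp.end))
            rows.append(
                {
                    "start": sp.report_start,
                    "end": sp.report_end,
                    "size": len(sp),
                    "label": f"spacer_{arm.arm_id}",
                    "partner": "",
                    "identity_pct": "",
                }
            )
    rows.sort(key=lambda r: r["start"])
    return rows
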