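"""Codon-level divergence (dS/dN) and distance-based phylogenetics.

dS/dN follows the Nei-Gojobori counting method: synonymous site fractions
per codon, pathway-averaged difference counts (paths through stop codons
excluded), and Jukes-Cantor correction of the proportions.  Pairwise
nucleotide distances use the Kimura 2-parameter model, optionally with
gamma-distributed rate variation among sites; trees are built by
neighbor-joining (Saitou-Nei) with bootstrap supports from column
resampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)
_NUC = "ACGT"
_PURINES = {"A", "G"}


class SaturationError(ValueError):
    """Observed divergence too high for the distance correction."""


def _aa(codon: str) -> str | None:
    return None if codon in _STOPS else _STANDARD.forward_table[codon]


# ---------------------------------------------------------------- dS/dN ----

@dataclass
class CodonAlignment:
    """Gap-free pair of in-frame coding sequences of equal length."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        self.seq_a, self.seq_b = self.seq_a.upper(), self.seq_b.upper()
        for seq in (self.seq_a, self.seq_b):
            if len(seq) % 3 != 0:
                raise ValueError("sequence length must be divisible by 3")
            if set(seq) - set(_NUC):
                raise ValueError("only unambiguous A/C/G/T allowed after filtering")
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences must have equal length")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError(f"in-frame stop codon at position {i + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


def filter_codon_columns(seq_a: str, seq_b: str) -> CodonAlignment:
    """Drop codon columns where either sequence has a gap or ambiguity code."""
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("aligned sequences of equal in-frame length required")
    keep_a, keep_b = [], []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if set(ca) | set(cb) <= set(_NUC) and ca not in _STOPS and cb not in _STOPS:
            keep_a.append(ca)
            keep_b.append(cb)
    return CodonAlignment("".join(keep_a), "".join(keep_b))


def _syn_sites(codon: str) -> float:
    """Fraction-of-3 synonymous sites: at each position, the share of the 3
    single-nucleotide changes that preserve the amino acid (changes to stop
    codons count as nonsynonymous)."""
    aa0 = _aa(codon)
    s = 0.0
    for pos in range(3):
        for nuc in _NUC:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1 :]
            if _aa(mutant) == aa0 and mutant not in _STOPS:
                s += 1.0 / 3.0
    return s


def _path_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all minimal substitution paths that avoid stop
    codons (all paths used if every one hits a stop)."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        current = ca
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if _aa(current) is not None and _aa(current) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        paths.append((sd, nd, through_stop))
    valid = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


@dataclass
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float

    @property
    def omega(self) -> float:
        return self.dN / self.dS if self.dS > 0 else math.inf


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4 saturates the correction")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def count_sites_and_differences(
    alignment: CodonAlignment,
) -> tuple[float, float, float, float]:
    """Nei-Gojobori counts (S, N, Sd, Nd): synonymous/nonsynonymous site
    totals (averaged across the two sequences; S + N = 3 x codon count) and
    pathway-averaged difference counts."""
    S = sum(
        (_syn_sites(ca) + _syn_sites(cb)) / 2.0 for ca, cb in alignment.codon_pairs()
    )
    N = 3.0 * alignment.n_codons - S
    Sd = Nd = 0.0
    for ca, cb in alignment.codon_pairs():
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def ng86_dnds(alignment: CodonAlignment) -> DnDsResult:
    """Nei-Gojobori synonymous/nonsynonymous rates for one sequence pair."""
    S, N, Sd, Nd = count_sites_and_differences(alignment)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return DnDsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=_jc(pS), dN=_jc(pN))


def filter_gene_pairs(
    results: dict[str, DnDsResult], ds_max: float = 0.5
) -> tuple[dict[str, DnDsResult], int]:
    """Drop pairs with anomalously high dS (> ``ds_max``, strict); such pairs
    are typically tandem paralogs of uncertain orthology.  Returns the
    retained mapping and the dropped count."""
    kept = {k: v for k, v in results.items() if v.dS <= ds_max}
    return kept, len(results) - len(kept)


# ---------------------------------------------------------- K2P distance ---

def k2p_distance(
    seq_a: str, seq_b: str, gamma_shape: float | None = None
) -> float:
    """Kimura 2-parameter distance; gapped/ambiguous columns excluded
    pairwise.

    Without gamma: d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).  With shape a:
    d = (a/2) [(1-2P-Q)^(-1/a) + 1/2 (1-2Q)^(-1/a) - 3/2], where P and Q are
    the transition and transversion proportions.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences of equal length required")
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in _NUC or y not in _NUC:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("substitution proportions saturate the K2P model")
    if gamma_shape is None:
        return -0.5 * math.log(w1 * math.sqrt(w2))
    a = gamma_shape
    return (a / 2.0) * (w1 ** (-1.0 / a) + 0.5 * w2 ** (-1.0 / a) - 1.5)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("distances must be non-negative with zero diagonal")


def distance_matrix(
    sequences: dict[str, str], gamma_shape: float | None = None
) -> DistanceMatrix:
    """Pairwise K2P distances of a multiple alignment."""
    labels = list(sequences)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = k2p_distance(
                sequences[labels[i]], sequences[labels[j]], gamma_shape
            )
    return DistanceMatrix(labels, d)


# ------------------------------------------------------------------- NJ ----

@dataclass
class Clade:
    name: str | None = None
    branch_length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree: the root clade is the central (trifurcating) node."""

    root: Clade
    clamped_branches: int = 0  # negative NJ estimates clamped to zero

    @property
    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaves())

    def to_newick(self) -> str:
        def render(c: Clade) -> str:
            if c.is_leaf:
                body = c.name
            else:
                inner = ",".join(render(x) for x in c.children)
                label = "" if c.support is None else f"{c.support:g}"
                body = f"({inner}){label}"
            if c.branch_length is None:
                return body
            return f"{body}:{c.branch_length:g}"

        return render(self.root) + ";"

    def _edges(self):
        """Yield (child clade, leaf-set below it) for every edge."""
        def walk(c: Clade):
            below = []
            for child in c.children:
                sub = walk(child)
                yield_list.append((child, sub))
                below.extend(sub)
            return below or [c.name]

        yield_list: list[tuple[Clade, list[str]]] = []
        walk(self.root)
        return yield_list

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the canonical side not containing the
        lexicographically smallest leaf."""
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out = set()
        for _, below in self._edges():
            side = frozenset(below)
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side if ref not in side else frozenset(all_leaves - side))
        return out

    def edge_lengths(self) -> dict[frozenset, float]:
        """Branch length per edge, keyed by the canonical split (leaf edges
        keyed by the singleton leaf set)."""
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out: dict[frozenset, float] = {}
        for clade, below in self._edges():
            side = frozenset(below)
            if len(side) >= len(all_leaves) - 1:
                continue  # trivial complement of a leaf edge at the root
            key = side
            if len(side) > 1 and ref in side:
                key = frozenset(all_leaves - side)
            out[key] = out.get(key, 0.0) + (clade.branch_length or 0.0)
        return out


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining.

    Q-criterion minimisation with ties broken by the lowest (row, column)
    index pair; branch lengths by the standard two-point formulas, negative
    estimates clamped to zero (tallied on the tree).
    """
    k = len(matrix.labels)
    if k < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Clade(name=lab) for lab in matrix.labels]
    D = matrix.values.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best, best_q = None, math.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = clamp(li)
        child_j.branch_length = clamp(lj)
        new = Clade(children=[child_i, child_j])
        dist_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        D2[n - 2, : n - 2] = D2[: n - 2, n - 2] = dist_new[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    # final three nodes join at the central (unrooted) vertex
    (a, b, c), d = nodes, D
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in zip((a, b, c), (la, lb, lc)):
        node.branch_length = clamp(ln)
    return PhyloTree(root=Clade(children=[a, b, c]), clamped_branches=clamped)


def bootstrap_tree(
    sequences: dict[str, str],
    replicates: int = 1000,
    seed: int = 0,
    gamma_shape: float | None = None,
) -> PhyloTree:
    """NJ tree of a multiple alignment with bootstrap supports.

    Alignment columns are resampled with replacement; each replicate is
    rebuilt with K2P(+gamma) + NJ and its bipartitions tallied.  Supports
    are percentages of successful replicates (a replicate whose resample
    saturates a pairwise distance is skipped and excluded from the
    denominator).
    """
    if len(sequences) < 4:
        raise ValueError("need at least 4 taxa for bootstrap supports")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    n_cols = lengths.pop()
    main = nj_tree(distance_matrix(sequences, gamma_shape))

    labels = list(sequences)
    arr = np.array([list(sequences[lab]) for lab in labels])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    n_ok = 0
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        boot = {lab: "".join(arr[i, idx]) for i, lab in enumerate(labels)}
        try:
            tree = nj_tree(distance_matrix(boot, gamma_shape))
        except SaturationError:
            continue
        n_ok += 1
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1

    def annotate(clade: Clade, all_leaves: set, ref: str):
        for child in clade.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                if ref in side:
                    side = frozenset(all_leaves - side)
                child.support = 100.0 * counts.get(side, 0) / max(n_ok, 1)
                annotate(child, all_leaves, ref)

    leaves = set(main.root.leaves())
    annotate(main.root, leaves, min(leaves))
    return main
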