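"""Motif similarity, decoy-calibrated Z-scores, and UPGMA clustering.

Two motifs are compared by sliding one over the other (both strands),
reducing each aligned column pair to a consensus-base match/mismatch, and
scoring the overlap with a one-sided Fisher-Irwin exact test against the
one-in-four random match expectation. Because the best attainable p-value
depends on the overlap length, raw p-values are calibrated into Z-scores
against a non-redundant decoy motif set at the same overlap length; Z is
capped at 10 and mapped to a distance D = |Z - 10| / 11.1 for tree building.
Motif families are the connected leaf sets of the UPGMA tree below the
height corresponding to the Z = 2 similarity cutoff (95% confidence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .errors import ComparisonError
from .motifgen import ALPHABET, PWM


@dataclass(frozen=True)
class ComparisonParams:
    min_overlap: int = 3        # columns
    z_cap: float = 10.0         # most-similar Z considered
    z_range: float = 11.1       # observed Z range (distance denominator)
    z_success: float = 2.0      # similarity threshold, 95% confidence
    decoy_redundancy_p: float = 0.05

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.z_cap <= self.z_success:
            raise ValueError("z_cap must exceed z_success")


@dataclass
class ComparisonResult:
    offset: int      # position of b's first column relative to a's first
    strand: str      # '+' or '-'
    overlap: int     # aligned columns L
    p_value: float
    z: float | None = None
    distance: float | None = None


@dataclass
class DecoySet:
    """Mutually non-redundant motifs used for Z-score calibration."""

    motifs: list[PWM] = field(default_factory=list)
    _pair_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.motifs)

    def pair_results(self, p: "ComparisonParams") -> list["ComparisonResult"]:
        """Best sliding comparison for every decoy pair (cached).

        These all-against-all comparisons are the calibration null: each is
        the same best-over-alignments statistic as a query-target
        comparison, so their -log10 p distribution at a given overlap
        length is directly comparable.
        """
        key = p.min_overlap
        if key not in self._pair_cache:
            results = []
            for i in range(len(self.motifs)):
                for j in range(i + 1, len(self.motifs)):
                    results.append(
                        fisher_slide_compare(self.motifs[i], self.motifs[j],
                                             p))
            self._pair_cache[key] = results
        return self._pair_cache[key]


def reverse_complement_pwm(m: PWM) -> PWM:
    """Reverse column order and swap A<->T, C<->G frequencies."""
    rc = m.matrix[::-1, ::-1].copy()  # ACGT reversed is TGCA: one flip does both
    return PWM(rc, name=f"{m.name}_rc" if m.name else "", meta=dict(m.meta))


@lru_cache(maxsize=None)
def _fisher_greater(L: int, matches: int) -> float:
    """One-sided Fisher-Irwin p for the 2x2 table
    [[matches, L - matches], [round(L/4), L - round(L/4)]]."""
    expected = round(L / 4)
    # hypergeometric tail: population 2L with (matches + expected) "successes",
    # draw L, observe >= matches
    return float(hypergeom.sf(matches - 1, 2 * L, matches + expected, L))


def _consensus_codes(m: PWM) -> np.ndarray:
    return np.argmax(m.matrix, axis=1)  # ties -> alphabetically first base


def _alignment_pvalues(a: PWM, b: PWM, p: ComparisonParams,
                       exact_overlap: int | None = None):
    """Yield (p_value, offset, strand, overlap) over all sliding alignments."""
    ca = _consensus_codes(a)
    for strand, bb in (("+", b), ("-", reverse_complement_pwm(b))):
        cb = _consensus_codes(bb)
        for offset in range(-(len(bb) - 1), len(a)):
            lo_a = max(0, offset)
            hi_a = min(len(a), offset + len(bb))
            overlap = hi_a - lo_a
            if overlap < p.min_overlap:
                continue
            if exact_overlap is not None and overlap != exact_overlap:
                continue
            seg_a = ca[lo_a:hi_a]
            seg_b = cb[lo_a - offset:hi_a - offset]
            matches = int(np.sum(seg_a == seg_b))
            yield (_fisher_greater(overlap, matches), offset, strand, overlap)


def fisher_slide_compare(a: PWM, b: PWM,
                         p: ComparisonParams | None = None,
                         exact_overlap: int | None = None) -> ComparisonResult:
    """Best sliding alignment of ``b`` (both strands) against ``a``.

    Returns the alignment with the smallest Fisher-Irwin p-value; ties keep
    the first alignment encountered (offsets ascending, '+' strand first),
    which makes the result deterministic.
    """
    p = p or ComparisonParams()
    if len(a) < p.min_overlap or len(b) < p.min_overlap:
        raise ComparisonError(
            f"motifs shorter than min_overlap={p.min_overlap}")
    best = None
    for pv, offset, strand, overlap in _alignment_pvalues(a, b, p,
                                                          exact_overlap):
        if best is None or pv < best[0]:
            best = (pv, offset, strand, overlap)
    if best is None:
        raise ComparisonError("no alignment achieves the requested overlap")
    pv, offset, strand, overlap = best
    return ComparisonResult(offset=offset, strand=strand, overlap=overlap,
                            p_value=pv)


def build_decoy_set(motifs: list[PWM],
                    p: ComparisonParams | None = None) -> DecoySet:
    """Greedy non-redundant decoy selection in input order.

    A candidate is rejected when its best sliding p-value against any
    already-retained decoy is below the redundancy cutoff.
    """
    import warnings

    p = p or ComparisonParams()
    if not motifs:
        raise ComparisonError("no motifs to build a decoy set from")
    if len(motifs) < 2:
        raise ComparisonError("need at least two candidate decoys")
    kept: list[PWM] = []
    for m in motifs:
        redundant = any(
            fisher_slide_compare(m, d, p).p_value < p.decoy_redundancy_p
            for d in kept)
        if not redundant:
            kept.append(m)
    if len(kept) < 2:
        warnings.warn("fewer than two decoys retained; "
                      "Z-score calibration will be unstable")
    return DecoySet(kept)


def similarity_zscore(result: ComparisonResult, query: PWM,
                      decoys: DecoySet,
                      p: ComparisonParams | None = None,
                      min_null: int = 8) -> float:
    """Calibrate a comparison p-value into a length-matched Z-score.

    The null is the all-against-all decoy comparison set restricted to best
    alignments of the same overlap length L as the query-target alignment
    (the equal-length requirement that makes short- and long-motif
    comparisons commensurable). When fewer than ``min_null`` decoy pairs
    land at exactly L, the length window widens symmetrically one column at
    a time until enough do. Z is the standard score of -log10(p) against
    that null, capped at ``z_cap``.
    """
    p = p or ComparisonParams()
    if len(decoys) < 2:
        raise ComparisonError("need at least two decoys for calibration")
    pairs = decoys.pair_results(p)
    xs: list[float] = []
    window = 0
    max_l = max(r.overlap for r in pairs)
    while len(xs) < min_null:
        xs = [-math.log10(r.p_value) for r in pairs
              if abs(r.overlap - result.overlap) <= window]
        if window > max_l:
            break
        window += 1
    if len(xs) < 2:
        raise ComparisonError(
            f"no decoy comparisons support alignment length L={result.overlap}")
    mu = float(np.mean(xs))
    sd = float(np.std(xs))
    if sd == 0:
        raise ComparisonError("degenerate calibration: zero decoy variance")
    z = (-math.log10(result.p_value) - mu) / sd
    return min(z, p.z_cap)


def z_to_distance(z: float, p: ComparisonParams | None = None) -> float:
    """D = |Z - z_cap| / z_range; zero for the most similar motifs."""
    p = p or ComparisonParams()
    if z > p.z_cap:
        raise ValueError(f"z={z} exceeds the cap {p.z_cap}")
    return abs(z - p.z_cap) / p.z_range


def compare_and_score(a: PWM, b: PWM, decoys: DecoySet,
                      p: ComparisonParams | None = None) -> ComparisonResult:
    """Full comparison: best alignment, calibrated Z and distance."""
    p = p or ComparisonParams()
    r = fisher_slide_compare(a, b, p)
    r.z = similarity_zscore(r, a, decoys, p)
    r.distance = z_to_distance(r.z, p)
    return r


# ---------------------------------------------------------------------------
# UPGMA clustering

@dataclass
class TreeNode:
    """Rooted ultrametric tree node (height = merge distance / 2)."""

    label: str
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=None) + ";"

    def _newick_inner(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.label
        else:
            inner = ",".join(c._newick_inner(self.height)
                             for c in self.children)
            body = f"({inner})"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6g}"


def upgma_tree(d: np.ndarray, labels: list[str]) -> TreeNode:
    """Standard UPGMA agglomeration with deterministic tie-breaking.

    Ties in the minimum pairwise distance are broken by the smallest
    (alphabetically first) pair of cluster labels, where a cluster is
    labelled by its alphabetically first leaf.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains NaN/inf")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")

    nodes = {i: TreeNode(labels[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    first_leaf = {i: labels[i] for i in range(n)}
    dist = {frozenset((i, j)): float(d[i, j])
            for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(
                first_leaf[i] for i in kv[0]))),
        )
        (pair, dmin) = best
        i, j = sorted(pair)
        merged = TreeNode(label=f"node{next_id}", height=dmin / 2.0,
                          children=[nodes[i], nodes[j]])
        ni, nj = sizes[i], sizes[j]
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        del dist[pair]
        del nodes[i], nodes[j]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        first_leaf[next_id] = min(first_leaf[i], first_leaf[j])
        del sizes[i], sizes[j], first_leaf[i], first_leaf[j]
        next_id += 1
    return next(iter(nodes.values()))


def cut_clusters(tree: TreeNode,
                 p: ComparisonParams | None = None) -> list[set[str]]:
    """Cut the UPGMA tree at the Z = z_success similarity level.

    The cut height is z_to_distance(z_success) / 2 (UPGMA node height is half
    the merge distance, so "pairwise distance <= D(z_success)" is "merged
    below the cut"). Returns the leaf sets of the maximal subtrees below the
    cut; motifs merging only above it come out as singletons.
    """
    p = p or ComparisonParams()
    cut = z_to_distance(p.z_success, p) / 2.0
    clusters: list[set[str]] = []

    def walk(node: TreeNode) -> None:
        if node.height <= cut + 1e-12:
            clusters.append(set(node.leaves()))
        else:
            for c in node.children:
                walk(c)

    walk(tree)
    return clusters


def benchmark_success(pairs: list[tuple[PWM, PWM]], decoys: DecoySet,
                      p: ComparisonParams | None = None) -> float:
    """Fraction of (predicted, experimental) motif pairs with Z >= z_success."""
    p = p or ComparisonParams()
    if not pairs:
        raise ComparisonError("no motif pairs to benchmark")
    hits = 0
    for pred, exp in pairs:
        r = fisher_slide_compare(pred, exp, p)
        z = similarity_zscore(r, pred, decoys, p)
        if z >= p.z_success:
            hits += 1
    return hits / len(pairs)
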