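"""From interface scores to binding-site sets and position weight matrices.

Raw interface scores are min-max normalized over the enumerated table
(S_norm = 0 for the strongest predicted binder, 1 for the weakest), turned
into relative affinities K_a = exp(-A / (k_B T) * S_norm), thresholded at a
relative affinity cutoff gamma, capped at a maximum number of sites, and
averaged -- weighting each k-mer by its K_a -- into a position weight matrix.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MotifError

ALPHABET = "ACGT"

#: Boltzmann constant, kcal/(mol K); fixed so A/(k_B T) is reproducible
K_BOLTZMANN = 1.9872041e-3


@dataclass(frozen=True)
class AffinityParams:
    """Score-to-affinity transform and site-selection parameters."""

    A: float = 4.74          # kcal/mol, slope of the exponential
    T: float = 298.0         # K
    k_B: float = K_BOLTZMANN
    gamma: float = 0.25      # relative affinity cutoff
    max_sites: int = 300

    def __post_init__(self) -> None:
        if self.A <= 0 or self.T <= 0 or not 0 < self.gamma < 1 \
                or self.max_sites < 1:
            raise ValueError("invalid affinity parameters")

    @property
    def beta(self) -> float:
        """A / (k_B T), about 8.004 at the defaults."""
        return self.A / (self.k_B * self.T)


@dataclass
class AffinityTable:
    """Per k-mer raw score, normalized score and relative affinity."""

    table: pd.DataFrame  # index: kmer; columns: S_RV, S_norm, (K_a)

    @property
    def k(self) -> int:
        return len(self.table.index[0])


@dataclass
class PWM:
    """A position weight matrix: one base-frequency column per position."""

    matrix: np.ndarray  # shape (k, 4), rows are positions, ACGT order
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise MotifError("PWM matrix must have shape (k, 4)")
        if np.any(self.matrix < 0):
            raise MotifError("PWM frequencies must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise MotifError("PWM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        """Per-position argmax base; ties go to the alphabetically first."""
        return "".join(ALPHABET[i] for i in np.argmax(self.matrix, axis=1))

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "",
                    meta: dict | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise MotifError("PWM counts have a non-positive column sum")
        return cls(counts / sums, name=name, meta=meta or {})


def normalize_scores(t) -> AffinityTable:
    """Min-max normalize raw scores; 0 = strongest binder, 1 = weakest."""
    scores = t.scores if hasattr(t, "scores") else dict(t)
    if len(scores) < 2:
        raise MotifError("need at least two scored sequences to normalize")
    s = pd.Series(scores, dtype=float).sort_index()
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise MotifError(
            "degenerate score table: all scores equal, no specificity signal")
    table = pd.DataFrame({"S_RV": s, "S_norm": (s - lo) / (hi - lo)})
    return AffinityTable(table)


def affinity_transform(s_norm, p: AffinityParams | None = None):
    """Relative affinity K_a = exp(-A/(k_B T) * S_norm), in (0, 1]."""
    p = p or AffinityParams()
    arr = np.asarray(s_norm, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("S_norm must lie in [0, 1]")
    out = np.exp(-p.beta * arr)
    return float(out) if np.isscalar(s_norm) else out


def add_affinities(t: AffinityTable,
                   p: AffinityParams | None = None) -> AffinityTable:
    p = p or AffinityParams()
    t.table["K_a"] = affinity_transform(t.table["S_norm"].to_numpy(), p)
    return t


def select_sites(t: AffinityTable, p: AffinityParams | None = None
                 ) -> list[tuple[str, float]]:
    """Binding sites: k-mers with K_a >= gamma, best first, capped.

    Sorted by K_a descending with lexicographic k-mer tie-break, then
    truncated to ``max_sites``. An empty selection is returned with a warning
    (no motif can be built from it).
    """
    import warnings

    p = p or AffinityParams()
    if "K_a" not in t.table:
        add_affinities(t, p)
    passing = t.table[t.table["K_a"] >= p.gamma]
    ordered = passing.sort_values(["K_a"], ascending=False, kind="mergesort")
    # mergesort is stable and the index is lexicographically sorted upstream,
    # so equal-K_a ties break alphabetically
    sites = list(zip(ordered.index, ordered["K_a"].astype(float)))[:p.max_sites]
    if not sites:
        warnings.warn("no k-mer passes the affinity cutoff; empty site set")
    return sites


def build_pwm(sites: list[tuple[str, float]], name: str = "") -> PWM:
    """Affinity-weighted base frequencies of the selected sites."""
    if not sites:
        raise MotifError("cannot build a PWM from an empty site set")
    k = len(sites[0][0])
    if any(len(s) != k for s, _ in sites):
        raise MotifError("sites have inconsistent lengths")
    counts = np.zeros((k, 4))
    for kmer, weight in sites:
        for pos, base in enumerate(kmer):
            counts[pos, ALPHABET.index(base)] += weight
    return PWM.from_counts(counts, name=name,
                           meta={"n_sites": len(sites)})


# ---------------------------------------------------------------------------
# PWM I/O: JASPAR PFM and MEME minimal dialects

def write_pwm(pwm: PWM, dialect: str = "jaspar_pfm",
              path: str | Path | None = None) -> str:
    if dialect == "jaspar_pfm":
        lines = [f">{pwm.name or 'motif'}"]
        for i, base in enumerate(ALPHABET):
            vals = " ".join(f"{v:.8f}" for v in pwm.matrix[:, i])
            lines.append(f"{base} [ {vals} ]")
        text = "\n".join(lines) + "\n"
    elif dialect == "meme_minimal":
        bg = "A 0.25 C 0.25 G 0.25 T 0.25"
        rows = "\n".join(" ".join(f"{v:.8f}" for v in row)
                         for row in pwm.matrix)
        text = (
            "MEME version 4\n\n"
            "ALPHABET= ACGT\n\n"
            "strands: + -\n\n"
            "Background letter frequencies\n"
            f"{bg}\n\n"
            f"MOTIF {pwm.name or 'motif'}\n"
            # large nsites keeps count-based readers faithful to 1e-6
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 100000000 E= 0\n"
            f"{rows}\n"
        )
    else:
        raise MotifError(f"unknown PWM dialect {dialect!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def read_pwm(source: str | Path, dialect: str = "jaspar_pfm") -> PWM:
    """Read a single motif; counts-style matrices are normalized."""
    from Bio import motifs as bio_motifs

    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    fmt = {"jaspar_pfm": "jaspar", "meme_minimal": "minimal"}.get(dialect)
    if fmt is None:
        raise MotifError(f"unknown PWM dialect {dialect!r}")
    try:
        record = bio_motifs.parse(io.StringIO(text), fmt)
        parsed = list(record)
    except Exception as exc:
        raise MotifError(f"malformed {dialect} motif: {exc}") from exc
    if not parsed:
        raise MotifError("no motif found in input")
    m = parsed[0]
    counts = np.array([[m.counts[b][i] for b in ALPHABET]
                       for i in range(m.length)], dtype=float)
    if np.any(counts.sum(axis=1) <= 0):
        raise MotifError("motif column does not sum to a positive value")
    name = getattr(m, "name", "") or getattr(m, "matrix_id", "") or ""
    return PWM.from_counts(counts, name=str(name))


def read_pwms(source: str | Path, dialect: str = "jaspar_pfm") -> list[PWM]:
    """Read every motif in a (possibly multi-motif) file."""
    from Bio import motifs as bio_motifs

    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    fmt = {"jaspar_pfm": "jaspar", "meme_minimal": "minimal"}[dialect]
    try:
        parsed = list(bio_motifs.parse(io.StringIO(text), fmt))
    except Exception as exc:
        raise MotifError(f"malformed {dialect} motif: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in ALPHABET]
                           for i in range(m.length)], dtype=float)
        name = getattr(m, "name", "") or getattr(m, "matrix_id", "") or ""
        out.append(PWM.from_counts(counts, name=str(name)))
    if not out:
        raise MotifError("no motif found in input")
    return out
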