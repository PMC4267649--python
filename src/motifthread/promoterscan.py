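"""Promoter extraction and PWM scanning with exact match-score p-values.

Promoters are windows around annotated transcription start sites (default
1500 bp upstream, 500 bp downstream, strand-aware). Scanning uses the
frequency-sum match score: a window of length k scores the sum over
positions of the PWM frequency of the letter it shows. P-values are exact
tail probabilities of that score for random sequences drawn from an iid
background, computed by position-wise convolution on a fixed score grid.
Hits below the p-value cutoff are ranked into a per-gene target table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .errors import ScanError
from .motifgen import ALPHABET, PWM

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: score grid resolution for the exact null distribution
GRID = 1e-4


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScanParams:
    upstream: int = 1500      # bp before the TSS
    downstream: int = 500     # bp after the TSS
    p_cutoff: float = 1e-4
    both_strands: bool = True
    background: tuple[float, float, float, float] | None = None  # ACGT

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream/downstream must be >= 0")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")


@dataclass
class Promoter:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int   # genomic, 0-based half-open, before strand flipping
    end: int
    sequence: str  # 5'->3' relative to the gene
    clipped: bool = False


@dataclass
class Hit:
    promoter_id: str
    gene_id: str
    position: int  # 0-based offset of the window on the promoter sequence
    strand: str    # '+': window as written; '-': site on the reverse strand
    word: str      # matched word read 5'->3' on its strand
    score: float
    p_value: float


# ---------------------------------------------------------------------------
# TSS parsing and promoter extraction

def _read_tss_bed(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype=str).iloc[:, :6]
        df.columns = ["chrom", "start", "end", "name", "score", "strand"]
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except Exception as exc:
        raise ScanError(f"malformed BED file {path}: {exc}") from exc
    if not set(df["strand"]).issubset({"+", "-"}):
        raise ScanError(f"malformed BED file {path}: bad strand field")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["chrom", "name", "strand", "tss"]]


def _read_tss_gff(path: Path,
                  feature_types: set[str] = frozenset(
                      {"gene", "mRNA", "transcript"})) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ScanError(f"malformed GFF line {lineno} in {path}")
        seqid, _, ftype, start, end, _, strand, _, attrs = parts
        if ftype not in feature_types:
            continue
        name = seqid
        for kv in attrs.rstrip(";").split(";"):
            if kv.startswith(("ID=", "Name=", "gene_id=")):
                name = kv.split("=", 1)[1]
                break
        # GFF is 1-based inclusive; convert to 0-based
        tss = int(start) - 1 if strand == "+" else int(end) - 1
        rows.append((seqid, name, strand, tss))
    return pd.DataFrame(rows, columns=["chrom", "name", "strand", "tss"])


def extract_promoters(genome: str | Path, tss: str | Path,
                      p: ScanParams | None = None) -> list[Promoter]:
    """Extract strand-aware promoter windows around each annotated TSS.

    For a + strand TSS t the window is [t - upstream, t + downstream);
    for a - strand TSS it is [t - downstream + 1, t + upstream + 1), reverse
    complemented so the output sequence reads 5'->3' relative to the gene.
    Windows falling off a contig edge are clipped and flagged.
    """
    p = p or ScanParams()
    tss = Path(tss)
    table = (_read_tss_gff(tss) if tss.suffix.lower() in (".gff", ".gff3")
             else _read_tss_bed(tss))
    fasta = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    promoters: list[Promoter] = []
    counts: dict[str, int] = {}
    for rec in table.itertuples(index=False):
        if rec.chrom not in fasta:
            raise ScanError(f"chromosome {rec.chrom!r} absent from the genome")
        clen = len(fasta[rec.chrom])
        if rec.strand == "+":
            lo, hi = rec.tss - p.upstream, rec.tss + p.downstream
        else:
            lo, hi = rec.tss - p.downstream + 1, rec.tss + p.upstream + 1
        clo, chi = max(0, lo), min(clen, hi)
        seq = str(fasta[rec.chrom][clo:chi])
        if rec.strand == "-":
            seq = revcomp(seq)
        n = counts.get(rec.name, 0)
        counts[rec.name] = n + 1
        promoters.append(Promoter(
            gene_id=rec.name,
            transcript_id=f"{rec.name}.{n}",
            chrom=rec.chrom, strand=rec.strand,
            start=clo, end=chi, sequence=seq,
            clipped=(clo != lo or chi != hi),
        ))
    return promoters


# ---------------------------------------------------------------------------
# exact score distribution

class ScoreDistribution:
    """Exact null distribution of frequency-sum match scores.

    Column score contributions are rounded to a fixed grid (resolution 1e-4)
    and convolved position by position against an iid background, giving the
    full probability mass function and an exact monotone tail function
    P(score >= s).
    """

    def __init__(self, pwm: PWM, background: np.ndarray):
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ScanError("background must be 4 ACGT frequencies summing to 1")
        self.grid = GRID
        self.col_scores = np.rint(pwm.matrix / GRID).astype(np.int64)  # (k, 4)
        pmf = np.array([1.0])
        for pos in range(len(pwm)):
            width = int(self.col_scores[pos].max())
            new = np.zeros(len(pmf) + width)
            for letter in range(4):
                s = int(self.col_scores[pos, letter])
                new[s:s + len(pmf)] += background[letter] * pmf
            pmf = new
        self.pmf = pmf
        # suffix sums give the tail; accumulate from the top for stability
        self.tail = np.cumsum(pmf[::-1])[::-1]

    def grid_score(self, word_codes: np.ndarray) -> int:
        return int(self.col_scores[np.arange(len(word_codes)),
                                   word_codes].sum())

    def pvalue_grid(self, grid_score) -> np.ndarray | float:
        """P(score >= s) for integer grid scores."""
        idx = np.clip(np.asarray(grid_score, dtype=np.int64), 0,
                      len(self.tail) - 1)
        out = self.tail[idx]
        return float(out) if np.isscalar(grid_score) else out

    def pvalue(self, score: float) -> float:
        """P(score >= s) for a float score, rounded onto the grid."""
        return float(self.pvalue_grid(int(round(score / self.grid))))


def score_distribution(m: PWM, background=None) -> ScoreDistribution:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return ScoreDistribution(m, bg)


# ---------------------------------------------------------------------------
# scanning

def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for i, base in enumerate(ALPHABET):
        codes[np.frombuffer(seq.encode(), dtype=np.uint8)
              == ord(base)] = i
    return codes


def promoter_background(promoters: list[Promoter]) -> np.ndarray:
    """ACGT composition over a promoter set (the default scanning null)."""
    counts = np.zeros(4)
    for pr in promoters:
        codes = _encode(pr.sequence)
        for i in range(4):
            counts[i] += int(np.sum(codes == i))
    if counts.sum() == 0:
        raise ScanError("promoter set contains no unambiguous bases")
    return counts / counts.sum()


def _scan_strand(codes: np.ndarray, dist: ScoreDistribution,
                 k: int) -> tuple[np.ndarray, np.ndarray]:
    """Grid scores and validity mask for every window start."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for pos in range(k):
        window_codes = codes[pos:pos + n]
        bad = window_codes < 0
        valid &= ~bad
        total += dist.col_scores[pos][np.where(bad, 0, window_codes)]
    return total, valid


def scan_pwm(m: PWM, promoters: list[Promoter],
             p: ScanParams | None = None,
             dist: ScoreDistribution | None = None) -> list[Hit]:
    """Scan promoters with a PWM; report windows with p <= p_cutoff.

    Every window on the forward strand (and, by default, the reverse strand)
    is scored by the frequency-sum rule on the exact-null score grid; windows
    containing ambiguous bases are skipped. Hits are sorted by p-value,
    promoter id, then position.
    """
    p = p or ScanParams()
    k = len(m)
    if dist is None:
        bg = (np.asarray(p.background) if p.background is not None
              else promoter_background(promoters))
        dist = ScoreDistribution(m, bg)
    hits: list[Hit] = []
    for pr in promoters:
        if len(pr.sequence) < k:
            continue
        codes = _encode(pr.sequence)
        strands = [("+", codes, pr.sequence)]
        if p.both_strands:
            rc = revcomp(pr.sequence)
            strands.append(("-", _encode(rc), rc))
        seq_len = len(pr.sequence)
        for strand, strand_codes, strand_seq in strands:
            totals, valid = _scan_strand(strand_codes, dist, k)
            if totals.size == 0:
                continue
            pvals = dist.pvalue_grid(totals)
            for j in np.nonzero(valid & (pvals <= p.p_cutoff))[0]:
                j = int(j)
                position = j if strand == "+" else seq_len - k - j
                hits.append(Hit(
                    promoter_id=pr.transcript_id,
                    gene_id=pr.gene_id,
                    position=position,
                    strand=strand,
                    word=strand_seq[j:j + k],
                    score=float(totals[j] * dist.grid),
                    p_value=float(pvals[j]),
                ))
    hits.sort(key=lambda h: (h.p_value, h.promoter_id, h.position))
    return hits


def rank_targets(hits: list[Hit], promoters: list[Promoter]) -> pd.DataFrame:
    """Per-gene target table: best hit across all promoters and strands.

    Genes are sorted by best match score descending, ties broken by p-value
    ascending then gene id; genes without hits are omitted.
    """
    if not hits:
        return pd.DataFrame(
            columns=["gene_id", "best_score", "best_p", "n_hits",
                     "best_word", "best_promoter"])
    df = pd.DataFrame([{
        "gene_id": h.gene_id, "score": h.score, "p": h.p_value,
        "word": h.word, "promoter": h.promoter_id,
    } for h in hits])
    rows = []
    for gene, grp in df.groupby("gene_id", sort=False):
        best = grp.sort_values(["score", "p"],
                               ascending=[False, True]).iloc[0]
        rows.append({
            "gene_id": gene,
            "best_score": float(best["score"]),
            "best_p": float(best["p"]),
            "n_hits": int(len(grp)),
            "best_word": best["word"],
            "best_promoter": best["promoter"],
        })
    out = pd.DataFrame(rows)
    out = out.sort_values(["best_score", "best_p", "gene_id"],
                          ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)
    return out
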