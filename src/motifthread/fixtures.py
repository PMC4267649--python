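"""Synthetic inputs with known ground truth.

Everything here is deliberately idealized: the pipeline's statistics see
only atom types and distances, so a physically naive geometry with exactly
controlled contacts is the strongest possible test input.

* :func:`make_toy_complex` -- a straight, untwisted DNA duplex built from the
  package's own base templates plus a pseudo-protein probe: one small
  residue per contacted base-pair position, each of a *distinct* residue
  type, parked within contact range (4.5 A) of exactly that position's
  reference base. Distinct residue types give the pair potential a
  positional handle, which the planted potential exploits.
* :func:`make_planted_potential` -- a pair potential whose energies make a
  chosen k-mer the unique global minimum over all 4^k threaded models.
* :func:`make_random_pwms` -- Dirichlet-random motifs for decoy calibration.
* :func:`make_toy_genome` -- a random genome + TSS annotation with motif
  words planted at recorded promoter offsets, for scanner tests.

All randomness flows through one seeded generator per call; identical specs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bases import BASE_TEMPLATES, COMPLEMENT
from .errors import GeometryError
from .motifgen import PWM
from .potential import DistanceBinning, PairPotential
from .promoterscan import revcomp
from .structio import Atom, StructureModel

#: residue types assigned to probe residues, one per contacted position;
#: distinct within k <= 9 so the potential can distinguish positions
PROBE_RESIDUES = ("ALA", "SER", "VAL", "THR", "LEU",
                  "ILE", "PHE", "ASP", "LYS")

# duplex layout (A): straight ladder, no twist -- contact bookkeeping only
RISE = 6.0            # base-pair separation along the axis
STRAND_SEP = 12.0     # glycosidic N to glycosidic N across the duplex
PROBE_X = 7.5         # probe anchor beyond the reference base edge

#: probe residue heavy atoms, offsets from the anchor in the base plane
PROBE_ATOMS = (
    ("N", "N", (0.8, 1.1)),
    ("CA", "C", (0.0, 0.0)),
    ("C", "C", (0.8, -1.1)),
    ("O", "O", (1.9, -1.3)),
    ("CB", "C", (1.4, 0.9)),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic test scenario."""

    seed: int = 0
    duplex_length: int = 9
    contact_positions: tuple[int, ...] = (3, 4, 5)  # 0-based, contiguous
    planted_kmer: str | None = None  # length = contact span; random if None
    # toy-genome parameters
    n_genes: int = 10
    upstream: int = 1500
    downstream: int = 500
    planted_sites: tuple[tuple[int, int, str], ...] = ()
    # (gene index, promoter offset, strand)

    def __post_init__(self) -> None:
        if not self.contact_positions:
            raise GeometryError("contact pattern is empty")
        if any(not 0 <= i < self.duplex_length
               for i in self.contact_positions):
            raise GeometryError("contact position outside the duplex")
        if self.planted_kmer is not None:
            if len(self.planted_kmer) != self.k:
                raise GeometryError(
                    f"planted k-mer length {len(self.planted_kmer)} != "
                    f"contact span {self.k}")
            if any(c not in "ACGT" for c in self.planted_kmer):
                raise GeometryError("planted k-mer must be over ACGT")

    @property
    def span(self) -> tuple[int, int]:
        return min(self.contact_positions), max(self.contact_positions)

    @property
    def k(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


def resolve_planted_kmer(spec: FixtureSpec) -> str:
    if spec.planted_kmer is not None:
        return spec.planted_kmer
    rng = np.random.default_rng(spec.seed)
    return "".join(rng.choice(list("ACGT"), size=spec.k))


def _base_atoms(base: str, resname_prefix: str, chain: str, index: int,
                glyco_xyz: np.ndarray, flip: bool) -> list[Atom]:
    """Place a base template (plus minimal C1'/P backbone) at a position."""
    sign = -1.0 if flip else 1.0
    atoms = []
    for name, local in BASE_TEMPLATES[base].items():
        xyz = glyco_xyz + np.array([sign * local[0], sign * local[1],
                                    local[2]])
        atoms.append(Atom(name=name, element=name[0],
                          residue_name=f"{resname_prefix}{base}",
                          residue_index=index, chain_id=chain, xyz=xyz))
    for name, offset in (("C1'", np.array([-1.45, 0.0, 0.0])),
                         ("P", np.array([-3.0, 1.2, 0.0]))):
        xyz = glyco_xyz + np.array([sign * offset[0], sign * offset[1],
                                    offset[2]])
        atoms.append(Atom(name=name, element=name[0],
                          residue_name=f"{resname_prefix}{base}",
                          residue_index=index, chain_id=chain, xyz=xyz))
    return atoms


def make_toy_complex(spec: FixtureSpec,
                     with_water: bool = False) -> StructureModel:
    """Idealized duplex + pseudo-protein probe with controlled contacts.

    The reference strand (chain B) runs along +z with bases extending +x;
    the complement strand (chain C) is offset by ``STRAND_SEP`` with bases
    extending -x, far outside the scoring cutoff of the probe. One probe
    residue (chain A) sits in the base plane of each contacted position.
    Deterministic given the spec (the seed fills uncontacted bases).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.duplex_length
    lo, _ = spec.span
    planted = resolve_planted_kmer(spec)
    native = [str(rng.choice(list("ACGT"))) for _ in range(n)]
    for i, base in enumerate(planted):
        native[lo + i] = base

    atoms: list[Atom] = []
    # probe residues, one per contacted position, in the base plane
    for ridx, pos in enumerate(sorted(spec.contact_positions), start=1):
        z = pos * RISE
        resname = PROBE_RESIDUES[(ridx - 1) % len(PROBE_RESIDUES)]
        for name, element, (dx, dy) in PROBE_ATOMS:
            atoms.append(Atom(name=name, element=element,
                              residue_name=resname, residue_index=ridx,
                              chain_id="A",
                              xyz=np.array([PROBE_X + dx, dy, z])))
    # reference strand, 5'->3' along +z
    for i in range(n):
        glyco = np.array([0.0, 0.0, i * RISE])
        atoms.extend(_base_atoms(native[i], "D", "B", i + 1, glyco,
                                 flip=False))
    # complement strand, antiparallel (its 5' end at the top)
    for j in range(n):
        pair_pos = n - 1 - j
        glyco = np.array([-STRAND_SEP, 0.0, pair_pos * RISE])
        atoms.extend(_base_atoms(COMPLEMENT[native[pair_pos]], "D", "C",
                                 j + 1, glyco, flip=True))
    if with_water:
        mid = sorted(spec.contact_positions)[len(spec.contact_positions) // 2]
        atoms.append(Atom(name="O", element="O", residue_name="HOH",
                          residue_index=1, chain_id="W",
                          xyz=np.array([PROBE_X - 2.0, 2.4, mid * RISE])))
    return StructureModel(atoms, resolution=1.8,
                          identifier=f"toy-seed{spec.seed}")


def make_planted_potential(
        spec: FixtureSpec,
        reward: float = 1.0,
        penalties: dict[int, dict[str, float]] | None = None,
        contact_bins: tuple[int, ...] = (0, 1, 2),
) -> tuple[PairPotential, str]:
    """A potential whose global minimum over 4^k threadings is the planted
    k-mer on the matching toy complex.

    By default the base planted at contact position i earns ``-reward`` per
    atom pair with that position's probe residue, everything else zero.
    ``penalties`` overrides the default with explicit per-position,
    per-base energies ({position: {base: energy}}), e.g. to build tables
    with a prescribed shape of the affinity distribution. Energies live
    only in the short-distance bins (< 5 A), which on the toy geometry are
    reachable exclusively by the position's own probe residue, so the score
    is exactly additive per position. Returns (potential, planted_kmer).
    """
    planted = resolve_planted_kmer(spec)
    binning = DistanceBinning()
    energies: dict = {}
    positions = sorted(spec.contact_positions)
    lo, _ = spec.span
    for ridx, pos in enumerate(positions):
        resname = PROBE_RESIDUES[ridx % len(PROBE_RESIDUES)]
        motif_pos = pos - lo
        for base in "ACGT":
            if penalties is not None:
                e = penalties.get(motif_pos, {}).get(base, 0.0)
            else:
                e = -reward if base == planted[motif_pos] else 0.0
            if e == 0.0:
                continue
            for pname, _, _ in PROBE_ATOMS:
                for bname in BASE_TEMPLATES[base]:
                    for b in contact_bins:
                        energies[((resname, pname), (base, bname), b)] = e
    pot = PairPotential(energies=energies, sigma=1.0, binning=binning,
                        meta={"planted_kmer": planted, "synthetic": True})
    return pot, planted


def make_random_pwms(n: int, k: int, sharpness: float = 5.0,
                     seed: int = 0) -> list[PWM]:
    """Dirichlet-random PWMs; larger sharpness gives peakier columns."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    alpha = np.full(4, 1.0 / sharpness)
    out = []
    for i in range(n):
        mat = rng.dirichlet(alpha, size=k)
        out.append(PWM(mat, name=f"random{i}",
                       meta={"seed": seed, "sharpness": sharpness}))
    return out


@dataclass
class ToyGenome:
    fasta_text: str
    bed_text: str
    truth: pd.DataFrame  # gene_id, promoter_offset, strand, word
    planted_kmer: str
    tss: list[int] = field(default_factory=list)

    def write(self, directory) -> tuple[str, str]:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        fa = d / "genome.fa"
        bed = d / "tss.bed"
        fa.write_text(self.fasta_text)
        bed.write_text(self.bed_text)
        return str(fa), str(bed)


def make_toy_genome(spec: FixtureSpec) -> ToyGenome:
    """Random-background genome with planted motif words in promoters.

    One chromosome; gene i's TSS sits at ``margin + i * spacing`` with
    strand drawn from the seed. Each planted site (gene, offset, strand)
    writes the planted k-mer into the genome so that the gene's promoter
    shows the word at that offset on that strand; the truth table records
    every planted site.
    """
    rng = np.random.default_rng(spec.seed)
    word = resolve_planted_kmer(spec)
    k = len(word)
    margin = spec.upstream + spec.downstream
    spacing = spec.upstream + spec.downstream + 1000
    length = 2 * margin + spec.n_genes * spacing
    genome = rng.choice(list("ACGT"), size=length)

    strands = [str(rng.choice(["+", "-"])) for _ in range(spec.n_genes)]
    tss = [margin + i * spacing for i in range(spec.n_genes)]

    prom_len = spec.upstream + spec.downstream
    truth_rows = []
    for gene, offset, strand in spec.planted_sites:
        if not 0 <= gene < spec.n_genes:
            raise GeometryError(f"planted site gene {gene} out of range")
        if not 0 <= offset <= prom_len - k:
            raise GeometryError(
                f"planted site offset {offset} outside the promoter window")
        g_strand = strands[gene]
        t = tss[gene]
        # promoter coordinates -> genomic coordinates
        if g_strand == "+":
            start = t - spec.upstream + offset
            insert = word if strand == "+" else revcomp(word)
        else:
            # promoter position p maps to genomic index t + upstream - p
            hi = t + spec.upstream - offset
            start = hi - k + 1
            insert = revcomp(word) if strand == "+" else word
        genome[start:start + k] = list(insert)
        truth_rows.append({"gene_id": f"gene{gene}", "promoter_offset": offset,
                           "strand": strand, "word": word})

    seq = "".join(genome)
    fasta_lines = [">chr1"]
    fasta_lines += [seq[i:i + 70] for i in range(0, len(seq), 70)]
    fasta_text = "\n".join(fasta_lines) + "\n"
    bed_lines = []
    for i in range(spec.n_genes):
        bed_lines.append(
            f"chr1\t{tss[i]}\t{tss[i] + 1}\tgene{i}\t0\t{strands[i]}")
    bed_text = "\n".join(bed_lines) + "\n"
    truth = pd.DataFrame(truth_rows,
                         columns=["gene_id", "promoter_offset", "strand",
                                  "word"])
    return ToyGenome(fasta_text=fasta_text, bed_text=bed_text, truth=truth,
                     planted_kmer=word, tss=tss)
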