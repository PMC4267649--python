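"""Distance-dependent, residue-specific knowledge-based contact potential.

The potential follows the Robertson-Varani recipe for protein-nucleic acid
interfaces: protein and DNA heavy atoms are typed by (residue name, atom
name), pair distances up to a 10 A cutoff are histogrammed into 8 bins (a
3 A first bin, then 1 A bins), and energies are log-odds of observed counts
against a reference state that factorizes pair-type and distance marginals:

    e(tp, td, bin) = -ln[(N(tp, td, bin) + sigma) / (N_exp(tp, td, bin) + sigma)]
    N_exp(tp, td, bin) = N(tp, td, .) * N(., ., bin) / N(., ., .)

with pseudocount ``sigma``. The interface score of a model is the sum of
energies over all protein-DNA heavy-atom pairs inside the cutoff (waters are
never scored). Lower scores mean stronger predicted association.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import PotentialError
from .structio import (AMINO_ACIDS, CuratedComplex, DNA_RESIDUES,
                       StructureModel)

ProteinType = tuple[str, str]  # (residue name, atom name)
DnaType = tuple[str, str]      # (base letter, atom name)


@dataclass(frozen=True)
class DistanceBinning:
    """Distance discretization of the potential."""

    cutoff: float = 10.0
    first_bin_width: float = 3.0
    other_bin_width: float = 1.0
    n_bins: int = 8

    def __post_init__(self) -> None:
        total = self.first_bin_width + (self.n_bins - 1) * self.other_bin_width
        if not math.isclose(total, self.cutoff):
            raise ValueError(
                "bin widths are inconsistent with the cutoff: "
                f"{self.first_bin_width} + {self.n_bins - 1} * "
                f"{self.other_bin_width} != {self.cutoff}")


def bin_index(d: float, b: DistanceBinning | None = None) -> int | None:
    """Distance bin for ``d`` (A), or None beyond the cutoff."""
    b = b or DistanceBinning()
    if d < 0:
        raise ValueError(f"negative distance {d}")
    if d >= b.cutoff:
        return None
    if d < b.first_bin_width:
        return 0
    return 1 + int((d - b.first_bin_width) // b.other_bin_width)


def _typed_atoms(m: StructureModel | CuratedComplex, strict: bool
                 ) -> tuple[list[tuple[ProteinType, np.ndarray]],
                            list[tuple[DnaType, np.ndarray]]]:
    atoms = (m.atoms if isinstance(m, StructureModel)
             else m.protein_atoms + m.dna_atoms)
    prot, dna = [], []
    for a in atoms:
        if not a.is_heavy:
            continue
        if a.record_class == "protein":
            prot.append(((a.residue_name.upper(), a.name), a.xyz))
        elif a.record_class == "dna":
            letter = DNA_RESIDUES.get(a.residue_name.strip().upper())
            if letter is None or letter not in "ACGT":
                if strict:
                    raise PotentialError(
                        f"unknown DNA residue {a.residue_name}")
                warnings.warn(f"skipping unknown DNA residue {a.residue_name}")
                continue
            dna.append(((letter, a.name), a.xyz))
        elif a.record_class == "other":
            if strict:
                raise PotentialError(
                    f"atom {a.name} of unknown residue {a.residue_name}")
            # silently outside the potential's universe (ions, ligands)
    return prot, dna


def iter_contact_pairs(m: StructureModel | CuratedComplex,
                       b: DistanceBinning | None = None,
                       strict: bool = False):
    """Yield (protein type, dna type, bin, distance) for in-range heavy-atom
    pairs, in deterministic (protein index, dna index) order."""
    b = b or DistanceBinning()
    prot, dna = _typed_atoms(m, strict)
    if not prot or not dna:
        return
    pcoords = np.array([x for _, x in prot])
    dcoords = np.array([x for _, x in dna])
    ptree = cKDTree(pcoords)
    dtree = cKDTree(dcoords)
    pairs = ptree.query_ball_tree(dtree, b.cutoff)
    for i, js in enumerate(pairs):
        for j in sorted(js):
            d = float(np.linalg.norm(pcoords[i] - dcoords[j]))
            k = bin_index(d, b)
            if k is not None:
                yield prot[i][0], dna[j][0], k, d


@dataclass
class PairPotential:
    """Trained energy table indexed by (protein type, dna type, bin)."""

    energies: dict[tuple[ProteinType, DnaType, int], float]
    sigma: float = 1.0
    binning: DistanceBinning = field(default_factory=DistanceBinning)
    meta: dict = field(default_factory=dict)

    def energy(self, tp: ProteinType, td: DnaType, bin_: int) -> float:
        return self.energies.get((tp, td, bin_), 0.0)

    def to_json(self) -> str:
        rows = [
            {"protein": list(tp), "dna": list(td), "bin": k, "e": e}
            for (tp, td, k), e in sorted(self.energies.items())
        ]
        return json.dumps({
            "format": "motifthread-potential-1",
            "sigma": self.sigma,
            "binning": {
                "cutoff": self.binning.cutoff,
                "first_bin_width": self.binning.first_bin_width,
                "other_bin_width": self.binning.other_bin_width,
                "n_bins": self.binning.n_bins,
            },
            "meta": self.meta,
            "energies": rows,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PairPotential":
        payload = json.loads(text)
        if payload.get("format") != "motifthread-potential-1":
            raise PotentialError("unrecognized potential file format")
        energies = {
            (tuple(r["protein"]), tuple(r["dna"]), int(r["bin"])): float(r["e"])
            for r in payload["energies"]
        }
        return cls(energies=energies, sigma=payload["sigma"],
                   binning=DistanceBinning(**payload["binning"]),
                   meta=payload.get("meta", {}))


def train_potential(complexes: list[CuratedComplex | StructureModel],
                    b: DistanceBinning | None = None,
                    sigma: float = 1.0,
                    self_swapped: bool = False) -> PairPotential:
    """Count-based training of the pair potential.

    Counts are accumulated over every protein-DNA heavy-atom pair within the
    cutoff across all training complexes (order-free), then converted to
    log-odds energies against the pair-type x distance marginal reference.
    ``self_swapped`` rebuilds each complex's bases onto their own backbone
    (native sequence) before counting, emulating training on self-modeled
    rather than raw crystal geometry.
    """
    b = b or DistanceBinning()
    if not complexes:
        raise PotentialError("cannot train on an empty complex list")
    counts: Counter = Counter()
    for c in complexes:
        if self_swapped:
            from .baseswap import swap_bases
            if not isinstance(c, CuratedComplex):
                raise PotentialError(
                    "self-swapped training requires curated complexes")
            c = swap_bases(c, c.native_sequence)
        for tp, td, k, _ in iter_contact_pairs(c, b):
            counts[(tp, td, k)] += 1
    total = sum(counts.values())
    pair_marg: Counter = Counter()
    bin_marg: Counter = Counter()
    for (tp, td, k), n in counts.items():
        pair_marg[(tp, td)] += n
        bin_marg[k] += n
    energies: dict[tuple[ProteinType, DnaType, int], float] = {}
    for (tp, td) in pair_marg:
        for k in range(b.n_bins):
            n_obs = counts.get((tp, td, k), 0)
            n_exp = pair_marg[(tp, td)] * bin_marg.get(k, 0) / total
            e = -math.log((n_obs + sigma) / (n_exp + sigma))
            if e != 0.0:
                energies[(tp, td, k)] = e
    return PairPotential(energies=energies, sigma=sigma, binning=b,
                         meta={"n_complexes": len(complexes),
                               "n_pairs": total,
                               "reference_state":
                                   "pair-type-marginal x distance-marginal",
                               "self_swapped": bool(self_swapped)})


def score_interface(m: StructureModel | CuratedComplex, pot: PairPotential,
                    b: DistanceBinning | None = None,
                    strict: bool = False) -> float:
    """Interface score: sum of pair energies over in-range heavy-atom pairs.

    Waters and non-protein/DNA residues are never scored; atoms of unknown
    type are skipped with a warning (or raise in ``strict`` mode). The sum
    uses math.fsum so the result is independent of pair enumeration order.
    """
    b = b or pot.binning
    terms = [pot.energy(tp, td, k)
             for tp, td, k, _ in iter_contact_pairs(m, b, strict=strict)]
    return math.fsum(terms)


@dataclass
class ScoreTable:
    """Raw interface scores for every enumerated k-mer."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        if not self.scores:
            raise PotentialError("empty score table")
        lengths = {len(s) for s in self.scores}
        if len(lengths) != 1:
            raise PotentialError("score table mixes k-mer lengths")

    @property
    def k(self) -> int:
        return len(next(iter(self.scores)))
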