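"""Threading DNA sequences onto a fixed backbone by base swapping.

For a curated complex with k contacted base pairs, every one of the 4^k
duplex sequences can be modeled by stripping each base down to its anchor
triad (the glycosidic nitrogen and its two bonded ring carbons, which carry
the directionality and planarity of the base) and rebuilding the desired
base on that triad with an idealized planar template. The sugar-phosphate
backbone, the protein and any interface waters are never touched. An
optional soft-sphere relaxation resolves steric clashes introduced by
bulkier replacement bases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.spatial import cKDTree

from .bases import (ANCHOR_TRIADS, BASE_ATOM_NAMES, BASE_TEMPLATES,
                    COMPLEMENT, kabsch_fit)
from .errors import StructureError
from .structio import (Atom, CuratedComplex, DuplexPosition, Residue,
                       StructureModel)

K_MAX = 9

#: soft-sphere radii by element (A); pairs closer than the radii sum clash
CLASH_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8}


@dataclass(frozen=True)
class SequenceAssignment:
    """A duplex sequence on the reference strand, 5'->3'."""

    kmer: str

    def __post_init__(self) -> None:
        if not self.kmer or any(c not in "ACGT" for c in self.kmer):
            raise ValueError(f"kmer must be over ACGT, got {self.kmer!r}")

    @property
    def complement_strand(self) -> str:
        """The paired strand read 5'->3'."""
        return "".join(COMPLEMENT[c] for c in reversed(self.kmer))


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k DNA sequences of length k in lexicographic order."""
    if not 1 <= k <= K_MAX:
        raise ValueError(f"k must be in 1..{K_MAX}, got {k}")
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def _replace_base(res: Residue, new_base: str) -> Residue:
    """Rebuild ``res`` with ``new_base`` on its retained anchor triad."""
    old_base = res.base_letter
    if old_base not in "ACGT":
        raise StructureError(
            f"cannot swap non-canonical base {res.residue_name} "
            f"at {res.residue_id}")
    old_triad = ANCHOR_TRIADS[old_base]
    new_triad = ANCHOR_TRIADS[new_base]
    by_name = {a.name: a for a in res.atoms}
    missing = [n for n in old_triad if n not in by_name]
    if missing:
        raise StructureError(
            f"base at {res.residue_id} is missing anchor atoms {missing}")
    new_resname = f"D{new_base}"
    strip = BASE_ATOM_NAMES[old_base] - set(old_triad)

    template = BASE_TEMPLATES[new_base]
    tri_mobile = np.array([template[n] for n in new_triad])
    tri_target = np.array([by_name[n].xyz for n in old_triad])
    rot, trans = kabsch_fit(tri_mobile, tri_target)

    atoms: list[Atom] = []
    for a in res.atoms:
        if a.name in strip:
            continue
        if a.name in old_triad:
            # retained in place, renamed positionally across base classes
            name = new_triad[old_triad.index(a.name)]
            atoms.append(dc_replace(a, name=name, element=name[0],
                                    residue_name=new_resname,
                                    xyz=a.xyz.copy()))
        else:  # backbone / sugar: untouched
            atoms.append(dc_replace(a, residue_name=new_resname,
                                    xyz=a.xyz.copy()))
    for name in template:
        if name in new_triad:
            continue
        atoms.append(Atom(name=name, element=name[0],
                          residue_name=new_resname,
                          residue_index=res.residue_index,
                          chain_id=res.chain_id,
                          xyz=rot @ template[name] + trans))
    return Residue(res.chain_id, res.residue_index, new_resname, atoms)


def swap_bases(c: CuratedComplex, s: SequenceAssignment | str) -> StructureModel:
    """Build the complex with the duplex carrying sequence ``s``.

    Both strands are rebuilt (reference base and Watson-Crick complement);
    protein, backbone and water coordinates are identical to the input.
    """
    if isinstance(s, str):
        s = SequenceAssignment(s)
    if len(s.kmer) != c.k:
        raise ValueError(
            f"sequence length {len(s.kmer)} does not match k={c.k}")
    atoms: list[Atom] = [dc_replace(a, xyz=a.xyz.copy())
                         for a in c.protein_atoms]
    for i, pos in enumerate(c.duplex):
        new_ref = _replace_base(pos.ref, s.kmer[i])
        atoms.extend(new_ref.atoms)
        if pos.mate is not None:
            new_mate = _replace_base(pos.mate, COMPLEMENT[s.kmer[i]])
            atoms.extend(new_mate.atoms)
    atoms.extend(dc_replace(a, xyz=a.xyz.copy()) for a in c.water_atoms)
    return StructureModel(atoms, resolution=c.resolution,
                          identifier=f"{c.identifier}:{s.kmer}")


def _default_movable(m: StructureModel) -> np.ndarray:
    """Indices of DNA base (non-backbone) heavy atoms: the swapped set."""
    idx = []
    for i, a in enumerate(m.atoms):
        if a.record_class != "dna" or not a.is_heavy:
            continue
        from .structio import DNA_RESIDUES
        letter = DNA_RESIDUES.get(a.residue_name.strip().upper())
        if letter in BASE_ATOM_NAMES and a.name in BASE_ATOM_NAMES[letter]:
            idx.append(i)
    return np.array(idx, dtype=int)


def clash_energy(m: StructureModel, movable: np.ndarray | None = None) -> float:
    """Soft-sphere repulsion: sum of max(0, r_i + r_j - d_ij)^2 over
    inter-residue pairs involving at least one movable (swapped-base) atom."""
    movable = _default_movable(m) if movable is None else np.asarray(movable)
    mask = np.zeros(len(m.atoms), dtype=bool)
    mask[movable] = True
    coords = np.array([a.xyz for a in m.atoms])
    e, _ = _energy_and_grad(coords, [a.element for a in m.atoms],
                            [a.residue_id for a in m.atoms], mask)
    return e


def _energy_and_grad(coords, elements, residue_keys, movable_mask):
    radii = np.array([CLASH_RADII.get(el.upper(), 1.7) for el in elements])
    rmax = 2 * radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(rmax, output_type="ndarray")
    energy = 0.0
    grad = np.zeros_like(coords)
    for i, j in pairs:
        if residue_keys[i] == residue_keys[j]:
            continue  # covalent neighbours within a residue are not clashes
        if not (movable_mask[i] or movable_mask[j]):
            continue  # frozen-frozen overlaps cannot be resolved here
        dvec = coords[i] - coords[j]
        d = float(np.linalg.norm(dvec))
        overlap = radii[i] + radii[j] - d
        if overlap <= 0 or d == 0:
            continue
        energy += overlap * overlap
        g = -2.0 * overlap * dvec / d
        if movable_mask[i]:
            grad[i] += g
        if movable_mask[j]:
            grad[j] -= g
    return energy, grad


def relax_clashes(m: StructureModel, steps: int = 100,
                  movable: np.ndarray | None = None) -> StructureModel:
    """Greedy descent on the soft-sphere clash energy, moving base atoms only.

    A line-searched gradient step guarantees the energy is monotonically
    non-increasing; a clash-free model is returned unchanged.
    """
    movable = _default_movable(m) if movable is None else np.asarray(movable)
    coords = np.array([a.xyz for a in m.atoms])
    elements = [a.element for a in m.atoms]
    keys = [a.residue_id for a in m.atoms]
    mask = np.zeros(len(m.atoms), dtype=bool)
    mask[movable] = True
    energy, grad = _energy_and_grad(coords, elements, keys, mask)
    if energy == 0.0:
        return m
    step = 0.1
    for _ in range(steps):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-12:
            break
        direction = -grad / gnorm
        alpha = step
        improved = False
        for _ in range(25):
            trial = coords + alpha * direction
            e_new, g_new = _energy_and_grad(trial, elements, keys, mask)
            if e_new < energy:
                coords, energy, grad = trial, e_new, g_new
                improved = True
                break
            alpha *= 0.5
        if not improved or energy == 0.0:
            break
    atoms = [dc_replace(a, xyz=coords[i].copy())
             for i, a in enumerate(m.atoms)]
    return StructureModel(atoms, resolution=m.resolution,
                          identifier=m.identifier)
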