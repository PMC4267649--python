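"""Reading, curating and trimming TF-DNA complex structures.

A raw crystal structure (PDB format) is reduced to a :class:`CuratedComplex`:
the protein, the stretch of duplex DNA it actually touches, and any crystal
waters bridging the interface. Curation follows the usual filters for
building a threading template: resolution better than 2.5 A, protein-DNA
contact defined as any heavy-atom pair within 4.5 A, at most nine contacted
base pairs (the motif length k), all retained bases canonical and complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .bases import BASE_ATOM_NAMES, COMPLEMENT
from .errors import CurationError, StructureError, StructureFormatError

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL".split()
)
#: residue name -> one-letter base code ('U' parses as DNA but is rejected as
#: non-canonical at curation time)
DNA_RESIDUES = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "U",
}
WATER_RESIDUES = frozenset({"HOH", "WAT"})
CANONICAL_BASES = frozenset("ACGT")

#: minimal sugar/phosphate atom names treated as DNA backbone when present
BACKBONE_ATOMS = frozenset(
    "P OP1 OP2 OP3 O5' C5' C4' O4' C3' O3' C2' C1'".split()
)


def classify_residue(residue_name: str) -> str:
    name = residue_name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    if name in WATER_RESIDUES:
        return "water"
    return "other"


@dataclass
class Atom:
    """One heavy (or hydrogen) atom of a structure."""

    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    xyz: np.ndarray
    record_class: str = field(default="")

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise StructureError(
                f"atom {self.name} has non-finite or malformed coordinates")
        if not self.record_class:
            self.record_class = classify_residue(self.residue_name)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class StructureModel:
    """A parsed structure: a flat atom list plus file-level metadata."""

    atoms: list[Atom]
    resolution: float | None = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureFormatError("empty structure: no atoms")

    def atoms_of_class(self, record_class: str, heavy_only: bool = True
                       ) -> list[Atom]:
        return [a for a in self.atoms
                if a.record_class == record_class
                and (a.is_heavy or not heavy_only)]

    @property
    def protein_atoms(self) -> list[Atom]:
        return self.atoms_of_class("protein")

    @property
    def dna_atoms(self) -> list[Atom]:
        return self.atoms_of_class("dna")

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen


@dataclass
class Residue:
    chain_id: str
    residue_index: int
    residue_name: str
    atoms: list[Atom]

    @property
    def base_letter(self) -> str | None:
        return DNA_RESIDUES.get(self.residue_name.strip().upper())

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms if a.is_heavy])


def group_residues(atoms: Iterable[Atom]) -> list[Residue]:
    """Group atoms into residues preserving file order."""
    order: list[tuple[str, int]] = []
    table: dict[tuple[str, int], Residue] = {}
    for a in atoms:
        key = a.residue_id
        if key not in table:
            table[key] = Residue(a.chain_id, a.residue_index, a.residue_name, [])
            order.append(key)
        table[key].atoms.append(a)
    return [table[k] for k in order]


@dataclass
class DuplexPosition:
    """One base-pair position of the (possibly trimmed) duplex."""

    ref: Residue
    mate: Residue | None

    @property
    def base(self) -> str | None:
        return self.ref.base_letter


@dataclass
class CurationParams:
    """Filters applied when curating a TF-DNA complex."""

    resolution_max: float = 2.5
    contact_cutoff: float = 4.5
    k_max: int = 9
    keep_interface_waters: bool = True

    def __post_init__(self) -> None:
        if (self.resolution_max <= 0 or self.contact_cutoff <= 0
                or self.k_max <= 0):
            raise ValueError("curation parameters must be positive")


@dataclass
class CuratedComplex:
    """A TF bound to the trimmed stretch of DNA it contacts."""

    protein_atoms: list[Atom]
    duplex: list[DuplexPosition]
    water_atoms: list[Atom]
    contacting_positions: list[int]
    interface_residue_ids: set[tuple[str, int]]
    native_sequence: str
    identifier: str = ""
    resolution: float | None = None

    @property
    def k(self) -> int:
        return len(self.duplex)

    @property
    def dna_atoms(self) -> list[Atom]:
        out: list[Atom] = []
        for pos in self.duplex:
            out.extend(pos.ref.atoms)
            if pos.mate is not None:
                out.extend(pos.mate.atoms)
        return out

    def to_structure_model(self) -> StructureModel:
        atoms = list(self.protein_atoms) + self.dna_atoms + list(self.water_atoms)
        return StructureModel(atoms, resolution=self.resolution,
                              identifier=self.identifier)


# ---------------------------------------------------------------------------
# parsing / writing

def parse_structure(text: str, identifier: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    All atoms of the first model are loaded; residues are classified as
    protein / dna / water / other by name. Malformed ATOM/HETATM records
    raise :class:`StructureFormatError` naming the offending line.
    """
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise StructureFormatError(
                    f"line {lineno}: truncated {line[:6].strip()} record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise StructureFormatError(
                    f"line {lineno}: unparseable coordinates") from exc
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"unparseable PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError("empty structure: no models")
    atoms: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            for at in res:
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    residue_index=res.seqid.num,
                    chain_id=chain.name,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                ))
    if not atoms:
        raise StructureFormatError("empty structure: no atoms")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(atoms, resolution=resolution,
                          identifier=identifier or st.name or "")


def read_structure(path: str | Path) -> StructureModel:
    path = Path(path)
    return parse_structure(path.read_text(), identifier=path.stem)


def write_pdb(model: StructureModel | Sequence[Atom],
              path: str | Path | None = None) -> str:
    """Serialize atoms as PDB-format text (and optionally write a file)."""
    atoms = model.atoms if isinstance(model, StructureModel) else list(model)
    lines = []
    resolution = model.resolution if isinstance(model, StructureModel) else None
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
    serial = 0
    for a in atoms:
        serial += 1
        record = "ATOM" if a.record_class in ("protein", "dna") else "HETATM"
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record:<6s}{serial:5d} {name:<4s} {a.residue_name:<3s} "
            f"{a.chain_id[:1]:1s}{a.residue_index:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# duplex bookkeeping

def duplex_positions(s: StructureModel) -> list[DuplexPosition]:
    """Pair the two DNA strands into base-pair positions.

    The first DNA chain in the file is the reference strand (5'->3' in file
    order); an equal-length second chain is paired antiparallel by index.
    Pairing is validated by Watson-Crick complementarity over the canonical
    bases (at least 60% of pairable positions must be complementary).
    """
    dna = [a for a in s.atoms if a.record_class == "dna"]
    if not dna:
        return []
    by_chain: dict[str, list[Atom]] = {}
    for a in dna:
        by_chain.setdefault(a.chain_id, []).append(a)
    chains = [group_residues(atoms) for atoms in by_chain.values()]
    if len(chains) == 1:
        return [DuplexPosition(res, None) for res in chains[0]]
    if len(chains) > 2:
        raise StructureError(
            f"expected at most 2 DNA chains, found {len(chains)}")
    ref, mate = chains
    if len(ref) != len(mate):
        raise StructureError(
            "DNA strands have unequal lengths; cannot pair the duplex")

    def complementarity(pairs: list[DuplexPosition]) -> float:
        checkable = [p for p in pairs
                     if p.ref.base_letter in CANONICAL_BASES
                     and p.mate.base_letter in CANONICAL_BASES]
        if not checkable:
            return 1.0
        return sum(COMPLEMENT[p.ref.base_letter] == p.mate.base_letter
                   for p in checkable) / len(checkable)

    # an antiparallel mate usually appears in reverse file order, but a
    # previously trimmed complex may store it already pairing-ordered
    for mate_order in (list(reversed(mate)), mate):
        pairs = [DuplexPosition(r, m) for r, m in zip(ref, mate_order)]
        if complementarity(pairs) >= 0.6:
            return pairs
    raise StructureError(
        "strand pairing is not Watson-Crick complementary in either "
        "orientation")


def _min_dist_to_set(coords: np.ndarray, tree: cKDTree) -> float:
    if coords.size == 0:
        return np.inf
    d, _ = tree.query(coords)
    return float(np.min(d))


def contacting_positions(s: StructureModel, cutoff: float = 4.5,
                         protein_chains: set[str] | None = None) -> list[int]:
    """Duplex positions with a heavy atom within ``cutoff`` of the protein.

    A contact on either strand marks the base-pair position; positions are
    returned 5'->3' on the reference strand (0-based).
    """
    prot = [a for a in s.protein_atoms
            if protein_chains is None or a.chain_id in protein_chains]
    if not prot:
        return []
    pairs = duplex_positions(s)
    if not pairs:
        return []
    tree = cKDTree(np.array([a.xyz for a in prot]))
    out = []
    for i, pos in enumerate(pairs):
        coords = pos.ref.heavy_coords()
        if pos.mate is not None:
            mate_coords = pos.mate.heavy_coords()
            if mate_coords.size:
                coords = (np.vstack([coords, mate_coords])
                          if coords.size else mate_coords)
        if _min_dist_to_set(coords, tree) <= cutoff:
            out.append(i)
    return out


def interface_residues(c: CuratedComplex | StructureModel,
                       cutoff: float = 4.5) -> set[tuple[str, int]]:
    """Protein residues with a heavy atom within ``cutoff`` of any DNA atom."""
    if isinstance(c, CuratedComplex):
        prot, dna = c.protein_atoms, c.dna_atoms
    else:
        prot, dna = c.protein_atoms, c.dna_atoms
    dna_coords = np.array([a.xyz for a in dna if a.is_heavy])
    if dna_coords.size == 0:
        return set()
    tree = cKDTree(dna_coords)
    out: set[tuple[str, int]] = set()
    for res in group_residues(a for a in prot if a.is_heavy):
        if _min_dist_to_set(res.heavy_coords(), tree) <= cutoff:
            out.add(res.residue_id)
    return out


# ---------------------------------------------------------------------------
# curation

def _check_base_complete(res: Residue) -> None:
    letter = res.base_letter
    if letter not in CANONICAL_BASES:
        raise CurationError(
            f"non-canonical base {res.residue_name} at {res.residue_id}")
    names = {a.name for a in res.atoms if a.is_heavy}
    missing = BASE_ATOM_NAMES[letter] - names
    if missing:
        raise CurationError(
            f"base {letter} at {res.residue_id} is missing heavy atoms: "
            f"{sorted(missing)}")


def curate_complex(s: StructureModel, p: CurationParams | None = None,
                   protein_chains: set[str] | None = None) -> CuratedComplex:
    """Apply the curation filters and trim DNA to the contacting stretch.

    The retained stretch is the contiguous span from the first to the last
    contacting base-pair position (interior non-contacting bases are kept: a
    duplex with holes is not threadable). ``protein_chains`` restricts the TF
    unit to a subset of protein chains, e.g. to split crystallographic
    multimers; by default every protein chain in the file is one TF unit.
    """
    p = p or CurationParams()
    prot = [a for a in s.protein_atoms
            if protein_chains is None or a.chain_id in protein_chains]
    if not prot:
        raise StructureError("no protein atoms")
    if not s.dna_atoms:
        raise StructureError("no DNA atoms")
    if s.resolution is not None and s.resolution > p.resolution_max:
        raise CurationError(
            f"resolution {s.resolution:.2f} A exceeds the "
            f"{p.resolution_max:.2f} A curation limit")
    contacts = contacting_positions(s, p.contact_cutoff, protein_chains)
    if not contacts:
        raise CurationError("no interface: no protein-DNA atom pair within "
                            f"{p.contact_cutoff} A")
    first, last = contacts[0], contacts[-1]
    k = last - first + 1
    if k > p.k_max:
        raise CurationError(
            f"motif too long: {k} contacted base pairs exceed k_max={p.k_max}")
    pairs = duplex_positions(s)[first:last + 1]
    for pos in pairs:
        _check_base_complete(pos.ref)
        if pos.mate is not None:
            _check_base_complete(pos.mate)
    native = "".join(pos.ref.base_letter for pos in pairs)

    waters: list[Atom] = []
    if p.keep_interface_waters:
        dna_coords = np.array([a.xyz for pos in pairs for a in
                               (pos.ref.atoms + (pos.mate.atoms if pos.mate
                                                 else [])) if a.is_heavy])
        prot_tree = cKDTree(np.array([a.xyz for a in prot if a.is_heavy]))
        dna_tree = cKDTree(dna_coords)
        for res in group_residues(a for a in s.atoms
                                  if a.record_class == "water"):
            coords = res.heavy_coords()
            if (coords.size
                    and _min_dist_to_set(coords, prot_tree) <= p.contact_cutoff
                    and _min_dist_to_set(coords, dna_tree) <= p.contact_cutoff):
                waters.extend(res.atoms)

    curated = CuratedComplex(
        protein_atoms=prot,
        duplex=pairs,
        water_atoms=waters,
        contacting_positions=[i - first for i in contacts],
        interface_residue_ids=set(),
        native_sequence=native,
        identifier=s.identifier,
        resolution=s.resolution,
    )
    curated.interface_residue_ids = interface_residues(curated, p.contact_cutoff)
    return curated


# ---------------------------------------------------------------------------
# serialization

def _atom_record(a: Atom) -> dict:
    d = asdict(a)
    d["xyz"] = [float(x) for x in a.xyz]
    return d


def curated_to_json(c: CuratedComplex) -> str:
    payload = {
        "identifier": c.identifier,
        "resolution": c.resolution,
        "k": c.k,
        "native_sequence": c.native_sequence,
        "contacting_positions": c.contacting_positions,
        "interface_residue_ids": sorted(list(r) for r in c.interface_residue_ids),
        "protein_atoms": [_atom_record(a) for a in c.protein_atoms],
        "water_atoms": [_atom_record(a) for a in c.water_atoms],
        "duplex": [
            {
                "ref": [_atom_record(a) for a in pos.ref.atoms],
                "mate": ([_atom_record(a) for a in pos.mate.atoms]
                         if pos.mate is not None else None),
            }
            for pos in c.duplex
        ],
    }
    return json.dumps(payload, indent=1)


def curated_from_json(text: str) -> CuratedComplex:
    payload = json.loads(text)

    def atoms(records: list[dict]) -> list[Atom]:
        return [Atom(**{**r, "xyz": np.array(r["xyz"])}) for r in records]

    def residue(records: list[dict]) -> Residue:
        ats = atoms(records)
        return Residue(ats[0].chain_id, ats[0].residue_index,
                       ats[0].residue_name, ats)

    duplex = [
        DuplexPosition(residue(pos["ref"]),
                       residue(pos["mate"]) if pos["mate"] else None)
        for pos in payload["duplex"]
    ]
    return CuratedComplex(
        protein_atoms=atoms(payload["protein_atoms"]),
        duplex=duplex,
        water_atoms=atoms(payload["water_atoms"]),
        contacting_positions=list(payload["contacting_positions"]),
        interface_residue_ids={tuple(r) for r in
                               payload["interface_residue_ids"]},
        native_sequence=payload["native_sequence"],
        identifier=payload.get("identifier", ""),
        resolution=payload.get("resolution"),
    )


# ---------------------------------------------------------------------------
# sequence redundancy removal

def _pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / length of the shorter sequence."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(a, b)[0]
    matches = sum(
        x == y
        for x, y in zip(str(aln[0]), str(aln[1]))
        if x != "-" and y != "-"
    )
    return matches / min(len(a), len(b))


def greedy_cluster_sequences(seqs: Sequence[str],
                             identity: float = 0.90) -> list[str]:
    """Greedy longest-first redundancy removal (cd-hit style stand-in).

    Sequences are sorted longest first; each joins the first existing cluster
    whose representative it matches at or above the identity threshold,
    otherwise it founds a new cluster. Returns the representatives.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    reps: list[str] = []
    for seq in sorted(seqs, key=lambda s: (-len(s), s)):
        if not any(_pairwise_identity(seq, rep) >= identity for rep in reps):
            reps.append(seq)
    return reps
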