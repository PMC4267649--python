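"""Idealized nucleobase geometry and rigid-body fitting.

Base templates are planar heavy-atom models built analytically: rings are
regular polygons with 1.39 A sides, exocyclic substituents sit on the radial
direction of the atom they attach to. Every template lives in a canonical
local frame with the glycosidic nitrogen (N9 for purines, N1 for pyrimidines)
at the origin, the base in the z=0 plane, and the ring system extending
towards +x. Bases are placed into a structure by a proper rigid
(Kabsch) superposition of the anchor triad -- the glycosidic nitrogen and its
two bonded ring carbons -- which is the set of atoms retained when a base is
stripped during threading.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: anchor triad atom names, in correspondence order (glycosidic N, then its
#: two bonded ring carbons).  Purine<->pyrimidine swaps map positionally:
#: N9<->N1, C8<->C6, C4<->C2, preserving the glycosidic direction.
ANCHOR_TRIADS = {
    "A": ("N9", "C8", "C4"),
    "G": ("N9", "C8", "C4"),
    "C": ("N1", "C6", "C2"),
    "T": ("N1", "C6", "C2"),
}

_RING_SIDE = 1.39  # A, aromatic C-C/C-N
_BOND_N = 1.35  # A, exocyclic C-N
_BOND_O = 1.23  # A, exocyclic C=O
_BOND_C = 1.50  # A, exocyclic C-CH3


def _regular_ring(n: int, start: np.ndarray, heading: np.ndarray,
                  turn_sign: float) -> np.ndarray:
    """Vertices of a regular n-gon walked edge by edge from ``start``."""
    ext = turn_sign * 2.0 * np.pi / n
    rot = np.array([[np.cos(ext), -np.sin(ext)], [np.sin(ext), np.cos(ext)]])
    pts = [np.asarray(start, dtype=float)]
    h = np.asarray(heading, dtype=float)
    h = h / np.linalg.norm(h)
    for _ in range(n - 1):
        pts.append(pts[-1] + _RING_SIDE * h)
        h = rot @ h
    return np.array(pts)


def _radial(ring: dict[str, np.ndarray], center: np.ndarray, atom: str,
            bond: float) -> np.ndarray:
    d = ring[atom] - center
    return ring[atom] + bond * d / np.linalg.norm(d)


def _pyrimidine_ring() -> dict[str, np.ndarray]:
    # ring order N1-C2-N3-C4-C5-C6; N1 at origin, ring towards +x
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    pts = _regular_ring(6, np.zeros(2), np.array([0.5, -np.sqrt(3) / 2]), 1.0)
    return dict(zip(names, pts))


def _purine_rings() -> dict[str, np.ndarray]:
    # pentagon N9-C8-N7-C5-C4 with N9 at origin, then hexagon fused on C4-C5
    names5 = ["N9", "C8", "N7", "C5", "C4"]
    pent = dict(zip(names5, _regular_ring(
        5, np.zeros(2), np.array([0.5, np.sqrt(3) / 2]), -1.0)))
    # hexagon ring order C5-C4-N3-C2-N1-C6, walked from C5 towards C4
    names6 = ["C5", "C4", "N3", "C2", "N1", "C6"]
    heading = pent["C4"] - pent["C5"]
    hexa = dict(zip(names6, _regular_ring(6, pent["C5"], heading, 1.0)))
    # the fused hexagon must extend away from the pentagon
    c5 = np.mean(list(pent.values()), axis=0)
    c6 = np.mean([hexa[n] for n in names6], axis=0)
    if np.linalg.norm(c6 - c5) < 1.5:  # folded back onto the pentagon
        hexa = dict(zip(names6, _regular_ring(6, pent["C5"], heading, -1.0)))
    out = dict(pent)
    out.update({k: v for k, v in hexa.items() if k not in out})
    return out


def _canonical_frame(coords: dict[str, np.ndarray],
                     glyco: str) -> dict[str, np.ndarray]:
    """Translate glycosidic N to origin, rotate centroid onto +x, embed z=0."""
    arr = {k: v - coords[glyco] for k, v in coords.items()}
    centroid = np.mean(list(arr.values()), axis=0)
    ang = -np.arctan2(centroid[1], centroid[0])
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    arr = {k: rot @ v for k, v in arr.items()}
    # fix chirality: first triad carbon on the +y side
    cplus = "C8" if glyco == "N9" else "C6"
    if arr[cplus][1] < 0:
        arr = {k: v * np.array([1.0, -1.0]) for k, v in arr.items()}
    return {k: np.array([v[0], v[1], 0.0]) for k, v in arr.items()}


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    pyr = _pyrimidine_ring()
    pyr_center = np.mean(list(pyr.values()), axis=0)
    pur = _purine_rings()
    hex_names = ["C5", "C4", "N3", "C2", "N1", "C6"]
    pur_hex_center = np.mean([pur[n] for n in hex_names], axis=0)

    cyt = dict(pyr)
    cyt["O2"] = _radial(pyr, pyr_center, "C2", _BOND_O)
    cyt["N4"] = _radial(pyr, pyr_center, "C4", _BOND_N)

    thy = dict(pyr)
    thy["O2"] = _radial(pyr, pyr_center, "C2", _BOND_O)
    thy["O4"] = _radial(pyr, pyr_center, "C4", _BOND_O)
    thy["C7"] = _radial(pyr, pyr_center, "C5", _BOND_C)

    ade = dict(pur)
    ade["N6"] = _radial(pur, pur_hex_center, "C6", _BOND_N)

    gua = dict(pur)
    gua["O6"] = _radial(pur, pur_hex_center, "C6", _BOND_O)
    gua["N2"] = _radial(pur, pur_hex_center, "C2", _BOND_N)

    return {
        "A": _canonical_frame(ade, "N9"),
        "G": _canonical_frame(gua, "N9"),
        "C": _canonical_frame(cyt, "N1"),
        "T": _canonical_frame(thy, "N1"),
    }


#: base letter -> {atom name -> xyz in the canonical local frame}
BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = _build_templates()

#: heavy atoms constituting each base (ring + exocyclic), by letter
BASE_ATOM_NAMES: dict[str, frozenset[str]] = {
    b: frozenset(t) for b, t in BASE_TEMPLATES.items()
}


def base_extent(base: str) -> float:
    """Largest distance of any base atom from the glycosidic nitrogen."""
    return float(max(np.linalg.norm(v) for v in BASE_TEMPLATES[base].values()))


def kabsch_fit(mobile: np.ndarray, target: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rigid fit of ``mobile`` points onto ``target``.

    Returns ``(R, t)`` with ``R @ x + t`` mapping mobile coordinates into the
    target frame; ``R`` is a proper rotation (det +1, reflections excluded).

    Raises
    ------
    GeometryError
        If either point set is (near-)collinear, which leaves the rotation
        about the common axis undetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("point sets must be matching (n, 3) arrays")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    pm = mobile - mc
    pt = target - tc
    for pts, which in ((pm, "mobile"), (pt, "target")):
        # collinearity: all cross products of the centered points ~ 0
        s = np.linalg.svd(pts, compute_uv=False)
        if len(s) < 2 or s[1] < 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"{which} points are collinear or degenerate")
    h = pm.T @ pt
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def fit_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after the best proper rigid superposition."""
    rot, trans = kabsch_fit(mobile, target)
    moved = (rot @ np.asarray(mobile, float).T).T + trans
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
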