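"""Distance queries, superposition, symmetry expansion and polar contacts.

Everything here is exact: neighbor-search acceleration (scipy KD-trees) is
used only to prune candidates, never to change a minimum.  Distances are kept
in double precision internally and rounded to one decimal only at the report
layer, matching crystallographic convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure_io import (
    AtomRecord,
    CrystalCell,
    StructureModel,
    coords,
)

POLAR_ELEMENTS = frozenset({"N", "O"})

# charged-group atoms used for the salt-bridge label (basic vs acidic)
BASIC_ATOMS = frozenset({("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE")})
ACIDIC_ATOMS = frozenset({("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")})


@dataclass(frozen=True)
class ContactRecord:
    atom_A: str
    atom_B: str
    distance: float
    kind: str  # salt_bridge | hydrogen_bond | metal_metal | generic

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


# ---------------------------------------------------------------------------
# Minimum-distance queries
# ---------------------------------------------------------------------------

def _min_pair(sel1: Sequence[AtomRecord], sel2: Sequence[AtomRecord]):
    """Exact minimum distance and its atom pair, ties broken by lowest serials."""
    s1 = sorted(sel1, key=lambda a: a.serial)
    s2 = sorted(sel2, key=lambda a: a.serial)
    x1, x2 = coords(s1), coords(s2)
    if len(s1) * len(s2) <= 250_000:
        d = cdist(x1, x2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        return float(d[i, j]), s1[i], s2[j]
    # prune with a KD-tree, then resolve ties exactly
    tree = cKDTree(x2)
    dmin, _ = tree.query(x1, k=1)
    best = float(dmin.min())
    cand = np.where(dmin <= best + 1e-9)[0]
    best_pair = None
    best_d = np.inf
    for i in cand:
        js = tree.query_ball_point(x1[i], best + 1e-9)
        for j in sorted(js):
            dij = float(np.linalg.norm(x1[i] - x2[j]))
            if dij < best_d - 1e-12:
                best_d, best_pair = dij, (s1[i], s2[j])
    assert best_pair is not None
    return best_d, best_pair[0], best_pair[1]


def min_atom_distance(sel1: Sequence[AtomRecord], sel2: Sequence[AtomRecord]):
    """Minimum inter-selection atom distance (Å) and the realizing pair."""
    if not sel1 or not sel2:
        raise ValueError("min_atom_distance: empty selection")
    d, a1, a2 = _min_pair(sel1, sel2)
    return d, (a1, a2)


def min_interchain_ca_distance(
    atoms_A: Sequence[AtomRecord], atoms_B: Sequence[AtomRecord]
):
    """Shortest Cα–Cα distance between two protein selections.

    This is the headline "span" metric of an interface: values near 5 Å mean
    backbone-to-backbone packing, values around 8 Å leave room for a solvent
    layer between the main chains.
    """
    ca_A = [a for a in atoms_A if a.name == "CA" and a.element == "C"]
    ca_B = [a for a in atoms_B if a.name == "CA" and a.element == "C"]
    if not ca_A or not ca_B:
        raise ValueError("min_interchain_ca_distance: a selection has no Cα atoms")
    d, (a1, a2) = min_atom_distance(ca_A, ca_B)
    return d, (a1.residue_id, a2.residue_id)


# ---------------------------------------------------------------------------
# Polar-contact inventory
# ---------------------------------------------------------------------------

def _is_charged_pair(a: AtomRecord, b: AtomRecord) -> bool:
    ka, kb = (a.resname, a.name), (b.resname, b.name)
    return (ka in BASIC_ATOMS and kb in ACIDIC_ATOMS) or (
        ka in ACIDIC_ATOMS and kb in BASIC_ATOMS
    )


def polar_contact_inventory(
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    max_dist: float = 3.5,
) -> list[ContactRecord]:
    """All inter-protein N/O–N/O pairs within ``max_dist`` Å, sorted by distance.

    A pair is labeled ``salt_bridge`` when both atoms belong to charged side
    chain groups (Lys NZ / Arg NH,NE vs Asp OD / Glu OE), ``hydrogen_bond``
    otherwise.  The label never changes the distance.
    """
    if not atoms_A or not atoms_B:
        raise ValueError("polar_contact_inventory: empty selection")
    pol_A = [a for a in atoms_A if a.element in POLAR_ELEMENTS]
    pol_B = [b for b in atoms_B if b.element in POLAR_ELEMENTS]
    out: list[ContactRecord] = []
    if pol_A and pol_B:
        d = cdist(coords(pol_A), coords(pol_B))
        for i, j in zip(*np.where(d <= max_dist)):
            a, b = pol_A[i], pol_B[j]
            kind = "salt_bridge" if _is_charged_pair(a, b) else "hydrogen_bond"
            out.append(ContactRecord(a.atom_id, b.atom_id, float(d[i, j]), kind))
    out.sort(key=lambda c: (c.distance, c.atom_A, c.atom_B))
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_P: np.ndarray, coords_Q: np.ndarray):
    """Least-squares rigid superposition of P onto Q (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` with ``rotation @ p + translation``
    the transformed P.  The rotation is always proper (det = +1); reflections
    are corrected by flipping the smallest singular direction.
    """
    P = np.asarray(coords_P, dtype=float)
    Q = np.asarray(coords_Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired points")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cP, Q - cQ
    # degenerate (collinear / coincident) inputs have rank < 2
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) coordinates; superposition undefined")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = (Pc @ R.T) - Qc
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def match_ca_by_resseq(
    atoms_P: Sequence[AtomRecord], atoms_Q: Sequence[AtomRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Pair Cα atoms by residue number over the common range (gaps dropped)."""
    ca_P = {a.resseq: a for a in atoms_P if a.name == "CA" and a.element == "C"}
    ca_Q = {a.resseq: a for a in atoms_Q if a.name == "CA" and a.element == "C"}
    common = sorted(set(ca_P) & set(ca_Q))
    if len(common) < 3:
        raise ValueError("fewer than 3 matched Cα residues")
    P = np.array([ca_P[r].xyz for r in common])
    Q = np.array([ca_Q[r].xyz for r in common])
    return P, Q


# ---------------------------------------------------------------------------
# Crystal symmetry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymImage:
    """One symmetry image of the whole model near the ASU."""

    op_triplet: str
    shift: tuple[int, int, int]
    coords: np.ndarray  # same atom order as model.atoms


def _all_images(model: StructureModel, shift_range: int = 1):
    cell = model.require_cell()
    orth, frac = cell.orth, cell.frac
    xyz = coords(model.atoms)
    fxyz = xyz @ frac.T
    shifts = itertools.product(*[range(-shift_range, shift_range + 1)] * 3)
    for shift in shifts:
        for op in cell.symops:
            if op.is_identity and shift == (0, 0, 0):
                continue
            img_frac = op.apply(fxyz) + np.asarray(shift, dtype=float)
            yield SymImage(op.triplet, tuple(shift), img_frac @ orth.T)


def symmetry_expand(model: StructureModel, shell: float) -> list[SymImage]:
    """Symmetry images (ops × lattice translations) near the ASU.

    An image is kept when at least one of its atoms falls inside the ASU
    bounding box padded by ``shell`` Å.  The identity image is excluded.
    Translations span one cell in each direction, which covers every image
    that can approach the ASU for any physically meaningful shell.
    """
    xyz = coords(model.atoms)
    lo, hi = xyz.min(axis=0) - shell, xyz.max(axis=0) + shell
    kept = []
    for img in _all_images(model):
        inside = np.all((img.coords >= lo) & (img.coords <= hi), axis=1)
        if inside.any():
            kept.append(img)
    return kept


def closest_symmetry_contact(model: StructureModel, sel: Sequence[AtomRecord]) -> float:
    """Minimum distance (Å) from ``sel`` to any symmetry image of the model."""
    if not sel:
        raise ValueError("closest_symmetry_contact: empty selection")
    model.require_cell()
    x = coords(sel)
    tree = cKDTree(x)
    best = np.inf
    for img in _all_images(model):
        d, _ = tree.query(img.coords, k=1)
        best = min(best, float(d.min()))
    return best
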