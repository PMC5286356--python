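"""Seeded toy complexes with ground-truth analytics.

The generator builds a miniature analogue of a water-mediated electron
transfer interface: two pseudo-helical chains (N, CA, C, O, CB atoms only)
facing each other across a controlled gap, with waters planted at exact
distances that realize each requested category (bridging, one-sided,
non-interacting), a B-factor field that grows linearly with distance from
designated anchor atoms, and a valid monoclinic P2_1 cell.  Every placement
is verified against the exact distance criteria *after* coordinates are
rounded to PDB precision, so the emitted file and the stored truth can never
disagree.

Geometry note: a water bridging both chains needs d_A + d_B >= gap with both
below the 3.5 Å cutoff, so bridging waters require gap < 7 Å; non-interacting
waters (both distances in (3.5, 7]) remain feasible slightly below 7 Å by
sitting off the closest-approach axis.  The default gap of 6.0 Å makes all
four categories realizable at once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .structure_io import (
    AtomRecord,
    CrystalCell,
    StructureModel,
    SymOp,
    coords,
    write_pdb,
)
from .geometry import POLAR_ELEMENTS

CATEGORY_ORDER = ("bridging", "nonbridging_A", "nonbridging_B", "noninteracting")

#: margin (Å) kept clear of every category boundary; PDB coordinates are
#: rounded to 3 decimals, which can move a distance by at most ~0.003 Å
BOUNDARY_MARGIN = 0.08
MIN_WATER_PROTEIN = 2.4
MIN_WATER_WATER = 2.3
MAX_ATTEMPTS = 10_000


class InfeasiblePlacementError(RuntimeError):
    """Requested water layout cannot be realized for this chain geometry."""


@dataclass
class ToyComplexTruth:
    """A generated toy complex plus everything the pipeline should recover."""

    model: StructureModel
    water_truth: dict[str, str]  # water atom id -> intended category
    hbond_truth: set[tuple[str, str]]  # intended H-bond edges (sorted id pairs)
    anchor_atoms: list[str]
    planted_b_slope: float
    base_b: float
    noise_sd: float
    gap: float
    cell: CrystalCell
    seed: int

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORY_ORDER}
        for cat in self.water_truth.values():
            out[cat] += 1
        return out

    def write(self, pdb_path: str | Path, truth_path: str | Path | None = None) -> None:
        write_pdb(self.model, pdb_path)
        if truth_path is not None:
            payload = {
                "seed": self.seed,
                "gap": self.gap,
                "planted_b_slope": self.planted_b_slope,
                "water_truth": self.water_truth,
                "hbond_truth": sorted(list(e) for e in self.hbond_truth),
                "anchor_atoms": self.anchor_atoms,
            }
            Path(truth_path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

_RISE = 1.5  # Å per residue along the helical axis
_TWIST = math.radians(100.0)
_CA_RADIUS = 2.3


def _round3(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float), 3)


def _helix_chain(n_res: int, chain_id: str, flip: bool) -> list[dict]:
    """Pseudo-helical backbone+CB chain along z; CB points radially outward.

    ``flip`` mirrors the chain through the y-z plane so that two copies can
    face each other CB-to-CB across the x axis.
    """
    atoms: list[dict] = []
    for i in range(n_res):
        t = _TWIST * i
        z = _RISE * i
        u = np.array([math.cos(t), math.sin(t), 0.0])  # radial
        v = np.array([-math.sin(t), math.cos(t), 0.0])  # tangential
        w = np.array([0.0, 0.0, 1.0])
        ca = _CA_RADIUS * u + z * w
        local = {
            "N": ca - 0.3 * u - 1.2 * v - 0.7 * w,
            "CA": ca,
            "C": ca - 0.3 * u + 1.2 * v + 0.8 * w,
            "O": ca - 0.1 * u + 1.6 * v + 1.95 * w,
            "CB": ca + 1.53 * u,
        }
        for name in ("N", "CA", "C", "O", "CB"):
            p = local[name].copy()
            if flip:
                p[0] = -p[0]
            atoms.append(
                {
                    "name": name,
                    "element": name[0],
                    "chain": chain_id,
                    "resseq": i + 1,
                    "resname": "ALA",
                    "xyz": p,
                }
            )
    return atoms


def _min_gap(xa: np.ndarray, xb: np.ndarray, shift: float) -> float:
    from scipy.spatial.distance import cdist

    return float(cdist(xa, xb + np.array([shift, 0.0, 0.0])).min())


# ---------------------------------------------------------------------------
# Water placement
# ---------------------------------------------------------------------------

def _category_ok(cat: str, da: float, db: float, cutoff: float, shell: float) -> bool:
    m = BOUNDARY_MARGIN
    lo = MIN_WATER_PROTEIN
    if cat == "bridging":
        return lo <= da <= cutoff - m and lo <= db <= cutoff - m
    if cat == "nonbridging_A":
        return lo <= da <= cutoff - m and cutoff + m <= db <= shell - m
    if cat == "nonbridging_B":
        return lo <= db <= cutoff - m and cutoff + m <= da <= shell - m
    if cat == "noninteracting":
        return (cutoff + m <= da <= shell - m) and (cutoff + m <= db <= shell - m)
    raise ValueError(cat)


def _place_water(
    cat: str,
    rng: np.random.Generator,
    xa: np.ndarray,
    xb: np.ndarray,
    placed: list[np.ndarray],
    cutoff: float,
    shell: float,
) -> np.ndarray:
    """Rejection-sample one water satisfying the exact category constraints."""
    from scipy.spatial.distance import cdist

    # seed positions around the closest-approach region
    d_ab = cdist(xa, xb)
    i0, j0 = np.unravel_index(np.argmin(d_ab), d_ab.shape)
    # A atoms close enough to B that a midpoint water can touch both sides
    near_a = np.where(d_ab.min(axis=1) <= 2 * (cutoff - BOUNDARY_MARGIN) - 0.1)[0]
    for _ in range(MAX_ATTEMPTS):
        if cat == "bridging":
            if len(near_a) == 0:
                break
            i = int(rng.choice(near_a))
            j = int(np.argmin(((xb - xa[i]) ** 2).sum(axis=1)))
            t = rng.uniform(0.4, 0.6)
            base = (1 - t) * xa[i] + t * xb[j]
            p = base + rng.uniform(-0.35, 0.35, 3)
        elif cat == "nonbridging_A":
            i = int(rng.integers(len(xa)))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p = xa[i] + rng.uniform(MIN_WATER_PROTEIN, cutoff - BOUNDARY_MARGIN) * direction
        elif cat == "nonbridging_B":
            j = int(rng.integers(len(xb)))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p = xb[j] + rng.uniform(MIN_WATER_PROTEIN, cutoff - BOUNDARY_MARGIN) * direction
        else:  # noninteracting
            base = 0.5 * (xa[i0] + xb[j0])
            p = base + rng.uniform(-3.5, 3.5, 3)
        p = _round3(p)
        da = float(np.sqrt(((xa - p) ** 2).sum(axis=1).min()))
        db = float(np.sqrt(((xb - p) ** 2).sum(axis=1).min()))
        if not _category_ok(cat, da, db, cutoff, shell):
            continue
        if placed and min(float(np.linalg.norm(p - q)) for q in placed) < MIN_WATER_WATER:
            continue
        return p
    raise InfeasiblePlacementError(
        f"could not place a {cat!r} water after {MAX_ATTEMPTS} attempts "
        f"(gap/cutoff/shell geometry may be infeasible)"
    )


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def make_toy_complex(
    n_res_A: int = 14,
    n_res_B: int = 14,
    n_waters_per_class: Sequence[int] = (3, 4, 4, 3),
    gap: float = 6.0,
    b_slope: float = 2.0,
    seed: int = 0,
    base_b: float = 30.0,
    noise_sd: float = 2.0,
    cutoff: float = 3.5,
    shell: float = 7.0,
) -> ToyComplexTruth:
    """Build a two-chain toy complex with known water categories.

    ``n_waters_per_class`` orders counts as (bridging, nonbridging_A,
    nonbridging_B, noninteracting).  Chain A carries the planted B-factor
    gradient ``b_slope`` (Å²/Å) away from its anchor atoms (the two CB atoms
    closest to chain B) plus Gaussian noise of SD ``noise_sd``.
    Regenerating with the same seed reproduces byte-identical output.
    """
    if min(n_res_A, n_res_B) < 1:
        raise ValueError("chain sizes must be >= 1")
    counts = tuple(int(n) for n in n_waters_per_class)
    if len(counts) != 4 or min(counts) < 0:
        raise ValueError("n_waters_per_class must be 4 non-negative integers")
    if counts[0] > 0 and gap >= 2 * cutoff:
        raise InfeasiblePlacementError(
            f"bridging waters need gap < {2 * cutoff:.1f} Å (got gap={gap})"
        )
    rng = np.random.default_rng(seed)

    raw_a = _helix_chain(n_res_A, "A", flip=False)
    raw_b = _helix_chain(n_res_B, "B", flip=True)
    xa = np.array([a["xyz"] for a in raw_a])
    xb = np.array([b["xyz"] for b in raw_b])
    # translate chain B along +x until the closest-approach distance equals gap
    lo_s, hi_s = 0.0, 60.0
    while _min_gap(xa, xb, hi_s) < gap:
        hi_s *= 2
    shift = brentq(lambda s: _min_gap(xa, xb, s) - gap, lo_s, hi_s, xtol=1e-6)
    xb = xb + np.array([shift, 0.0, 0.0])
    xa, xb = _round3(xa), _round3(xb)
    for rec, p in zip(raw_a, xa):
        rec["xyz"] = p
    for rec, p in zip(raw_b, xb):
        rec["xyz"] = p

    # waters, category by category in fixed order
    water_positions: list[np.ndarray] = []
    water_cats: list[str] = []
    for cat, n in zip(CATEGORY_ORDER, counts):
        for _ in range(n):
            p = _place_water(cat, rng, xa, xb, water_positions, cutoff, shell)
            water_positions.append(p)
            water_cats.append(cat)

    # anchors: chain-A CB atoms closest to chain B
    cb_idx = [k for k, a in enumerate(raw_a) if a["name"] == "CB"]
    d_to_b = [float(np.sqrt(((xb - xa[k]) ** 2).sum(axis=1).min())) for k in cb_idx]
    anchor_idx = [cb_idx[k] for k in np.argsort(d_to_b)[:2]]
    anchor_xyz = xa[anchor_idx]

    # B-factors: planted gradient on chain A, flat chain B, broad waters
    atoms: list[AtomRecord] = []
    serial = 0

    def _add(rec: dict, bfac: float, is_water: bool) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial,
                name=rec["name"],
                element=rec["element"],
                altloc="",
                resname=rec["resname"],
                chain=rec["chain"],
                resseq=rec["resseq"],
                icode="",
                xyz=tuple(rec["xyz"]),
                occupancy=1.0,
                bfactor=round(max(float(bfac), 1.0), 2),
                is_water=is_water,
                is_hetero=is_water,
            )
        )

    for rec in raw_a:
        d_anchor = float(np.sqrt(((anchor_xyz - rec["xyz"]) ** 2).sum(axis=1).min()))
        _add(rec, base_b + b_slope * d_anchor + rng.normal(0.0, noise_sd), False)
    for rec in raw_b:
        _add(rec, 25.0 + rng.normal(0.0, 1.0), False)
    for k, (p, _cat) in enumerate(zip(water_positions, water_cats)):
        rec = {
            "name": "O",
            "element": "O",
            "chain": "W",
            "resseq": k + 1,
            "resname": "HOH",
            "xyz": p,
        }
        _add(rec, 45.0 + rng.normal(0.0, 8.0), True)

    # P2_1 cell comfortably enclosing the complex
    all_xyz = np.array([a.xyz for a in atoms])
    extent = all_xyz.max(axis=0) - all_xyz.min(axis=0)
    identity = SymOp(rot=tuple(map(tuple, np.eye(3))), tran=(0.0, 0.0, 0.0), triplet="x,y,z")
    screw = SymOp(
        rot=((-1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, -1.0)),
        tran=(0.0, 0.5, 0.0),
        triplet="-x,y+1/2,-z",
    )
    cell = CrystalCell(
        a=round(extent[0] + 25.0, 3),
        b=round(extent[1] + 25.0, 3),
        c=round(extent[2] + 25.0, 3),
        alpha=90.0,
        beta=102.0,
        gamma=90.0,
        spacegroup="P 1 21 1",
        symops=(identity, screw),
    )
    model = StructureModel(atoms=atoms, cell=cell, source_id=f"toy-seed{seed}")

    waters = [a for a in atoms if a.is_water]
    water_truth = {w.atom_id: cat for w, cat in zip(waters, water_cats)}

    # intended H-bond edges by exhaustive double loop (< 3.5 Å heavy-atom)
    hbond_truth: set[tuple[str, str]] = set()
    protein_polar = [a for a in atoms if not a.is_water and a.element in POLAR_ELEMENTS]
    for i, w in enumerate(waters):
        for v in waters[i + 1:]:
            if np.linalg.norm(np.subtract(w.xyz, v.xyz)) < cutoff:
                hbond_truth.add(tuple(sorted((w.atom_id, v.atom_id))))
        for p_at in protein_polar:
            if np.linalg.norm(np.subtract(w.xyz, p_at.xyz)) < cutoff:
                hbond_truth.add(tuple(sorted((w.atom_id, p_at.atom_id))))

    return ToyComplexTruth(
        model=model,
        water_truth=water_truth,
        hbond_truth=hbond_truth,
        anchor_atoms=[atoms[i].atom_id for i in anchor_idx],
        planted_b_slope=b_slope,
        base_b=base_b,
        noise_sd=noise_sd,
        gap=gap,
        cell=cell,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Coupling-graph cases
# ---------------------------------------------------------------------------

@dataclass
class ToyCouplingCase:
    """A tiny structure whose best tunneling path is known by hand."""

    model: StructureModel
    covalent_bonds: list[tuple[str, str]]
    donor: str
    acceptor: str
    expected_nodes: tuple[str, ...]
    expected_T_DA: float


def _case_atoms(positions: np.ndarray) -> list[AtomRecord]:
    atoms = []
    for k, p in enumerate(_round3(positions)):
        atoms.append(
            AtomRecord(
                serial=k + 1,
                name=f"C{k + 1}",
                element="C",
                altloc="",
                resname="TOY",
                chain="X",
                resseq=k + 1,
                icode="",
                xyz=tuple(p),
                occupancy=1.0,
                bfactor=10.0,
                is_water=False,
                is_hetero=True,
            )
        )
    return atoms


def make_toy_coupling_case(topology: str = "linear4", seed: int = 0):
    """Small structures with hand-computable best tunneling paths.

    Presets:

    * ``linear4`` — four atoms in a covalent chain; T_DA = 0.6**3 = 0.216.
    * ``y_shortcut`` — a five-atom covalent arc whose ends approach to 2.0 Å;
      the single through-space jump (eps = 0.6 e^{-1.7*0.6}) beats the
      four-bond covalent route (0.6**4).
    * ``eq_space`` — two non-bonded atoms exactly at the 1.4 Å through-space
      equilibrium distance; eps equals the 0.6 prefactor.

    ``seed`` is accepted for API symmetry; the presets are deterministic.
    """
    from .et_pathways import PathwaysParams

    params = PathwaysParams()
    if topology == "linear4":
        pos = np.array([[1.5 * k, 0.0, 0.0] for k in range(4)])
        atoms = _case_atoms(pos)
        ids = [a.atom_id for a in atoms]
        bonds = [(ids[k], ids[k + 1]) for k in range(3)]
        return ToyCouplingCase(
            model=StructureModel(atoms=atoms, source_id="toy-linear4"),
            covalent_bonds=bonds,
            donor=ids[0],
            acceptor=ids[-1],
            expected_nodes=tuple(ids),
            expected_T_DA=params.eps_covalent**3,
        )
    if topology == "y_shortcut":
        # five points on a circular arc: consecutive chords 1.5 Å, end chord 2.0 Å
        def end_chord(rc: float) -> float:
            theta = 2.0 * math.asin(0.75 / rc)
            return 2.0 * rc * math.sin(2.0 * theta) - 2.0

        rc = brentq(end_chord, 1.31, 1.45, xtol=1e-9)
        theta = 2.0 * math.asin(0.75 / rc)
        pos = np.array(
            [[rc * math.cos(k * theta), rc * math.sin(k * theta), 0.0] for k in range(5)]
        )
        atoms = _case_atoms(pos)
        ids = [a.atom_id for a in atoms]
        bonds = [(ids[k], ids[k + 1]) for k in range(4)]
        d_end = float(np.linalg.norm(np.subtract(atoms[0].xyz, atoms[4].xyz)))
        return ToyCouplingCase(
            model=StructureModel(atoms=atoms, source_id="toy-y-shortcut"),
            covalent_bonds=bonds,
            donor=ids[0],
            acceptor=ids[4],
            expected_nodes=(ids[0], ids[4]),
            expected_T_DA=params.eps_space(d_end),
        )
    if topology == "eq_space":
        pos = np.array([[0.0, 0.0, 0.0], [params.space_equilibrium, 0.0, 0.0]])
        atoms = _case_atoms(pos)
        ids = [a.atom_id for a in atoms]
        return ToyCouplingCase(
            model=StructureModel(atoms=atoms, source_id="toy-eq-space"),
            covalent_bonds=[],
            donor=ids[0],
            acceptor=ids[1],
            expected_nodes=tuple(ids),
            expected_T_DA=params.space_prefactor,
        )
    raise ValueError(f"unknown topology preset {topology!r}")


def random_coupling_graph(n_nodes: int, seed: int, edge_prob: float = 0.4):
    """Random abstract coupling graph for oracle testing of the path search."""
    from .et_pathways import CouplingGraph, PathwaysParams
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    names = [f"n{k:02d}" for k in range(n_nodes)]
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                eps = float(rng.uniform(0.05, 0.9))
                g.add_edge(
                    names[i], names[j],
                    kind="space", eps=eps, R=float(rng.uniform(1.5, 5.0)),
                    weight=-math.log(eps),
                )
    return CouplingGraph(graph=g, atoms={}, params=PathwaysParams())
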