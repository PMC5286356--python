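"""Classification of interfacial waters and their hydrogen-bond network.

At a "soft" protein-protein interface the two partners stay far enough apart
that ordered waters persist between them.  Waters within a two-sided shell
(default 7 Å of *both* proteins) are sorted into four categories by the
distance from the water oxygen to the nearest protein atom (default
cutoff 3.5 Å, strict ``<``):

* ``bridging`` — interacts with both proteins,
* ``nonbridging_A`` / ``nonbridging_B`` — interacts with one side only,
* ``noninteracting`` — interacts with neither (boundary equality 3.5 Å
  counts as non-interacting).

Hydrogen bonds are heavy-atom distance criteria only: deposited waters carry
no hydrogens and no angle term is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, coords
from .geometry import POLAR_ELEMENTS

NONPOLAR_ELEMENTS = frozenset({"C", "S"})

CATEGORIES = ("bridging", "nonbridging_A", "nonbridging_B", "noninteracting")


@dataclass
class WaterClass:
    """Per-water classification record."""

    water_id: str
    category: str
    d_min_A: float
    d_min_B: float
    n_polar_contacts: int = 0
    n_nonpolar_contacts: int = 0
    n_water_contacts: int = 0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown water category {self.category!r}")
        if min(self.n_polar_contacts, self.n_nonpolar_contacts, self.n_water_contacts) < 0:
            raise ValueError("contact counts must be non-negative")


@dataclass
class WaterCensus:
    """Aggregate water bookkeeping for one complex."""

    records: list[WaterClass]
    shell: float
    cutoff: float

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for r in self.records:
            out[r.category] += 1
        return out

    @property
    def n_interface(self) -> int:
        return len(self.records)


@dataclass
class HBondNetwork:
    """Water/protein-polar-atom hydrogen-bond graph.

    Nodes are water ids plus protein polar atom ids (tagged with their side);
    edges are heavy-atom pairs within the H-bond cutoff.
    """

    graph: nx.Graph
    cutoff: float

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def water_degree(self, water_id: str) -> int:
        return self.graph.degree(water_id) if water_id in self.graph else 0

    @property
    def connects_A_to_B(self) -> bool:
        """True when some path of H-bonds links an A-side polar atom to a B-side one."""
        a_nodes = [n for n, d in self.graph.nodes(data=True) if d.get("side") == "A"]
        b_nodes = {n for n, d in self.graph.nodes(data=True) if d.get("side") == "B"}
        if not a_nodes or not b_nodes:
            return False
        for comp in nx.connected_components(self.graph):
            if comp & set(a_nodes) and comp & b_nodes:
                return True
        return False


def _water_oxygens(waters: Sequence[AtomRecord]) -> list[AtomRecord]:
    """Each water is represented by its O atom for all distance criteria."""
    return [w for w in waters if w.element == "O"]


def _dmin_to(sel_coords: np.ndarray, pts: np.ndarray) -> np.ndarray:
    tree = cKDTree(sel_coords)
    d, _ = tree.query(pts, k=1)
    return np.asarray(d, dtype=float)


def select_interface_waters(
    waters: Sequence[AtomRecord],
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    shell: float = 7.0,
) -> list[AtomRecord]:
    """Waters whose O atom lies within ``shell`` Å of both proteins."""
    if not atoms_A or not atoms_B:
        raise ValueError("select_interface_waters: empty protein selection")
    ox = _water_oxygens(waters)
    if not ox:
        return []
    pts = coords(ox)
    dA = _dmin_to(coords(atoms_A), pts)
    dB = _dmin_to(coords(atoms_B), pts)
    keep = (dA <= shell) & (dB <= shell)
    return [w for w, k in zip(ox, keep) if k]


def classify_waters(
    interface_waters: Sequence[AtomRecord],
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    cutoff: float = 3.5,
) -> list[WaterClass]:
    """Assign each interface water to exactly one of the four categories.

    ``bridging`` iff d_min_A < cutoff and d_min_B < cutoff; one-sided
    interaction gives ``nonbridging_A``/``nonbridging_B``; otherwise
    ``noninteracting``.  The partition is exhaustive and exclusive by
    construction.
    """
    if not interface_waters:
        return []
    pts = coords(list(interface_waters))
    dA = _dmin_to(coords(atoms_A), pts)
    dB = _dmin_to(coords(atoms_B), pts)
    out: list[WaterClass] = []
    for w, da, db in zip(interface_waters, dA, dB):
        near_a, near_b = da < cutoff, db < cutoff
        if near_a and near_b:
            cat = "bridging"
        elif near_a:
            cat = "nonbridging_A"
        elif near_b:
            cat = "nonbridging_B"
        else:
            cat = "noninteracting"
        out.append(
            WaterClass(
                water_id=w.atom_id,
                category=cat,
                d_min_A=float(da),
                d_min_B=float(db),
                bfactor=w.bfactor,
            )
        )
    return out


def water_contact_profile(
    wc: Sequence[WaterClass],
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    waters: Sequence[AtomRecord],
    cutoff: float = 3.5,
    nonpolar_cutoff: float | None = None,
) -> dict:
    """Per-water contact counts and per-category aggregates.

    For each classified water, counts protein polar atoms (N/O), protein
    non-polar atoms (C/S) and other water O atoms within the cutoff, and
    tallies which residue types the water-protein polar contacts involve on
    each side.  The records in ``wc`` are updated in place.
    """
    npc = cutoff if nonpolar_cutoff is None else nonpolar_cutoff
    ox = _water_oxygens(waters)
    by_id = {w.atom_id: w for w in ox}
    prot = list(atoms_A) + list(atoms_B)
    side = ["A"] * len(atoms_A) + ["B"] * len(atoms_B)
    pxyz = coords(prot)
    ptree = cKDTree(pxyz) if len(prot) else None
    wxyz = coords(ox)
    wtree = cKDTree(wxyz) if len(ox) else None

    residue_tally: dict[str, dict[str, int]] = {"A": {}, "B": {}}
    for rec in wc:
        w = by_id.get(rec.water_id)
        if w is None:
            raise KeyError(f"classified water {rec.water_id} not among supplied waters")
        p0 = np.asarray(w.xyz)
        n_pol = n_np = 0
        if ptree is not None:
            for j in ptree.query_ball_point(p0, max(cutoff, npc)):
                d = float(np.linalg.norm(pxyz[j] - p0))
                el = prot[j].element
                if el in POLAR_ELEMENTS and d < cutoff:
                    n_pol += 1
                    tally = residue_tally[side[j]]
                    tally[prot[j].resname] = tally.get(prot[j].resname, 0) + 1
                elif el in NONPOLAR_ELEMENTS and d < npc:
                    n_np += 1
        n_wat = 0
        if wtree is not None:
            for j in wtree.query_ball_point(p0, cutoff):
                if ox[j].atom_id != rec.water_id and float(np.linalg.norm(wxyz[j] - p0)) < cutoff:
                    n_wat += 1
        rec.n_polar_contacts = n_pol
        rec.n_nonpolar_contacts = n_np
        rec.n_water_contacts = n_wat

    def _mean(vals: list[float]) -> float | None:
        return float(np.mean(vals)) if vals else None

    per_cat: dict[str, dict] = {}
    for cat in CATEGORIES:
        rs = [r for r in wc if r.category == cat]
        per_cat[cat] = {
            "n": len(rs),
            "mean_polar_or_water": _mean([r.n_polar_contacts + r.n_water_contacts for r in rs]),
            "mean_nonpolar": _mean([r.n_nonpolar_contacts for r in rs]),
        }
    interacting = [r for r in wc if r.category != "noninteracting"]
    return {
        "per_category": per_cat,
        "interacting_mean_polar_or_water": _mean(
            [r.n_polar_contacts + r.n_water_contacts for r in interacting]
        ),
        "interacting_mean_nonpolar": _mean([r.n_nonpolar_contacts for r in interacting]),
        "residue_tally": residue_tally,
    }


def build_hbond_network(
    wc: Sequence[WaterClass],
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    waters: Sequence[AtomRecord],
    hb_cutoff: float = 3.5,
) -> HBondNetwork:
    """Hydrogen-bond graph over interface waters and protein polar atoms.

    Edges join water-O/water-O and water-O/protein-N,O pairs within
    ``hb_cutoff``.  Every classified water appears as a node even if isolated.
    """
    g = nx.Graph()
    ox = {w.atom_id: w for w in _water_oxygens(waters)}
    wlist = [ox[rec.water_id] for rec in wc]
    for rec in wlist:
        g.add_node(rec.atom_id, kind="water")
    pol = [(a, "A") for a in atoms_A if a.element in POLAR_ELEMENTS] + [
        (b, "B") for b in atoms_B if b.element in POLAR_ELEMENTS
    ]
    if wlist:
        wxyz = coords(wlist)
        wtree = cKDTree(wxyz)
        # water-water edges
        for i, j in sorted(wtree.query_pairs(hb_cutoff)):
            g.add_edge(
                wlist[i].atom_id,
                wlist[j].atom_id,
                distance=float(np.linalg.norm(wxyz[i] - wxyz[j])),
                kind="water-water",
            )
        # water-protein edges
        if pol:
            pxyz = np.array([a.xyz for a, _ in pol])
            for j, (atom, side_tag) in enumerate(pol):
                for i in wtree.query_ball_point(pxyz[j], hb_cutoff):
                    if atom.atom_id not in g:
                        g.add_node(atom.atom_id, kind="protein", side=side_tag)
                    g.add_edge(
                        wlist[i].atom_id,
                        atom.atom_id,
                        distance=float(np.linalg.norm(wxyz[i] - pxyz[j])),
                        kind="water-protein",
                    )
    return HBondNetwork(graph=g, cutoff=hb_cutoff)


def water_bfactor_stats(wc: Sequence[WaterClass]) -> dict:
    """Mean water B-factor per category plus the overall mean.

    Empty categories report ``None`` (absent), never 0.
    """
    out: dict[str, float | None] = {}
    for cat in CATEGORIES:
        vals = [r.bfactor for r in wc if r.category == cat]
        out[cat] = float(np.mean(vals)) if vals else None
    out["overall"] = float(np.mean([r.bfactor for r in wc])) if wc else None
    return out


def water_census(
    waters: Sequence[AtomRecord],
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    shell: float = 7.0,
    cutoff: float = 3.5,
) -> WaterCensus:
    """Shell selection followed by classification, as one call."""
    interface = select_interface_waters(waters, atoms_A, atoms_B, shell=shell)
    records = classify_waters(interface, atoms_A, atoms_B, cutoff=cutoff)
    return WaterCensus(records=records, shell=shell, cutoff=cutoff)
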