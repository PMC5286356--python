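"""Empirical electron-tunneling pathway search (Pathways-style coupling).

The tunneling coupling of a donor-to-acceptor route through a protein is
modeled as a product of per-step decay factors eps in (0, 1]:

* covalent bond:      eps_C = 0.6 (distance independent),
* hydrogen bond:      eps_H = 0.36 * exp[-1.7 (R - 2.8)],
* through-space jump: eps_S = 0.6  * exp[-1.7 (R - 1.4)],

with R the heavy-atom distance in Å and each exponential clamped at its
contact value (exponent floored at 0), so decay is monotone beyond the
equilibrium distance and eps never exceeds its prefactor.  Hydrogens are not
modeled as graph nodes; H-bond steps connect the heavy donor/acceptor atoms
directly, with the 2.8 Å equilibrium calibrated for heavy-atom separations.

The best route maximizes the product of eps, found exactly as a shortest
path under edge weight -ln(eps); candidate diversity comes from Yen-style
enumeration of the k best simple paths.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, coords
from .geometry import POLAR_ELEMENTS

#: single-bond covalent radii (Å) used for automatic bond perception
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "FE": 1.32, "CU": 1.32, "ZN": 1.22, "MG": 1.41, "NA": 1.66,
}
BOND_TOLERANCE = 0.45  # Å beyond the covalent-radii sum


@dataclass(frozen=True)
class PathwaysParams:
    """Decay-law parameters; the standard empirical parameterization."""

    eps_covalent: float = 0.6
    hb_prefactor: float = 0.36
    space_prefactor: float = 0.6
    decay: float = 1.7  # 1/Å
    hb_equilibrium: float = 2.8  # Å, heavy-atom
    space_equilibrium: float = 1.4  # Å

    def eps_hbond(self, R: float) -> float:
        return self.hb_prefactor * math.exp(-self.decay * max(R - self.hb_equilibrium, 0.0))

    def eps_space(self, R: float) -> float:
        return self.space_prefactor * math.exp(
            -self.decay * max(R - self.space_equilibrium, 0.0)
        )


@dataclass
class CouplingGraph:
    """Atom-node graph with per-edge decay factors.

    ``graph`` is an undirected networkx graph whose nodes are qualified atom
    ids and whose edges carry ``kind`` (covalent/hbond/space), ``R`` (Å),
    ``eps`` and ``weight`` = -ln(eps).
    """

    graph: nx.Graph
    atoms: dict[str, AtomRecord]
    params: PathwaysParams

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge(self, u: str, v: str) -> dict:
        return self.graph.edges[u, v]


@dataclass
class ETPath:
    """A simple donor->acceptor path with its total coupling."""

    nodes: tuple[str, ...]
    edges: list[dict]  # per-step {u, v, kind, R, eps}
    T_DA: float

    def __post_init__(self) -> None:
        if not (0.0 < self.T_DA <= 1.0):
            raise ValueError(f"T_DA {self.T_DA} outside (0, 1]")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path is not simple")

    @property
    def running_distance(self) -> float:
        return float(sum(e["R"] for e in self.edges))

    @property
    def jumps(self) -> list[dict]:
        """Non-covalent steps (H-bond and through-space) with distances."""
        return [e for e in self.edges if e["kind"] != "covalent"]


# ---------------------------------------------------------------------------
# Bond patches
# ---------------------------------------------------------------------------

def load_bond_patches(path=None) -> list[tuple[str, str, str, str, float]]:
    """Read extra covalent bonds from a patch table.

    Format: whitespace-separated columns ``resname1 atom1 resname2 atom2
    max_dist``, '#' comments allowed.  Defaults to the packaged table, which
    covers heme/metal-site linkages not reachable by covalent-radii
    perception.
    """
    if path is None:
        text = resources.files("softcontact").joinpath("data/bond_patches.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        r1, a1, r2, a2, dmax = line.split()
        out.append((r1, a1, r2, a2, float(dmax)))
    return out


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _auto_covalent_pairs(atoms: Sequence[AtomRecord], xyz: np.ndarray) -> set[tuple[int, int]]:
    rcov = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    cutoff = 2 * rcov.max() + BOND_TOLERANCE
    tree = cKDTree(xyz)
    pairs: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(cutoff):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if 0.0 < d <= rcov[i] + rcov[j] + BOND_TOLERANCE:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def _patch_pairs(
    atoms: Sequence[AtomRecord],
    xyz: np.ndarray,
    patches: Iterable[tuple[str, str, str, str, float]],
) -> set[tuple[int, int]]:
    by_key: dict[tuple[str, str], list[int]] = {}
    for idx, a in enumerate(atoms):
        by_key.setdefault((a.resname, a.name), []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for r1, a1, r2, a2, dmax in patches:
        for i in by_key.get((r1, a1), ()):
            for j in by_key.get((r2, a2), ()):
                if i != j and np.linalg.norm(xyz[i] - xyz[j]) <= dmax:
                    pairs.add((min(i, j), max(i, j)))
    return pairs


def build_coupling_graph(
    atoms: Sequence[AtomRecord],
    hb_cutoff: float = 3.5,
    space_cutoff: float = 5.0,
    params: PathwaysParams | None = None,
    covalent: str | Iterable[tuple[str, str]] = "auto",
    bond_patches: Iterable[tuple[str, str, str, str, float]] | None = None,
) -> CouplingGraph:
    """Build the tunneling graph over a heavy-atom selection.

    Covalent edges come from distance perception against covalent radii
    (``covalent="auto"``) or an explicit list of qualified-atom-id pairs,
    plus the bond-patch table (heme thioether links, Fe/Cu ligations).
    Remaining N/O-N/O pairs within ``hb_cutoff`` become H-bond edges; any
    other pair within ``space_cutoff`` becomes a through-space edge.
    """
    params = params or PathwaysParams()
    atoms = list(atoms)
    if not atoms:
        raise ValueError("build_coupling_graph: empty selection")
    xyz = coords(atoms)
    ids = [a.atom_id for a in atoms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate atom ids in selection")

    if covalent == "auto":
        cov_pairs = _auto_covalent_pairs(atoms, xyz)
        patches = load_bond_patches() if bond_patches is None else list(bond_patches)
        cov_pairs |= _patch_pairs(atoms, xyz, patches)
    else:
        index = {aid: k for k, aid in enumerate(ids)}
        cov_pairs = set()
        for u, v in covalent:  # type: ignore[union-attr]
            i, j = index[u], index[v]
            cov_pairs.add((min(i, j), max(i, j)))
        if bond_patches:
            cov_pairs |= _patch_pairs(atoms, xyz, bond_patches)

    g = nx.Graph()
    for aid in ids:
        g.add_node(aid)

    def _add(i: int, j: int, kind: str, eps: float, R: float) -> None:
        g.add_edge(ids[i], ids[j], kind=kind, eps=eps, R=R, weight=-math.log(eps))

    for i, j in sorted(cov_pairs):
        _add(i, j, "covalent", params.eps_covalent, float(np.linalg.norm(xyz[i] - xyz[j])))

    tree = cKDTree(xyz)
    for i, j in sorted(tree.query_pairs(max(hb_cutoff, space_cutoff))):
        if g.has_edge(ids[i], ids[j]):
            continue
        R = float(np.linalg.norm(xyz[i] - xyz[j]))
        polar = atoms[i].element in POLAR_ELEMENTS and atoms[j].element in POLAR_ELEMENTS
        same_res = atoms[i].residue_id == atoms[j].residue_id
        if polar and not same_res and R <= hb_cutoff:
            _add(i, j, "hbond", params.eps_hbond(R), R)
        elif R <= space_cutoff:
            _add(i, j, "space", params.eps_space(R), R)

    return CouplingGraph(graph=g, atoms=dict(zip(ids, atoms)), params=params)


# ---------------------------------------------------------------------------
# Path search
# ---------------------------------------------------------------------------

def _path_from_nodes(g: CouplingGraph, nodes: Sequence[str]) -> ETPath:
    edges = []
    t_da = 1.0
    for u, v in zip(nodes, nodes[1:]):
        data = g.graph.edges[u, v]
        edges.append({"u": u, "v": v, "kind": data["kind"], "R": data["R"], "eps": data["eps"]})
        t_da *= data["eps"]
    return ETPath(nodes=tuple(nodes), edges=edges, T_DA=t_da)


def best_path(g: CouplingGraph, donor: str, acceptor: str) -> ETPath | None:
    """Maximum-coupling path; ``None`` when donor and acceptor are disconnected.

    Dijkstra on -ln(eps) with a deterministic tie break: among equal-coupling
    routes the lexicographically smallest node sequence wins.
    """
    for node in (donor, acceptor):
        if node not in g.graph:
            raise KeyError(f"node {node!r} not in coupling graph")
    if donor == acceptor:
        raise ValueError("donor and acceptor coincide")
    # label-setting search on the composite key (distance, node sequence)
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (donor,))]
    done: set[str] = set()
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == acceptor:
            return _path_from_nodes(g, path)
        for nbr, data in sorted(g.graph[node].items()):
            if nbr not in done:
                heapq.heappush(heap, (dist + data["weight"], path + (nbr,)))
    return None


def k_best_paths(g: CouplingGraph, donor: str, acceptor: str, k: int = 200) -> list[ETPath]:
    """The ``k`` strongest-coupling simple paths, in non-increasing T_DA order.

    Yen-style enumeration (networkx ``shortest_simple_paths``) on the
    -ln(eps) weights; fewer paths are returned when fewer exist.
    """
    for node in (donor, acceptor):
        if node not in g.graph:
            raise KeyError(f"node {node!r} not in coupling graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[ETPath] = []
    try:
        gen = nx.shortest_simple_paths(g.graph, donor, acceptor, weight="weight")
        for nodes in gen:
            out.append(_path_from_nodes(g, nodes))
            if len(out) >= k:
                break
    except nx.NetworkXNoPath:
        return []
    out.sort(key=lambda p: (-p.T_DA, p.nodes))
    return out


def path_metrics(p: ETPath) -> tuple[float, list[dict]]:
    """Running distance (sum of step lengths, Å) and the non-covalent jumps."""
    return p.running_distance, p.jumps
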