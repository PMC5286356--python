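"""Macromolecular structure I/O and the uniform atomic data model.

Parsing of mmCIF/PDB files is delegated to :mod:`gemmi`; this module flattens
the hierarchy into a plain list of :class:`AtomRecord` objects plus crystal
metadata (:class:`CrystalCell`), which is what every downstream analysis
consumes.  A :class:`ComplexSpec` names which chains form the electron-donor
protein (side *A*, e.g. cytochrome *c*), which form the acceptor (side *B*,
e.g. cytochrome *c* oxidase), and where the redox cofactors sit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import yaml

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

#: altloc codes kept for all geometric analyses: the blank (single-conformer)
#: code plus conformer "A".  Crystal structures with alternate conformations
#: report one set of distances; we follow the highest-priority conformer.
DEFAULT_ALTLOCS = ("", "A")


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read in the named dialect."""


class NoCellError(ValueError):
    """Raised when an operation requires crystal symmetry but the model has none."""


class ConfigurationError(ValueError):
    """Raised when a ComplexSpec does not resolve against a model."""


class SelectorError(KeyError):
    """Raised when an atom selector is missing or ambiguous."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of a crystallographic model (isotropic B only)."""

    serial: int
    name: str
    element: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    xyz: tuple[float, float, float]
    occupancy: float
    bfactor: float
    is_water: bool
    is_hetero: bool

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name!r}: empty element")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(
                f"atom {self.serial} {self.name!r}: occupancy {self.occupancy} outside [0, 1]"
            )
        if not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"atom {self.serial} {self.name!r}: non-finite coordinates")

    @property
    def atom_id(self) -> str:
        """Qualified id ``chain/resname resseq[icode]/name`` used in reports."""
        ic = self.icode.strip()
        return f"{self.chain}/{self.resname}{self.resseq}{ic}/{self.name}"

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


@dataclass(frozen=True)
class SymOp:
    """Affine symmetry operator in fractional coordinates."""

    rot: tuple[tuple[float, float, float], ...]
    tran: tuple[float, float, float]
    triplet: str = ""

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return frac @ np.asarray(self.rot).T + np.asarray(self.tran)

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.rot, np.eye(3)) and np.allclose(self.tran, 0.0)
        )


@dataclass(frozen=True)
class CrystalCell:
    """Unit cell plus the spacegroup operator list (identity included)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    spacegroup: str
    symops: tuple[SymOp, ...]

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError(f"cell angle {ang} outside (0, 180)")
        if not self.symops:
            raise ValueError("symops must be non-empty")
        if not any(op.is_identity for op in self.symops):
            raise ValueError("symops must include the identity")

    @property
    def orth(self) -> np.ndarray:
        """Fractional -> cartesian matrix (standard PDB convention)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        cos_al, cos_be, cos_ga = np.cos([al, be, ga])
        sin_ga = np.sin(ga)
        v = math.sqrt(
            1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
        )
        return np.array(
            [
                [self.a, self.b * cos_ga, self.c * cos_be],
                [0.0, self.b * sin_ga, self.c * (cos_al - cos_be * cos_ga) / sin_ga],
                [0.0, 0.0, self.c * v / sin_ga],
            ]
        )

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)


@dataclass
class StructureModel:
    """Parsed structure: flat atom list, optional cell, provenance label."""

    atoms: list[AtomRecord]
    cell: CrystalCell | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        keys = [(a.chain, a.resseq, a.icode, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom key {k}")
                seen.add(k)

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain not in out:
                out.append(a.chain)
        return out

    def require_cell(self) -> CrystalCell:
        if self.cell is None:
            raise NoCellError(f"model {self.source_id!r} carries no crystal cell")
        return self.cell


def coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Nx3 cartesian coordinate array for a selection."""
    if not atoms:
        return np.empty((0, 3))
    return np.array([a.xyz for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_DIALECT_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}


def _cell_from_gemmi(st: gemmi.Structure) -> CrystalCell | None:
    cell = st.cell
    if not cell.is_crystal() or cell.volume <= 0:
        return None
    hm = st.spacegroup_hm or "P 1"
    sg = gemmi.find_spacegroup_by_name(hm)
    ops: list[SymOp] = []
    if sg is not None:
        for op in sg.operations():
            seitz = np.array(op.float_seitz())
            ops.append(
                SymOp(
                    rot=tuple(map(tuple, seitz[:3, :3])),
                    tran=tuple(seitz[:3, 3]),
                    triplet=op.triplet(),
                )
            )
    if not ops:
        ops = [SymOp(rot=tuple(map(tuple, np.eye(3))), tran=(0.0, 0.0, 0.0), triplet="x,y,z")]
    return CrystalCell(
        a=cell.a, b=cell.b, c=cell.c,
        alpha=cell.alpha, beta=cell.beta, gamma=cell.gamma,
        spacegroup=hm, symops=tuple(ops),
    )


def read_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records are retained (waters, altlocs included);
    anisotropic displacement entries are reduced to the stored isotropic B.
    ``dialect`` forces the parser ("pdb" or "mmcif"); by default the format
    is detected from the file contents/extension.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = gemmi.CoorFormat.Detect
    if dialect is not None:
        try:
            fmt = _DIALECT_FORMATS[dialect.lower()]
        except KeyError:
            raise ValueError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    serial = 0
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no model")
    model = st[0]
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_RESNAMES or res.is_water()
            is_het = res.het_flag == "H"
            for at in res:
                serial += 1
                altloc = "" if at.altloc in ("\0", " ", "") else at.altloc
                atoms.append(
                    AtomRecord(
                        serial=at.serial if at.serial > 0 else serial,
                        name=at.name,
                        element=at.element.name.upper(),
                        altloc=altloc,
                        resname=res.name,
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        bfactor=at.b_iso,
                        is_water=is_water,
                        is_hetero=is_het,
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path}: no atoms found")
    return StructureModel(atoms=atoms, cell=_cell_from_gemmi(st), source_id=path.stem)


# ---------------------------------------------------------------------------
# Writing (PDB)
# ---------------------------------------------------------------------------

def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (via gemmi; deterministic output)."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    if model.cell is not None:
        c = model.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        st.spacegroup_hm = c.spacegroup
    gmodel = gemmi.Model("1")
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain, []).append(a)
    for chain_name, chain_atoms in by_chain.items():
        gchain = gemmi.Chain(chain_name)
        current_key: tuple | None = None
        gres: gemmi.Residue | None = None
        for a in chain_atoms:
            key = (a.resseq, a.icode, a.resname)
            if key != current_key:
                gres = gemmi.Residue()
                gres.name = a.resname
                gres.seqid = gemmi.SeqId(a.resseq, a.icode if a.icode else " ")
                gres.het_flag = "H" if (a.is_hetero or a.is_water) else "A"
                gres = gchain.add_residue(gres)  # gemmi copies; keep the live ref
                current_key = key
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element.capitalize())
            gat.altloc = a.altloc if a.altloc else "\0"
            gat.pos = gemmi.Position(*a.xyz)
            gat.occ = a.occupancy
            gat.b_iso = a.bfactor
            gat.serial = a.serial
            assert gres is not None
            gres.add_atom(gat)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Complex specification & selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexSpec:
    """Which chains constitute one biological complex inside a file.

    ``cofactors_A`` / ``cofactors_B`` map a cofactor label (e.g. ``"heme_c"``,
    ``"CuA"``) to a residue selection: a list of ``[chain, resseq]`` pairs or a
    residue-name string matched within that side's chains.  ``donor_atom`` and
    ``acceptor_atom`` are ``chain:resseq:atomname`` selectors used by the
    electron-tunneling search.
    """

    chains_A: tuple[str, ...]
    chains_B: tuple[str, ...]
    water_mode: str = "auto"  # "auto": any residue named HOH/WAT anywhere
    cofactors_A: Mapping[str, object] = field(default_factory=dict)
    cofactors_B: Mapping[str, object] = field(default_factory=dict)
    donor_atom: str | None = None
    acceptor_atom: str | None = None

    def __post_init__(self) -> None:
        if set(self.chains_A) & set(self.chains_B):
            raise ConfigurationError(
                f"chains_A and chains_B overlap: {set(self.chains_A) & set(self.chains_B)}"
            )
        if not self.chains_A or not self.chains_B:
            raise ConfigurationError("both chains_A and chains_B must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ComplexSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ComplexSpec":
        return cls(
            chains_A=tuple(raw["chains_A"]),
            chains_B=tuple(raw["chains_B"]),
            water_mode=raw.get("water_mode", "auto"),
            cofactors_A=dict(raw.get("cofactors_A", {})),
            cofactors_B=dict(raw.get("cofactors_B", {})),
            donor_atom=raw.get("donor_atom"),
            acceptor_atom=raw.get("acceptor_atom"),
        )

    def to_dict(self) -> dict:
        return {
            "chains_A": list(self.chains_A),
            "chains_B": list(self.chains_B),
            "water_mode": self.water_mode,
            "cofactors_A": dict(self.cofactors_A),
            "cofactors_B": dict(self.cofactors_B),
            "donor_atom": self.donor_atom,
            "acceptor_atom": self.acceptor_atom,
        }


@dataclass
class ComplexSelection:
    """Disjoint atom selections for one complex."""

    atoms_A: list[AtomRecord]
    atoms_B: list[AtomRecord]
    waters: list[AtomRecord]
    cofactors: dict[str, list[AtomRecord]]


def _match_cofactor(atoms: Sequence[AtomRecord], sel: object) -> list[AtomRecord]:
    if isinstance(sel, str):
        return [a for a in atoms if a.resname == sel]
    out: list[AtomRecord] = []
    for item in sel:  # type: ignore[union-attr]
        ch, resseq = item[0], int(item[1])
        out.extend(a for a in atoms if a.chain == ch and a.resseq == resseq)
    return out


def select_complex(
    model: StructureModel,
    spec: ComplexSpec,
    altlocs: Sequence[str] = DEFAULT_ALTLOCS,
) -> ComplexSelection:
    """Partition the model into side-A atoms, side-B atoms and waters.

    Protein selections include hetero cofactor residues on their chains
    (hemes, metal sites); waters are pulled out of every chain by residue
    name.  Only the altloc codes in ``altlocs`` are kept.
    """
    present = set(model.chains())
    for ch in (*spec.chains_A, *spec.chains_B):
        if ch not in present:
            raise ConfigurationError(
                f"chain {ch!r} not in model {model.source_id!r} (has {sorted(present)})"
            )
    keep = [a for a in model.atoms if a.altloc in altlocs]
    waters = [a for a in keep if a.is_water]
    atoms_A = [a for a in keep if a.chain in spec.chains_A and not a.is_water]
    atoms_B = [a for a in keep if a.chain in spec.chains_B and not a.is_water]
    for label, sel in (("A", atoms_A), ("B", atoms_B)):
        if not sel:
            raise ConfigurationError(f"empty protein selection for side {label}")
    cof: dict[str, list[AtomRecord]] = {}
    for name, rule in spec.cofactors_A.items():
        cof[name] = _match_cofactor(atoms_A, rule)
    for name, rule in spec.cofactors_B.items():
        cof[name] = _match_cofactor(atoms_B, rule)
    for name, sel in cof.items():
        if not sel:
            raise ConfigurationError(f"cofactor {name!r} matched no atoms")
    return ComplexSelection(atoms_A=atoms_A, atoms_B=atoms_B, waters=waters, cofactors=cof)


def resolve_atom(atoms: Iterable[AtomRecord], selector: str) -> AtomRecord:
    """Resolve a ``chain:resseq:atomname`` selector to exactly one atom."""
    try:
        chain, resseq_s, name = selector.split(":")
        resseq = int(resseq_s)
    except ValueError:
        raise SelectorError(f"malformed selector {selector!r}; want 'chain:resseq:name'")
    hits = [a for a in atoms if a.chain == chain and a.resseq == resseq and a.name == name]
    if not hits:
        raise SelectorError(f"selector {selector!r} matched no atom")
    if len(hits) > 1:
        raise SelectorError(f"selector {selector!r} ambiguous ({len(hits)} atoms)")
    return hits[0]
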