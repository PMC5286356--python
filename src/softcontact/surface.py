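"""Solvent-accessible surface area (Shrake-Rupley) and contact surface area.

The SASA integrator is written here on purpose rather than delegated: each
atom is inflated by the probe radius (default 1.4 Å, a water-sized probe) and
sampled with a deterministic golden-section spiral point set; a sample point
is accessible iff it lies outside every neighbor's inflated sphere.  With the
default 960 points per atom, totals are converged well below 1% on
protein-sized inputs and bit-stable for a fixed ``n_points``.

The contact surface area (CSA) of a complex is the area buried on
complexation.  Two conventions circulate; the default here is half the total
buried area, CSA = (SASA(A) + SASA(B) - SASA(A+B)) / 2, with the full-ΔASA
alternative exposed via ``convention="full"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import AtomRecord, coords

#: van der Waals radii (Å) by element.  The set is deliberately small and
#: explicit; an element outside it is an error, never a silent default.
DEFAULT_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "FE": 1.40,
    "CU": 1.40,
    "ZN": 1.40,
    "MG": 1.40,
    "NA": 1.40,
}


class UnknownElementError(KeyError):
    pass


@dataclass
class SasaResult:
    per_atom_area: np.ndarray  # Å² per atom, same order as the input selection
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom_area.sum())


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (golden-section spiral).

    Deterministic for fixed ``n``, so every SASA number is reproducible
    bit-for-bit.
    """
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: Sequence[AtomRecord], radii: Mapping[str, float]) -> np.ndarray:
    out = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        try:
            out[k] = radii[a.element]
        except KeyError:
            raise UnknownElementError(
                f"no van der Waals radius for element {a.element!r} "
                f"(atom {a.atom_id}); extend the radii table explicitly"
            )
    return out


def sasa(
    atoms: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley numerical SASA of a selection."""
    if not atoms:
        raise ValueError("sasa: empty selection")
    rad = _radii_for(atoms, radii or DEFAULT_RADII) + probe
    xyz = coords(atoms)
    pts = sphere_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()
    per_atom = np.zeros(len(atoms))
    for i in range(len(atoms)):
        sphere = xyz[i] + rad[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], max_reach):
            if j == i:
                continue
            d2 = ((sphere - xyz[j]) ** 2).sum(axis=1)
            accessible &= d2 > rad[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = 4.0 * np.pi * rad[i] ** 2 * accessible.sum() / n_points
    return SasaResult(per_atom_area=per_atom, probe_radius=probe, n_points=n_points)


def contact_surface_area(
    atoms_A: Sequence[AtomRecord],
    atoms_B: Sequence[AtomRecord],
    probe: float = 1.4,
    n_points: int = 960,
    radii: Mapping[str, float] | None = None,
    convention: str = "half",
) -> float:
    """Contact surface area (Å²) between two protein selections.

    Solvent must be excluded by the caller (waters in either selection raise);
    hetero cofactors belong to their protein and stay in.  ``convention`` is
    ``"half"`` (ΔASA/2, default) or ``"full"`` (ΔASA).
    """
    if convention not in ("half", "full"):
        raise ValueError(f"unknown CSA convention {convention!r}")
    for label, sel in (("A", atoms_A), ("B", atoms_B)):
        if any(a.is_water for a in sel):
            raise ValueError(f"selection {label} still contains waters; strip solvent first")
    serials_A = {a.serial for a in atoms_A}
    if serials_A & {b.serial for b in atoms_B}:
        raise ValueError("selections A and B share atom serials")
    kw = dict(probe=probe, n_points=n_points, radii=radii)
    buried = (
        sasa(atoms_A, **kw).total
        + sasa(atoms_B, **kw).total
        - sasa(list(atoms_A) + list(atoms_B), **kw).total
    )
    buried = max(buried, 0.0)  # guard against sampling noise for distant pairs
    return buried / 2.0 if convention == "half" else buried
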