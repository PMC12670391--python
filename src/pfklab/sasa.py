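"""Solvent-accessible surface area by Shrake-Rupley spherical quadrature,
and relative SASA against per-residue-type fully-exposed reference maxima.

Each particle is inflated by the probe radius (water, 0.14 nm) and covered
with a deterministic golden-spiral point set; the accessible fraction is
the fraction of points outside every neighboring inflated sphere.  rSASA
divides a residue's area by the reference value for a fully exposed
residue of that type, clamped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import BeadStructure
from .tables import MAX_SASA_TABLES, VDW_RADII_NM, bead_radius_for_type

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS_NM = 0.14
DEFAULT_N_QUADRATURE_POINTS = 960


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([
        np.sin(phi) * np.cos(theta),
        np.sin(phi) * np.sin(theta),
        np.cos(phi),
    ])


def assign_radii(structure: BeadStructure,
                 mode: str = "auto",
                 bead_radius_table: dict[str, float] | None = None
                 ) -> BeadStructure:
    """Fill in particle radii.

    ``mode='atomistic'`` uses element van der Waals radii inferred from
    atom names; ``mode='cg'`` uses the per-bead-type table (half the LJ
    sigma of the bead size class by default); ``'auto'`` picks atomistic
    when names look like atom names (contain an element letter followed
    by locants, e.g. CA, OD1) and all residues are standard.
    """
    out = structure.subset(np.arange(structure.n_particles))
    if mode == "auto":
        names = {str(n).upper() for n in structure.names}
        mode = "cg" if names & {"BB", "SC1", "SC2", "SC3", "SC4"} else "atomistic"
    radii = np.empty(structure.n_particles)
    if mode == "atomistic":
        for i, name in enumerate(structure.names):
            elem = _element_from_name(str(name))
            if elem not in VDW_RADII_NM:
                raise KeyError(
                    f"no van der Waals radius for particle {name!r} "
                    f"(element guess {elem!r})"
                )
            radii[i] = VDW_RADII_NM[elem]
    elif mode == "cg":
        for i, name in enumerate(structure.names):
            key = str(name)
            if bead_radius_table and key in bead_radius_table:
                radii[i] = bead_radius_table[key]
            else:
                radii[i] = bead_radius_for_type(key)
    else:
        raise ValueError(f"unknown radius mode {mode!r}")
    out.radii[:] = radii
    return out


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789").upper()
    if stripped[:2] in VDW_RADII_NM:
        return stripped[:2]
    return stripped[:1]


def compute_sasa(structure: BeadStructure,
                 probe_radius: float = DEFAULT_PROBE_RADIUS_NM,
                 n_quadrature_points: int = DEFAULT_N_QUADRATURE_POINTS
                 ) -> "SasaResult":
    """Per-particle, per-residue and total SASA in nm^2.

    Deterministic for a fixed point count; accuracy improves with
    ``n_quadrature_points`` (isolated spheres are exact at any count).
    """
    radii = np.asarray(structure.radii, dtype=float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError(
            "all particle radii must be positive and finite; "
            "call assign_radii() first"
        )
    coords = structure.coords
    n = structure.n_particles
    inflated = radii + probe_radius
    sphere = golden_spiral_points(n_quadrature_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    per_particle = np.zeros(n)
    for i in range(n):
        pts = coords[i] + inflated[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], r=max_reach)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (inflated[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_particle[i] = 4.0 * np.pi * inflated[i] ** 2 * frac

    per_residue: dict[tuple[str, int], float] = {}
    res_names: dict[tuple[str, int], str] = {}
    for i in range(n):
        key = (str(structure.chain_ids[i]), int(structure.residue_numbers[i]))
        per_residue[key] = per_residue.get(key, 0.0) + per_particle[i]
        res_names.setdefault(key, str(structure.residue_names[i]))
    return SasaResult(per_particle=per_particle, per_residue=per_residue,
                      residue_names=res_names,
                      total=float(per_particle.sum()),
                      probe_radius=probe_radius,
                      n_quadrature_points=n_quadrature_points)


@dataclass
class SasaResult:
    per_particle: np.ndarray
    per_residue: dict[tuple[str, int], float]   # (chain, resnum) -> nm^2
    residue_names: dict[tuple[str, int], str]
    total: float
    probe_radius: float
    n_quadrature_points: int

    def group_area(self, particle_indices: np.ndarray) -> float:
        """Summed SASA over a particle group (nm^2)."""
        return float(self.per_particle[np.asarray(particle_indices, int)].sum())


def relative_sasa(per_residue_sasa: dict[tuple[str, int], float],
                  residue_names: dict[tuple[str, int], str],
                  reference: str | dict[str, float] = "theoretical"
                  ) -> dict[tuple[str, int], float]:
    """rSASA per residue: observed SASA over the fully-exposed reference
    maximum for that residue type, clamped to [0, 1] (clamping logged)."""
    table = (MAX_SASA_TABLES[reference] if isinstance(reference, str)
             else reference)
    out: dict[tuple[str, int], float] = {}
    for key, area in per_residue_sasa.items():
        resname = residue_names[key].upper()
        if resname not in table:
            raise KeyError(
                f"residue type {resname!r} absent from the reference table"
            )
        ratio = area / table[resname]
        if ratio > 1.0:
            logger.warning(
                "rSASA %.3f > 1 for %s %s; clamping to 1.0",
                ratio, resname, key)
            ratio = 1.0
        out[key] = max(0.0, ratio)
    return out
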