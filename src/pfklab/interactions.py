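"""Geometric detection of hydrogen bonds, salt bridges and aromatic
stacking; persistence statistics across frames; and hydration-based
dissection of a protein-protein interface into core / support / rim /
noninteracting-surface (NIS) regions.

Interaction criteria are purely geometric.  Hydrogen bonds use the
standard donor-acceptor distance + donor-angle definition; when the
structure carries no hydrogens a heavy-atom fallback (distance plus a
donor-capability check) is applied.  Interface regions follow the
hydration convention: a residue is buried when its rSASA falls below a
threshold (default 0.25); interface residues (those losing SASA upon
complexation) split into support (buried already in the free monomer),
core (exposed free, buried in the complex) and interacting rim (exposed
in both), while nearby non-interface surface forms the NIS rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import BeadStructure
from .sasa import compute_sasa, relative_sasa

# --- criteria and records ----------------------------------------------------


@dataclass(frozen=True)
class HBondCriteria:
    max_da_distance: float = 0.35      # donor-acceptor, nm
    min_dha_angle: float = 120.0       # donor-H-acceptor, degrees


@dataclass(frozen=True)
class SaltBridgeCriteria:
    max_no_distance: float = 0.40      # side-chain N-O, nm


@dataclass(frozen=True)
class StackingCriteria:
    max_centroid_distance: float = 0.55     # nm
    max_parallel_angle: float = 30.0        # degrees
    tshape_angle_range: tuple[float, float] = (60.0, 120.0)


@dataclass(frozen=True)
class InteractionCriteria:
    hb: HBondCriteria = field(default_factory=HBondCriteria)
    sb: SaltBridgeCriteria = field(default_factory=SaltBridgeCriteria)
    stack: StackingCriteria = field(default_factory=StackingCriteria)


@dataclass(frozen=True)
class InteractionRecord:
    """One detected non-covalent contact."""

    type: str                                   # hydrogen_bond | salt_bridge | aromatic_stacking
    residue_a: tuple[str, int, str]             # (chain, number, name)
    residue_b: tuple[str, int, str]
    frame: int
    distance: float                             # nm
    angle: float | None = None                  # degrees
    subtype: str | None = None                  # parallel | t_shaped
    atoms: tuple[str, str] | None = None

    @property
    def pair(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return tuple(sorted((self.residue_a, self.residue_b)))


# Donor heavy atoms (and their hydrogens' name prefixes) and acceptors,
# by residue; backbone N/O handled for every residue.
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}
ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CATIONIC_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


class CapabilityError(ValueError):
    """The structure lacks the atom naming needed for a detector."""


def _residue_table(structure: BeadStructure):
    """Group particle indices by (chain, resnum); returns dict with name."""
    table: dict[tuple[str, int], dict] = {}
    for i in range(structure.n_particles):
        key = (str(structure.chain_ids[i]), int(structure.residue_numbers[i]))
        entry = table.setdefault(
            key, {"name": str(structure.residue_names[i]).upper(),
                  "atoms": {}})
        entry["atoms"][str(structure.names[i]).upper()] = i
    return table


def _res_id(key, entry) -> tuple[str, int, str]:
    return (key[0], key[1], entry["name"])


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hydrogens_of(entry: dict, donor_name: str) -> list[int]:
    """Hydrogens bonded to a donor heavy atom, matched by naming
    convention (e.g. ND2 -> HD21, HD22; N -> H, H1..)."""
    hits = []
    if donor_name == "N":
        prefixes = ("H", "H1", "H2", "H3", "HN")
        for aname, idx in entry["atoms"].items():
            if aname in prefixes:
                hits.append(idx)
        return hits
    stem = donor_name[1:]  # e.g. ND2 -> D2, OG1 -> G1, NZ -> Z
    for aname, idx in entry["atoms"].items():
        if aname.startswith("H") and aname[1:].startswith(stem):
            hits.append(idx)
    return hits


def detect_hydrogen_bonds(structure: BeadStructure,
                          criteria: HBondCriteria = HBondCriteria(),
                          frame: int = 0,
                          coords: np.ndarray | None = None
                          ) -> list[InteractionRecord]:
    """Hydrogen bonds between residues of different chains or
    non-adjacent residues; one record per donor-H/acceptor atom pair, so
    a bidentate arrangement yields two records."""
    x = structure.coords if coords is None else coords
    table = _residue_table(structure)
    donors: list[tuple[tuple, dict, str, int]] = []     # (key, entry, atom, idx)
    acceptors: list[tuple[tuple, dict, str, int]] = []
    any_hydrogens = any(str(n).upper().startswith("H")
                        for n in structure.names)
    for key, entry in table.items():
        name = entry["name"]
        donor_names = ("N",) + SIDECHAIN_DONORS.get(name, ())
        acceptor_names = ("O", "OXT") + SIDECHAIN_ACCEPTORS.get(name, ())
        for a in donor_names:
            if a in entry["atoms"]:
                donors.append((key, entry, a, entry["atoms"][a]))
        for a in acceptor_names:
            if a in entry["atoms"]:
                acceptors.append((key, entry, a, entry["atoms"][a]))
    if not donors or not acceptors:
        if structure.n_particles == 0:
            return []
        raise CapabilityError(
            "structure has no recognizable donor/acceptor atom names"
        )
    records = []
    acc_coords = np.array([x[i] for *_, i in acceptors])
    tree = cKDTree(acc_coords)
    for dkey, dentry, dname, didx in donors:
        for aj in tree.query_ball_point(x[didx], r=criteria.max_da_distance):
            akey, aentry, aname, aidx = acceptors[aj]
            if akey == dkey:
                continue
            if akey[0] == dkey[0] and abs(akey[1] - dkey[1]) <= 1:
                continue  # skip local backbone neighbors
            d = float(np.linalg.norm(x[aidx] - x[didx]))
            if d > criteria.max_da_distance:
                continue
            hydrogens = _hydrogens_of(dentry, dname)
            if hydrogens:
                best = None
                for hidx in hydrogens:
                    ang = _angle_deg(x[didx], x[hidx], x[aidx])
                    if ang >= criteria.min_dha_angle and (
                            best is None or ang > best):
                        best = ang
                if best is None:
                    continue
                angle = best
            elif any_hydrogens:
                # hydrogens exist elsewhere but not on this donor: not a donor
                continue
            else:
                angle = None  # heavy-atom fallback: distance + donor capability
            records.append(InteractionRecord(
                type="hydrogen_bond",
                residue_a=_res_id(dkey, dentry),
                residue_b=_res_id(akey, aentry),
                frame=frame, distance=d, angle=angle,
                atoms=(dname, aname),
            ))
    return records


def detect_salt_bridges(structure: BeadStructure,
                        criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
                        frame: int = 0,
                        coords: np.ndarray | None = None
                        ) -> list[InteractionRecord]:
    """Salt bridges: anionic Asp/Glu carboxylate oxygen within the cutoff
    of a cationic Lys/Arg/His nitrogen; one record per residue pair with
    the minimum N-O distance."""
    x = structure.coords if coords is None else coords
    table = _residue_table(structure)
    pairs: dict[tuple, tuple[float, tuple, tuple]] = {}
    anions, cations = [], []
    for key, entry in table.items():
        for aname in ANIONIC_ATOMS.get(entry["name"], ()):
            if aname in entry["atoms"]:
                anions.append((key, entry, entry["atoms"][aname]))
        for aname in CATIONIC_ATOMS.get(entry["name"], ()):
            if aname in entry["atoms"]:
                cations.append((key, entry, entry["atoms"][aname]))
    for akey, aentry, ai in anions:
        for ckey, centry, ci in cations:
            if akey == ckey:
                continue
            d = float(np.linalg.norm(x[ai] - x[ci]))
            if d <= criteria.max_no_distance:
                pkey = tuple(sorted((akey, ckey)))
                if pkey not in pairs or d < pairs[pkey][0]:
                    pairs[pkey] = (d, _res_id(akey, aentry),
                                   _res_id(ckey, centry))
    return [InteractionRecord(type="salt_bridge", residue_a=ra, residue_b=rc,
                              frame=frame, distance=d)
            for d, ra, rc in pairs.values()]


def detect_aromatic_stacking(structure: BeadStructure,
                             criteria: StackingCriteria = StackingCriteria(),
                             frame: int = 0,
                             coords: np.ndarray | None = None
                             ) -> list[InteractionRecord]:
    """Aromatic ring stacking by centroid distance and interplanar angle,
    labelled parallel or t_shaped."""
    x = structure.coords if coords is None else coords
    table = _residue_table(structure)
    rings = []
    for key, entry in table.items():
        names = RING_ATOMS.get(entry["name"])
        if not names:
            continue
        idx = [entry["atoms"][a] for a in names if a in entry["atoms"]]
        if len(idx) < 3:
            continue
        pts = x[idx]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        # ring normal: smallest principal axis
        _, _, vt = np.linalg.svd(centered)
        rings.append((key, entry, centroid, vt[2]))
    records = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            (k1, e1, c1, n1), (k2, e2, c2, n2) = rings[i], rings[j]
            if k1 == k2:
                continue
            d = float(np.linalg.norm(c2 - c1))
            if d > criteria.max_centroid_distance:
                continue
            cosang = abs(float(np.dot(n1, n2)))
            angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            lo, hi = criteria.tshape_angle_range
            if angle <= criteria.max_parallel_angle:
                subtype = "parallel"
            elif lo <= angle <= hi:
                subtype = "t_shaped"
            else:
                continue
            records.append(InteractionRecord(
                type="aromatic_stacking",
                residue_a=_res_id(k1, e1), residue_b=_res_id(k2, e2),
                frame=frame, distance=d, angle=angle, subtype=subtype))
    return records


_DETECTORS = {
    "hydrogen_bond": (detect_hydrogen_bonds, "hb"),
    "salt_bridge": (detect_salt_bridges, "sb"),
    "aromatic_stacking": (detect_aromatic_stacking, "stack"),
}


def detect_interactions(structure: BeadStructure,
                        kinds: str | Iterable[str] = ("hydrogen_bond",
                                                      "salt_bridge",
                                                      "aromatic_stacking"),
                        criteria: InteractionCriteria = InteractionCriteria(),
                        frame: int = 0,
                        coords: np.ndarray | None = None
                        ) -> list[InteractionRecord]:
    """Run one or more geometric detectors on a frame; deterministic."""
    if isinstance(kinds, str):
        kinds = (kinds,)
    if structure.n_particles == 0:
        return []
    records: list[InteractionRecord] = []
    strict = len(tuple(kinds)) == 1
    for kind in kinds:
        if kind not in _DETECTORS:
            raise ValueError(f"unknown interaction type {kind!r}")
        fn, attr = _DETECTORS[kind]
        try:
            records.extend(fn(structure, getattr(criteria, attr),
                              frame=frame, coords=coords))
        except CapabilityError:
            # a structure with no donors/acceptors simply yields nothing
            # when scanning all types; asking for one type specifically
            # still surfaces the capability gap
            if strict:
                raise
    return records


# --- persistence across frames -------------------------------------------------


def stable_pairs(records: Sequence[InteractionRecord], n_frames: int,
                 persistence_threshold: float = 0.5
                 ) -> list[tuple[tuple, str, float]]:
    """Residue pairs whose interaction occupancy (distinct frames present
    / n_frames) meets the threshold, sorted by occupancy descending."""
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if not 0 < persistence_threshold <= 1:
        raise ValueError("persistence threshold must be in (0, 1]")
    frames_seen: dict[tuple, set[int]] = {}
    for rec in records:
        key = (rec.pair, rec.type)
        frames_seen.setdefault(key, set()).add(rec.frame)
    out = []
    for (pair, kind), frames in frames_seen.items():
        occ = len(frames) / n_frames
        if occ >= persistence_threshold:
            out.append((pair, kind, occ))
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def subsample_frames(n_frames: int, n_keep: int = 16) -> np.ndarray:
    """Evenly spaced frame indices (the per-replica subsampling used for
    interaction inventories)."""
    if n_keep >= n_frames:
        return np.arange(n_frames)
    return np.unique(np.linspace(0, n_frames - 1, n_keep).round().astype(int))


# --- interface region classification -------------------------------------------


@dataclass
class RegionAssignment:
    """Region per residue plus the monomer and complex rSASA values."""

    regions: dict[tuple[str, int], str]
    monomer_rsasa: dict[tuple[str, int], float]
    complex_rsasa: dict[tuple[str, int], float]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for region in self.regions.values():
            out[region] = out.get(region, 0) + 1
        return out

    def residues_in(self, region: str) -> list[tuple[str, int]]:
        return sorted(k for k, v in self.regions.items() if v == region)


def classify_interface_regions(monomer: BeadStructure,
                               complex_structure: BeadStructure,
                               monomer_chain: str,
                               rsasa_threshold: float = 0.25,
                               nis_distance: float = 0.7,
                               sasa_kwargs: dict | None = None,
                               reference: str = "theoretical"
                               ) -> RegionAssignment:
    """Hydration-based interface dissection for one monomer of a complex.

    A residue is an interface residue when it loses SASA upon
    complexation.  Among interface residues: support = buried already in
    the free monomer (rSASA < threshold); core = exposed free but buried
    in the complex; rim_interacting = exposed in both.  Non-interface
    residues are interior when buried in the free monomer, rim_nis when
    on the surface with a particle within ``nis_distance`` of an
    interface residue, else surface.
    """
    sasa_kwargs = sasa_kwargs or {}
    mono_sasa = compute_sasa(monomer, **sasa_kwargs)
    cplx_sasa = compute_sasa(complex_structure, **sasa_kwargs)

    mono_keys = {k for k in mono_sasa.per_residue if k[0] == monomer_chain}
    cplx_keys = {k for k in cplx_sasa.per_residue if k[0] == monomer_chain}
    if mono_keys != cplx_keys:
        raise ValueError(
            "monomer and complex disagree on the residue set of chain "
            f"{monomer_chain!r}"
        )
    mono_rel = relative_sasa(
        {k: v for k, v in mono_sasa.per_residue.items() if k in mono_keys},
        mono_sasa.residue_names, reference)
    cplx_rel = relative_sasa(
        {k: v for k, v in cplx_sasa.per_residue.items() if k in mono_keys},
        cplx_sasa.residue_names, reference)

    interface = {k for k in mono_keys
                 if mono_sasa.per_residue[k] - cplx_sasa.per_residue[k] > 1e-9}

    regions: dict[tuple[str, int], str] = {}
    for k in mono_keys:
        m, c = mono_rel[k], cplx_rel[k]
        if k in interface:
            if m < rsasa_threshold:
                regions[k] = "support"
            elif c < rsasa_threshold:
                regions[k] = "core"
            else:
                regions[k] = "rim_interacting"
        else:
            regions[k] = "interior" if m < rsasa_threshold else "surface"

    # NIS rim: non-interface surface residues near an interface residue
    if interface:
        iface_idx = np.concatenate(
            [complex_structure.particle_indices(c, r) for c, r in interface])
        tree = cKDTree(complex_structure.coords[iface_idx])
        for k in mono_keys:
            if regions[k] != "surface":
                continue
            idx = complex_structure.particle_indices(*k)
            d, _ = tree.query(complex_structure.coords[idx], k=1)
            if np.any(d <= nis_distance):
                regions[k] = "rim_nis"

    return RegionAssignment(regions=regions, monomer_rsasa=mono_rel,
                            complex_rsasa=cplx_rel)
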