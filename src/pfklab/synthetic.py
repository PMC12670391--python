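"""Synthetic input generators.

These produce inputs with the geometric and statistical structure the
analysis modules assume — two-rigid-body bead trajectories realizing a
prescribed inter-body contact schedule, umbrella-window samples drawn
exactly from an analytic potential of mean force under harmonic biases,
atomistic-style fixtures with planted hydrogen bonds / salt bridges /
aromatic stacks, and labeled toy tetramer assemblies — so the whole
pipeline runs and is testable without any structure download or MD
engine.  Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import BeadStructure, Trajectory
from .tables import DEFAULT_BEAD_RADIUS_NM, KB_KJ_PER_MOL_K
from .wham import UmbrellaWindow

# --- two-body contact trajectories ---------------------------------------------

TETRAMER_A_CHAINS = ("A", "B", "C", "D")
TETRAMER_B_CHAINS = ("E", "F", "G", "H")


@dataclass(frozen=True)
class ContactSchedule:
    """Which residue copies are in contact in each frame.

    ``frames[f]`` is the set of (monomer index 0-3, residue number)
    copies designated "in contact" in frame f; the designation is applied
    symmetrically to both bodies (the paired copies approach each other).
    ``margin`` is the clearance on each side of the cutoff: designated
    copies sit at cutoff - margin from their partner, all other
    inter-body distances are >= cutoff + margin, so strict-inequality
    counting is unambiguous.
    """

    frames: tuple[frozenset[tuple[int, int]], ...]
    cutoff: float = 0.7
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.margin <= 0 or self.cutoff - self.margin <= 0:
            raise ValueError("need 0 < margin < cutoff")
        for f, designated in enumerate(self.frames):
            for m, r in designated:
                # four monomers per body: at most 4 copies per residue
                if not 0 <= m <= 3:
                    raise ValueError(
                        f"frame {f}: monomer index {m} not in 0..3")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def saturating_schedule(n_frames: int, residue_numbers: Sequence[int],
                        monomers: tuple[int, int] = (0, 1),
                        cutoff: float = 0.7, margin: float = 0.05
                        ) -> ContactSchedule:
    """The geometric-maximum schedule: in every frame exactly two monomer
    copies of every residue in each tetramer touch the other tetramer,
    so the per-residue average contact probability equals the 0.5 bound."""
    designated = frozenset((m, int(r)) for m in monomers
                           for r in residue_numbers)
    return ContactSchedule(frames=(designated,) * n_frames,
                           cutoff=cutoff, margin=margin)


def gen_two_body_trajectory(schedule: ContactSchedule,
                            beads_per_monomer: int = 10,
                            seed: int = 0,
                            lateral_spacing: float = 2.0
                            ) -> tuple[BeadStructure, Trajectory]:
    """Two four-monomer bodies (chains A-D vs E-H, one bead per residue,
    residues 1..beads_per_monomer) realizing a contact schedule exactly.

    Each (monomer, residue) copy owns a lateral slot; body B's copy sits
    on the x = 0 plane and body A's copy at x = cutoff - margin when
    designated (else cutoff + margin).  Slots are ``lateral_spacing``
    apart, which must exceed cutoff + margin so no cross-slot pair can
    come into contact.
    """
    if schedule.cutoff + schedule.margin >= lateral_spacing:
        raise ValueError(
            "unrealizable schedule: lateral spacing must exceed "
            "cutoff + margin")
    n_res = beads_per_monomer
    residues = np.arange(1, n_res + 1)
    n_mono = 4
    n_per_body = n_mono * n_res

    def slot(m: int, r: int) -> float:
        return (m * n_res + (r - 1)) * lateral_spacing

    chains, resnums = [], []
    coords0 = np.zeros((2 * n_per_body, 3))
    x_far = schedule.cutoff + schedule.margin
    i = 0
    for body, chain_set in ((0, TETRAMER_A_CHAINS), (1, TETRAMER_B_CHAINS)):
        for m in range(n_mono):
            for r in residues:
                chains.append(chain_set[m])
                resnums.append(int(r))
                coords0[i] = (x_far if body == 0 else 0.0, slot(m, r), 0.0)
                i += 1
    n = 2 * n_per_body
    structure = BeadStructure(
        particle_ids=np.arange(1, n + 1),
        names=np.array(["BB"] * n),
        residue_names=np.array(["GLY"] * n),
        residue_numbers=np.array(resnums),
        chain_ids=np.array(chains),
        coords=coords0,
        masses=np.full(n, 72.0),
        radii=np.full(n, DEFAULT_BEAD_RADIUS_NM),
    )
    # per-frame coordinates: move designated copies of body A inward
    rng = np.random.default_rng(seed)
    frames = np.empty((schedule.n_frames, n, 3))
    x_near = schedule.cutoff - schedule.margin
    a_index = {}
    for idx in range(n_per_body):
        m, r0 = divmod(idx, n_res)
        a_index[(m, int(residues[r0]))] = idx
    for f, designated in enumerate(schedule.frames):
        frame = coords0.copy()
        for key in designated:
            if key not in a_index:
                raise ValueError(
                    f"schedule references residue copy {key} outside the "
                    f"generated body")
            frame[a_index[key], 0] = x_near
        # tiny z-jitter keeps frames distinct without crossing any margin
        frame[:, 2] += rng.uniform(-0.01, 0.01, size=n)
        frames[f] = frame
    traj = Trajectory(frames=frames,
                      times=np.arange(schedule.n_frames, dtype=float),
                      box=np.zeros(3), periodic=False)
    return structure, traj


# --- umbrella-window samples ----------------------------------------------------

N_GRID = 10_000


def gen_umbrella_samples(pmf: Callable[[np.ndarray], np.ndarray],
                         centers: Sequence[float],
                         spring_constants: float | Sequence[float],
                         n_samples: int,
                         temperature: float = 300.0,
                         seed: int = 0,
                         x_range: tuple[float, float] | None = None
                         ) -> list[UmbrellaWindow]:
    """Exact biased-density samples for each umbrella window.

    Samples are drawn from p_i(x) proportional to
    exp(-[V(x) + k_i (x - c_i)^2 / 2] / kT) by inverse-CDF lookup on a
    10^4-point grid — exact to grid resolution, fast, and free of the
    autocorrelation an MD or MCMC sampler would add.
    """
    centers = np.asarray(centers, dtype=float)
    ks = np.broadcast_to(np.asarray(spring_constants, dtype=float),
                         centers.shape).copy()
    if x_range is None:
        x_range = (centers.min() - 1.0, centers.max() + 1.0)
    x = np.linspace(*x_range, N_GRID)
    kt = KB_KJ_PER_MOL_K * temperature
    v = np.asarray(pmf(x), dtype=float)
    rng = np.random.default_rng(seed)
    windows = []
    for c, k in zip(centers, ks):
        u = v + 0.5 * k * (x - c) ** 2
        w = np.exp(-(u - u.min()) / kt)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                               * np.diff(x))])
        if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
            raise ValueError(
                f"biased density not normalizable on {x_range} for window "
                f"center {c}")
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_samples), cdf, x)
        windows.append(UmbrellaWindow(center=float(c), spring_constant=float(k),
                                      samples=samples,
                                      temperature=temperature))
    return windows


def double_well_pmf(x: np.ndarray,
                    minima: tuple[float, float] = (0.8, 1.6),
                    barrier: float = 12.0,
                    depth2: float = 0.0) -> np.ndarray:
    """Analytic double-well test potential (kJ/mol): quartic through the
    two minima with the stated barrier at the midpoint; ``depth2`` tilts
    the second well relative to the first."""
    x = np.asarray(x, dtype=float)
    a, b = minima
    mid = 0.5 * (a + b)
    half = 0.5 * (b - a)
    # quartic (x-a)^2 (x-b)^2 scaled so V(mid) - V(a) = barrier
    quartic = ((x - a) * (x - b)) ** 2 / half ** 4 * barrier
    tilt = depth2 * (x - a) / (b - a)
    return quartic + tilt


# --- planted interaction fixtures ----------------------------------------------


def _structure_from_atoms(atoms: list[tuple[str, str, int, str, tuple, float]]
                          ) -> BeadStructure:
    """atoms: (name, resname, resnum, chain, xyz nm, mass)."""
    n = len(atoms)
    return BeadStructure(
        particle_ids=np.arange(1, n + 1),
        names=np.array([a[0] for a in atoms]),
        residue_names=np.array([a[1] for a in atoms]),
        residue_numbers=np.array([a[2] for a in atoms]),
        chain_ids=np.array([a[3] for a in atoms]),
        coords=np.array([a[4] for a in atoms], dtype=float),
        masses=np.array([a[5] for a in atoms]),
        radii=np.full(n, np.nan),
    )


def _hb_hydrogen(n_pos: np.ndarray, acc_pos: np.ndarray,
                 off_axis_deg: float = 12.0) -> np.ndarray:
    """Place a hydrogen 0.10 nm from the donor, rotated slightly off the
    donor-acceptor axis so the donor-H-acceptor angle lands near 165
    degrees — comfortably above the 120-degree criterion."""
    u = acc_pos - n_pos
    u = u / np.linalg.norm(u)
    # any perpendicular
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    ang = np.radians(off_axis_deg)
    direction = np.cos(ang) * u + np.sin(ang) * perp
    return n_pos + 0.10 * direction


def gen_interaction_fixture(kind: str) -> BeadStructure:
    """Atomistic-style two-residue fixture planted to satisfy (or, for
    ``'none'``, violate) the default interaction criteria by a clear
    margin.

    kinds: ``hb_bidentate`` — facing asparagine amides exchanging two
    side-chain hydrogen bonds (the reciprocal Asn-Asn arrangement);
    ``salt_bridge`` — one Glu/Arg pair at 0.37 nm N-O; ``stack`` — two
    parallel phenylalanine rings 0.45 nm apart; ``none`` — residues far
    beyond every cutoff.
    """
    if kind == "hb_bidentate":
        a_od1 = np.array([0.0, 0.0, 0.0])
        a_nd2 = np.array([0.0, 0.22, 0.0])
        b_nd2 = np.array([0.29, 0.0, 0.0])
        b_od1 = np.array([0.29, 0.22, 0.0])
        a_h = _hb_hydrogen(a_nd2, b_od1)
        b_h = _hb_hydrogen(b_nd2, a_od1)
        a_cg = a_od1 + np.array([-0.12, 0.11, 0.0])
        b_cg = b_od1 + np.array([0.12, 0.11, 0.0])
        atoms = [
            ("CG", "ASN", 702, "A", tuple(a_cg), 12.0),
            ("OD1", "ASN", 702, "A", tuple(a_od1), 16.0),
            ("ND2", "ASN", 702, "A", tuple(a_nd2), 14.0),
            ("HD21", "ASN", 702, "A", tuple(a_h), 1.0),
            ("CG", "ASN", 702, "B", tuple(b_cg), 12.0),
            ("OD1", "ASN", 702, "B", tuple(b_od1), 16.0),
            ("ND2", "ASN", 702, "B", tuple(b_nd2), 14.0),
            ("HD21", "ASN", 702, "B", tuple(b_h), 1.0),
        ]
        return _structure_from_atoms(atoms)
    if kind == "salt_bridge":
        # Glu carboxylate vs Arg guanidinium, nearest N-O = 0.37 nm:
        # inside the 0.40 nm salt-bridge cutoff, outside the 0.35 nm
        # hydrogen-bond cutoff.
        atoms = [
            ("CD", "GLU", 10, "A", (-0.12, 0.0, 0.0), 12.0),
            ("OE1", "GLU", 10, "A", (0.0, 0.0, 0.0), 16.0),
            ("OE2", "GLU", 10, "A", (-0.18, 0.12, 0.0), 16.0),
            ("CZ", "ARG", 20, "B", (0.49, 0.0, 0.0), 12.0),
            ("NH1", "ARG", 20, "B", (0.37, 0.0, 0.0), 14.0),
            ("NH2", "ARG", 20, "B", (0.55, 0.12, 0.0), 14.0),
        ]
        return _structure_from_atoms(atoms)
    if kind == "stack":
        def ring(center, resnum, chain):
            names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
            out = []
            for k, name in enumerate(names):
                ang = np.pi / 3 * k
                pos = center + 0.14 * np.array([np.cos(ang), np.sin(ang), 0.0])
                out.append((name, "PHE", resnum, chain, tuple(pos), 12.0))
            return out
        atoms = ring(np.zeros(3), 700, "A") + ring(np.array([0.0, 0.0, 0.45]),
                                                   700, "B")
        return _structure_from_atoms(atoms)
    if kind == "none":
        atoms = [
            ("OD1", "ASN", 1, "A", (0.0, 0.0, 0.0), 16.0),
            ("ND2", "ASN", 1, "A", (0.0, 0.22, 0.0), 14.0),
            ("OD1", "ASN", 2, "B", (5.0, 0.0, 0.0), 16.0),
            ("ND2", "ASN", 2, "B", (5.0, 0.22, 0.0), 14.0),
        ]
        return _structure_from_atoms(atoms)
    raise ValueError(f"unknown fixture kind {kind!r}")


# --- toy assemblies -------------------------------------------------------------


def gen_toy_assembly(n_monomers: int = 4,
                     beads_per_monomer: int = 20,
                     interface1: Sequence[int] = (3, 4, 5),
                     interface2: Sequence[int] = (12, 13),
                     seed: int = 0,
                     chain_ids: Sequence[str] | None = None,
                     center: np.ndarray | None = None
                     ) -> BeadStructure:
    """Labeled toy tetramer: monomers on a ring, one backbone bead per
    residue, with designated interface-1 and interface-2 residue subsets
    pushed to the assembly surface.  Deterministic per seed."""
    if n_monomers <= 0 or beads_per_monomer <= 0:
        raise ValueError("counts must be positive")
    i1 = set(int(r) for r in interface1)
    i2 = set(int(r) for r in interface2)
    if i1 & i2:
        raise ValueError("interface residue lists must be disjoint")
    for r in i1 | i2:
        if not 1 <= r <= beads_per_monomer:
            raise ValueError(
                f"interface residue {r} exceeds beads_per_monomer")
    if chain_ids is None:
        chain_ids = [chr(ord("A") + m) for m in range(n_monomers)]
    center = np.zeros(3) if center is None else np.asarray(center, float)
    rng = np.random.default_rng(seed)
    atoms = []
    ring_radius = 2.0
    for m in range(n_monomers):
        ang = 2 * np.pi * m / n_monomers
        m_center = center + ring_radius * np.array(
            [np.cos(ang), np.sin(ang), 0.0])
        outward = np.array([np.cos(ang), np.sin(ang), 0.0])
        for r in range(1, beads_per_monomer + 1):
            pos = m_center + np.array([0.0, 0.0, 0.35 * (r - 1)])
            if r in i1:
                pos = pos + 0.5 * outward                 # surface, face +z side
            elif r in i2:
                pos = pos + 0.5 * outward + np.array([0.0, 0.0, -0.2])
            pos = pos + rng.normal(0.0, 0.02, size=3)
            atoms.append(("BB", "GLY", r, chain_ids[m], tuple(pos), 72.0))
    structure = _structure_from_atoms(atoms)
    structure.radii[:] = DEFAULT_BEAD_RADIUS_NM
    return structure
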