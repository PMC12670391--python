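"""Contact counting and SASA-normalized contact statistics.

Two beads are in contact when their distance is strictly less than the
cutoff (default 0.7 nm); ties at exactly the cutoff are non-contacts.
The normalized statistic divides the per-frame mean contact count by the
product of the two groups' solvent-accessible surface areas,

    N_norm = N_contacts(group1, group2) / (SASA_group1 * SASA_group2),

so surfaces of very different size become comparable.  In a system of
two tetramers at most two copies of any residue — one per tetramer being
impossible, each copy from a different monomer of the same tetramer —
can touch the partner tetramer at once, which caps the per-residue
average contact probability at 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import BeadStructure, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF_NM = 0.7


@dataclass(frozen=True)
class ContactParameters:
    """Contact definition: strict distance cutoff in nm."""

    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ContactStatistic:
    """Per-frame mean contact count, the two group SASAs (nm^2) and the
    normalized value in contacts * nm^-4."""

    n_contacts: float
    sasa_group1: float
    sasa_group2: float
    n_norm: float


@dataclass
class ContactProbabilityProfile:
    """Per-residue contact probability with SEM, averaged over the eight
    monomers of a two-tetramer system (and over replicas if several
    trajectories are pooled)."""

    residue_numbers: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_monomers: int
    n_replicas: int


def _minimum_image(deltas: np.ndarray, box: np.ndarray) -> np.ndarray:
    return deltas - box * np.round(deltas / box)


def count_contacts(frame: np.ndarray, set_a: np.ndarray, set_b: np.ndarray,
                   params: ContactParameters = ContactParameters(),
                   box: np.ndarray | None = None,
                   periodic: bool = False) -> int:
    """Number of (a, b) particle pairs at distance strictly below the
    cutoff.  Symmetric in the two sets; empty sets give 0 with a warning.
    Minimum-image distances are used when a periodic box is declared.
    """
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        warnings.warn("count_contacts called with an empty particle set",
                      stacklevel=2)
        return 0
    xa = frame[set_a]
    xb = frame[set_b]
    if periodic and box is not None and np.all(np.asarray(box) > 0):
        box = np.asarray(box, dtype=float)
        d = _minimum_image(xa[:, None, :] - xb[None, :, :], box)
        dist = np.sqrt((d * d).sum(axis=-1))
        return int((dist < params.cutoff).sum())
    # non-periodic: sparse KD-tree query scales to large sets
    tree_a = cKDTree(xa)
    tree_b = cKDTree(xb)
    pairs = tree_a.query_ball_tree(tree_b, r=params.cutoff)
    n = 0
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        d = np.linalg.norm(xb[hits] - xa[i], axis=1)
        n += int((d < params.cutoff).sum())  # strict inequality
    return n


def contacts_per_frame(traj: Trajectory, set_a: np.ndarray, set_b: np.ndarray,
                       params: ContactParameters = ContactParameters()
                       ) -> np.ndarray:
    """Contact count for every frame of a trajectory."""
    return np.array([
        count_contacts(traj.frames[i], set_a, set_b, params,
                       box=traj.box, periodic=traj.periodic)
        for i in range(traj.n_frames)
    ])


def normalized_contact_statistic(traj: Trajectory, group1: np.ndarray,
                                 group2: np.ndarray, sasa1: float,
                                 sasa2: float,
                                 params: ContactParameters = ContactParameters()
                                 ) -> ContactStatistic:
    """SASA-normalized contact statistic between two particle groups.

    ``n_contacts`` is the mean over frames; the group SASAs are computed
    once on a static reference conformation (see :mod:`pfklab.sasa`) so
    the normalization is a fixed property of the surfaces, not of the
    trajectory.  Swapping the group labels leaves the value unchanged.
    """
    if sasa1 <= 0 or sasa2 <= 0:
        raise ValueError(
            f"group SASAs must be positive to normalize (got {sasa1}, {sasa2})"
        )
    per_frame = contacts_per_frame(traj, group1, group2, params)
    mean_contacts = float(per_frame.mean())
    return ContactStatistic(
        n_contacts=mean_contacts,
        sasa_group1=float(sasa1),
        sasa_group2=float(sasa2),
        n_norm=mean_contacts / (sasa1 * sasa2),
    )


def _monomer_contact_matrix(traj: Trajectory,
                            monomer_indices: Sequence[np.ndarray],
                            other_indices: np.ndarray,
                            residue_numbers: np.ndarray,
                            monomer_residue_numbers: Sequence[np.ndarray],
                            params: ContactParameters) -> np.ndarray:
    """Indicator[residue, monomer, frame]: the monomer's copy of the
    residue has >=1 particle within the cutoff of the other tetramer."""
    n_res = len(residue_numbers)
    res_pos = {int(r): i for i, r in enumerate(residue_numbers)}
    out = np.zeros((n_res, len(monomer_indices), traj.n_frames), dtype=bool)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        xb = frame[other_indices]
        tree_b = cKDTree(xb)
        for m, idx in enumerate(monomer_indices):
            xa = frame[idx]
            hits = tree_b.query_ball_point(xa, r=params.cutoff)
            for local_i, hit in enumerate(hits):
                if not hit:
                    continue
                d = np.linalg.norm(xb[hit] - xa[local_i], axis=1)
                if np.any(d < params.cutoff):
                    rnum = int(monomer_residue_numbers[m][local_i])
                    out[res_pos[rnum], m, f] = True
    return out


def per_residue_contact_probability(
        trajs: Trajectory | Sequence[Trajectory],
        structure: BeadStructure,
        tetramer_a: Sequence[str],
        tetramer_b: Sequence[str],
        params: ContactParameters = ContactParameters()
        ) -> ContactProbabilityProfile:
    """Per-residue contact probability for a two-tetramer system.

    ``tetramer_a`` and ``tetramer_b`` list the chain IDs of the four
    monomers of each tetramer; monomers must share residue numbering.
    For each residue the probability is the fraction of (frame, monomer)
    samples in which that monomer's copy has at least one particle in
    contact with any particle of the other tetramer, averaged over all
    eight monomers and over replicas.  The SEM is taken across the
    monomer x replica sample means — the finest grouping at which the
    profile is averaged.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    chains_a = list(tetramer_a)
    chains_b = list(tetramer_b)

    def monomer_info(chains):
        indices, resnums_per = [], []
        resnum_sets = []
        for c in chains:
            idx = np.flatnonzero(structure.chain_ids == c)
            if idx.size == 0:
                raise ValueError(f"no particles on chain {c!r}")
            indices.append(idx)
            rn = structure.residue_numbers[idx]
            resnums_per.append(rn)
            resnum_sets.append(frozenset(int(r) for r in rn))
        if len(set(resnum_sets)) != 1:
            raise ValueError("monomers differ in residue numbering")
        return indices, resnums_per, np.array(sorted(resnum_sets[0]))

    idx_a, rn_a, residues = monomer_info(chains_a)
    idx_b, rn_b, residues_b = monomer_info(chains_b)
    if not np.array_equal(residues, residues_b):
        raise ValueError("the two tetramers differ in residue numbering")
    all_a = np.concatenate(idx_a)
    all_b = np.concatenate(idx_b)

    # one sample mean per (monomer, replica): fraction of frames in contact
    sample_means = []  # list over replicas of (n_res, 8) arrays
    for traj in trajs:
        mat_a = _monomer_contact_matrix(traj, idx_a, all_b,
                                        residues, rn_a, params)
        mat_b = _monomer_contact_matrix(traj, idx_b, all_a,
                                        residues, rn_b, params)
        per_monomer = np.concatenate(
            [mat_a.mean(axis=2), mat_b.mean(axis=2)], axis=1)
        sample_means.append(per_monomer)
    stacked = np.concatenate(sample_means, axis=1)  # (n_res, 8 * n_replicas)
    mean = stacked.mean(axis=1)
    n = stacked.shape[1]
    sem = stacked.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ContactProbabilityProfile(
        residue_numbers=residues, mean=mean, sem=sem,
        n_monomers=len(chains_a) + len(chains_b), n_replicas=len(trajs),
    )


def contact_time_fraction(traj: Trajectory, set_a: np.ndarray,
                          set_b: np.ndarray,
                          params: ContactParameters = ContactParameters(),
                          min_pairs: int = 1) -> float:
    """Fraction of frames in which the two groups share at least
    ``min_pairs`` particle pairs inside the cutoff."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    per_frame = contacts_per_frame(traj, set_a, set_b, params)
    return float((per_frame >= min_pairs).mean())
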