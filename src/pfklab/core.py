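"""Structure, trajectory and sequence data model with format I/O.

Coordinates are stored in nm everywhere (PDB angstroms are converted on
read).  Residue numbering follows the source file (1-based author
numbering); chains are identified by author chain ID.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tables import AA1_TO_3, AA3_TO_1, STANDARD_AA3

NM_PER_ANGSTROM = 0.1


class StructureParseError(ValueError):
    """A coordinate or trajectory file could not be parsed."""


class SelectionError(ValueError):
    """A residue selection is malformed or unresolvable."""


@dataclass
class BeadStructure:
    """Named particles (atoms or coarse beads) with residue and chain
    identity, coordinates in nm, masses in Da and radii in nm.

    Arrays are parallel over particles and never reordered by analysis
    code; particle order is the file order.
    """

    particle_ids: np.ndarray          # int
    names: np.ndarray                 # str
    residue_names: np.ndarray         # 3-letter str
    residue_numbers: np.ndarray       # int, >=1
    chain_ids: np.ndarray             # str
    coords: np.ndarray                # (n, 3) float, nm
    masses: np.ndarray                # Da
    radii: np.ndarray                 # nm; may be nan until assigned

    def __post_init__(self) -> None:
        n = len(self.particle_ids)
        for name in ("names", "residue_names", "residue_numbers",
                     "chain_ids", "masses", "radii"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length != {n}")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_particles(self) -> int:
        return len(self.particle_ids)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Distinct (chain, residue number) pairs in particle order."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.residue_numbers):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def particle_indices(self, chain_id: str, residue_number: int) -> np.ndarray:
        return np.flatnonzero(
            (self.chain_ids == chain_id) & (self.residue_numbers == residue_number)
        )

    def subset(self, indices: np.ndarray) -> "BeadStructure":
        idx = np.asarray(indices, dtype=int)
        return BeadStructure(
            particle_ids=self.particle_ids[idx],
            names=self.names[idx],
            residue_names=self.residue_names[idx],
            residue_numbers=self.residue_numbers[idx],
            chain_ids=self.chain_ids[idx],
            coords=self.coords[idx],
            masses=self.masses[idx],
            radii=self.radii[idx],
        )

    def with_coords(self, coords: np.ndarray) -> "BeadStructure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain, in residue-number order;
        nonstandard residues become 'X'."""
        mask = self.chain_ids == chain_id
        resnums = self.residue_numbers[mask]
        resnames = self.residue_names[mask]
        seen: dict[int, str] = {}
        for num, name in zip(resnums, resnames):
            seen.setdefault(int(num), AA3_TO_1.get(str(name).upper(), "X"))
        return "".join(seen[k] for k in sorted(seen))


@dataclass
class Trajectory:
    """Ordered coordinate frames (nm) matching a parent BeadStructure."""

    frames: np.ndarray                # (n_frames, n_particles, 3) nm
    times: np.ndarray                 # ps, strictly increasing
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))  # nm
    periodic: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_particles, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_particles(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue-number ranges per chain."""

    ranges: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chain, first, last in self.ranges:
            if first > last:
                raise SelectionError(
                    f"inverted range {first}-{last} on chain {chain!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]],
                   chain_id: str = "A") -> "ResidueSelection":
        return cls(tuple((chain_id, int(a), int(b)) for a, b in pairs))


# Packaged selections for the PFKL filament interfaces and the
# Interface 1 fragment, in author numbering (chain set per use).
def pfkl_interface1_selection(chain_id: str = "A") -> ResidueSelection:
    from .tables import PFKL_INTERFACE1_RANGES
    return ResidueSelection.from_pairs(PFKL_INTERFACE1_RANGES, chain_id)


def pfkl_interface2_selection(chain_id: str = "A") -> ResidueSelection:
    from .tables import PFKL_INTERFACE2_RANGES
    return ResidueSelection.from_pairs(PFKL_INTERFACE2_RANGES, chain_id)


def pfkl_fragment_selection(chain_id: str = "A") -> ResidueSelection:
    from .tables import PFKL_FRAGMENT_RANGES
    return ResidueSelection.from_pairs(PFKL_FRAGMENT_RANGES, chain_id)


# --- format I/O (MDAnalysis-backed) ------------------------------------------

def _quiet_mda():
    import MDAnalysis as mda
    return mda


def _validate_pdb_text(path: Path) -> None:
    """Light pre-scan so malformed/truncated records fail with a line number
    instead of silently yielding a partial structure."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM") and len(line.rstrip("\n")) < 54:
            raise StructureParseError(
                f"{path}: truncated {rec} record at line {lineno}"
            )


def _validate_gro_text(path: Path) -> None:
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise StructureParseError(f"{path}: too short to be a GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise StructureParseError(
            f"{path}: line 2 is not an atom count"
        ) from exc
    if len(lines) < n_atoms + 3:
        raise StructureParseError(
            f"{path}: declares {n_atoms} atoms but ends at line {len(lines)}"
        )
    for lineno in range(3, 3 + n_atoms):
        if len(lines[lineno - 1]) < 44:
            raise StructureParseError(
                f"{path}: truncated atom record at line {lineno}"
            )


def read_structure(path: str | Path, fmt: str | None = None) -> BeadStructure:
    """Read a PDB or GRO coordinate file into a BeadStructure (nm).

    ``fmt`` is inferred from the suffix when omitted.  Particle order is
    preserved; masses default to 0 and radii to nan when the format does
    not carry them (assign radii before requesting SASA).
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise StructureParseError(f"unsupported structure format {fmt!r}")
    if fmt == "PDB":
        _validate_pdb_text(path)
    else:
        _validate_gro_text(path)

    mda = _quiet_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt)
        except Exception as exc:  # noqa: BLE001 - normalize reader errors
            raise StructureParseError(f"{path}: {exc}") from exc
        atoms = u.atoms
        n = len(atoms)
        if n == 0:
            raise StructureParseError(f"{path}: no particles found")
        try:
            chains = np.array([str(c) for c in atoms.chainIDs])
        except (mda.exceptions.NoDataError, AttributeError):
            try:
                chains = np.array([str(s) for s in atoms.segids])
            except (mda.exceptions.NoDataError, AttributeError):
                chains = np.full(n, "A")
        chains = np.where(np.char.str_len(np.char.strip(chains)) == 0,
                          "A", np.char.strip(chains))
        try:
            masses = np.asarray(atoms.masses, dtype=float)
        except (mda.exceptions.NoDataError, AttributeError):
            masses = np.zeros(n)
        coords_nm = np.asarray(atoms.positions, dtype=float) * NM_PER_ANGSTROM

    return BeadStructure(
        particle_ids=np.arange(1, n + 1),
        names=np.array([str(a) for a in atoms.names]),
        residue_names=np.array([str(r).upper() for r in atoms.resnames]),
        residue_numbers=np.asarray(atoms.resids, dtype=int),
        chain_ids=chains,
        coords=coords_nm,
        masses=masses,
        radii=np.full(n, np.nan),
    )


def _as_universe(structure: BeadStructure):
    """Build an in-memory MDAnalysis Universe mirroring the structure
    (positions in angstrom, MDAnalysis native units)."""
    mda = _quiet_mda()
    res_keys = structure.residue_keys()
    res_index = {key: i for i, key in enumerate(res_keys)}
    atom_resindex = np.array(
        [res_index[(str(c), int(r))]
         for c, r in zip(structure.chain_ids, structure.residue_numbers)]
    )
    seg_ids = sorted({key[0] for key in res_keys})
    seg_index = {seg: i for i, seg in enumerate(seg_ids)}
    res_segindex = np.array([seg_index[key[0]] for key in res_keys])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=structure.n_particles,
            n_residues=len(res_keys),
            n_segments=len(seg_ids),
            atom_resindex=atom_resindex,
            residue_segindex=res_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(x) for x in structure.names])
        u.add_TopologyAttr("masses", structure.masses)
        u.add_TopologyAttr("resnames",
                           [structure.residue_names[
                               structure.particle_indices(c, r)[0]]
                            for c, r in res_keys])
        u.add_TopologyAttr("resids", [r for _, r in res_keys])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("chainIDs",
                           [str(c) for c in structure.chain_ids])
        u.add_TopologyAttr(
            "elements",
            [_guess_element(str(n)) for n in structure.names],
        )
        u.atoms.positions = structure.coords / NM_PER_ANGSTROM
    return u


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_structure(structure: BeadStructure, path: str | Path,
                    fmt: str | None = None) -> None:
    """Write a BeadStructure as PDB or GRO (nm converted to the format's
    native unit)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    u = _as_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(path: str | Path, topology: BeadStructure,
                    periodic: bool | None = None) -> Trajectory:
    """Read an XTC or DCD trajectory against a BeadStructure topology."""
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    u = _as_universe(topology)
    mda = _quiet_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u.load_new(str(path))
        except (OSError, ValueError) as exc:
            msg = str(exc)
            raise StructureParseError(
                f"{path}: cannot read trajectory against a topology of "
                f"{topology.n_particles} particles ({msg})"
            ) from exc
        n_file = u.trajectory.n_atoms
        if n_file != topology.n_particles:
            raise StructureParseError(
                f"{path}: trajectory has {n_file} particles but topology "
                f"has {topology.n_particles}"
            )
        frames, times, boxes = [], [], []
        for ts in u.trajectory:
            frames.append(ts.positions.copy() * NM_PER_ANGSTROM)
            times.append(ts.time)
            dims = ts.dimensions
            boxes.append(dims[:3] * NM_PER_ANGSTROM
                         if dims is not None else np.zeros(3))
    box = boxes[-1]
    if periodic is None:
        periodic = bool(np.all(box > 0))
    return Trajectory(frames=np.array(frames), times=np.array(times),
                      box=box, periodic=periodic)


def write_trajectory(traj: Trajectory, path: str | Path,
                     topology: BeadStructure) -> None:
    """Write a Trajectory as XTC or DCD."""
    path = Path(path)
    if traj.n_particles != topology.n_particles:
        raise ValueError(
            f"trajectory has {traj.n_particles} particles but topology "
            f"has {topology.n_particles}"
        )
    mda = _quiet_mda()
    u = _as_universe(topology)
    box_a = traj.box / NM_PER_ANGSTROM
    dims = np.array([*box_a, 90.0, 90.0, 90.0], dtype=np.float32)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_particles) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i] / NM_PER_ANGSTROM
                u.trajectory.ts.time = traj.times[i]
                u.trajectory.ts.frame = i
                if np.all(traj.box > 0):
                    u.trajectory.ts.dimensions = dims
                w.write(u.atoms)


# --- selection and mutation ---------------------------------------------------

@dataclass
class SelectionResult:
    particle_indices: np.ndarray
    residue_keys: list[tuple[str, int]]
    missing: list[tuple[str, int]]

    @property
    def n_residues(self) -> int:
        return len(self.residue_keys)


def select_residues(structure: BeadStructure,
                    selection: ResidueSelection) -> SelectionResult:
    """Resolve residue ranges to a deduplicated particle set.

    Residue numbers absent from the structure are skipped silently but
    reported in ``missing`` — cryoEM models routinely have gaps.
    """
    wanted: dict[tuple[str, int], None] = {}
    for chain, first, last in selection.ranges:
        for num in range(first, last + 1):
            wanted.setdefault((chain, num), None)
    present: list[tuple[str, int]] = []
    missing: list[tuple[str, int]] = []
    idx_parts: list[np.ndarray] = []
    for key in wanted:
        idx = structure.particle_indices(*key)
        if idx.size:
            present.append(key)
            idx_parts.append(idx)
        else:
            missing.append(key)
    indices = (np.unique(np.concatenate(idx_parts))
               if idx_parts else np.empty(0, dtype=int))
    return SelectionResult(particle_indices=indices,
                           residue_keys=present, missing=missing)


class MutationError(ValueError):
    """A point mutation could not be applied."""


BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT",
                            "BB"})  # BB = coarse backbone bead


def mutate_residue(structure_or_sequence, chain_id: str | None,
                   position: int, new_residue: str):
    """Point-mutate one residue, e.g. the Loop 2 N702T substitution.

    On a sequence (str), ``chain_id`` is ignored and ``position`` is the
    1-based residue number; returns the mutated sequence.  On a
    BeadStructure, the residue name is changed and side-chain particles
    beyond the shared backbone are dropped (side-chain rebuilding is out
    of scope).  Identity mutations return an equal copy.
    """
    code3 = new_residue.upper()
    if len(code3) == 1:
        if code3 not in AA1_TO_3:
            raise MutationError(f"unknown residue code {new_residue!r}")
        code3 = AA1_TO_3[code3]
    if code3 not in STANDARD_AA3:
        raise MutationError(f"{new_residue!r} is not a standard amino acid")

    if isinstance(structure_or_sequence, str):
        seq = structure_or_sequence
        if not 1 <= position <= len(seq):
            raise MutationError(
                f"position {position} outside sequence of length {len(seq)}"
            )
        new1 = AA3_TO_1[code3]
        return seq[:position - 1] + new1 + seq[position:]

    structure: BeadStructure = structure_or_sequence
    chain = chain_id if chain_id is not None else "A"
    idx = structure.particle_indices(chain, position)
    if idx.size == 0:
        raise MutationError(
            f"no residue {position} on chain {chain!r}"
        )
    old_name = str(structure.residue_names[idx[0]])
    if old_name == code3:
        return structure.subset(np.arange(structure.n_particles))
    keep = np.ones(structure.n_particles, dtype=bool)
    sidechain = [i for i in idx
                 if str(structure.names[i]).upper() not in BACKBONE_ATOMS]
    keep[sidechain] = False
    out = structure.subset(np.flatnonzero(keep))
    new_idx = out.particle_indices(chain, position)
    out.residue_names[new_idx] = code3
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
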