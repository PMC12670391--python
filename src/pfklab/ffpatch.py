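"""Coarse-grained topology model: GROMACS-dialect .itp/.top I/O, elastic
network construction, and the hydrogen-bonding virtual-site Lennard-Jones
patch.

The patch adds, on top of the unmodified base interactions, a massless
virtual site at the side-chain center of mass of each selected residue
(Asn702 in the liver-isoform fragment) carrying an LJ term that acts only
between sites of its own type — sigma = 0.39630469 nm, epsilon =
22.76096 kJ/mol — and is exactly zero against every other particle type.
This restores, at coarse-grained resolution, the specific side chain to
side chain hydrogen bonding that the unpatched model averages away, and
it refuses to apply where the selected residue is not an asparagine
(e.g. after the filament-disrupting N702T mutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import BeadStructure

# --- data model ----------------------------------------------------------------


@dataclass(frozen=True)
class AtomType:
    name: str
    mass: float
    charge: float
    ptype: str          # A (atom) or V (virtual)
    sigma: float        # nm
    epsilon: float      # kJ/mol


@dataclass(frozen=True)
class NonbondParam:
    type_a: str
    type_b: str
    funct: int
    sigma: float
    epsilon: float


@dataclass(frozen=True)
class TopAtom:
    index: int          # 1-based within the molecule
    type: str
    resnr: int
    resname: str
    name: str
    cgnr: int
    charge: float
    mass: float


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    funct: int
    r0: float           # nm
    k: float            # kJ mol^-1 nm^-2


@dataclass(frozen=True)
class Constraint:
    i: int
    j: int
    funct: int
    r0: float


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k_atom: int
    funct: int
    theta0: float
    k: float


@dataclass(frozen=True)
class VirtualSiteN:
    site: int
    funct: int          # 1 = center of geometry, 2 = center of mass
    constructing: tuple[int, ...]


@dataclass(frozen=True)
class Exclusion:
    atoms: tuple[int, ...]


@dataclass
class MoleculeBlock:
    name: str
    nrexcl: int
    atoms: list[TopAtom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    constraints: list[Constraint] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    virtual_sitesn: list[VirtualSiteN] = field(default_factory=list)
    exclusions: list[Exclusion] = field(default_factory=list)

    def copy(self) -> "MoleculeBlock":
        return MoleculeBlock(
            name=self.name, nrexcl=self.nrexcl,
            atoms=list(self.atoms), bonds=list(self.bonds),
            constraints=list(self.constraints), angles=list(self.angles),
            virtual_sitesn=list(self.virtual_sitesn),
            exclusions=list(self.exclusions),
        )


@dataclass
class CGTopology:
    """A coarse-grained topology in the GROMACS dialect."""

    defaults: tuple | None = None     # (nbfunc, comb-rule)
    atomtypes: list[AtomType] = field(default_factory=list)
    nonbond_params: list[NonbondParam] = field(default_factory=list)
    molecules: list[MoleculeBlock] = field(default_factory=list)
    system_name: str | None = None
    molecule_counts: list[tuple[str, int]] = field(default_factory=list)

    def copy(self) -> "CGTopology":
        return CGTopology(
            defaults=self.defaults,
            atomtypes=list(self.atomtypes),
            nonbond_params=list(self.nonbond_params),
            molecules=[m.copy() for m in self.molecules],
            system_name=self.system_name,
            molecule_counts=list(self.molecule_counts),
        )

    def molecule(self, name: str) -> MoleculeBlock:
        for mol in self.molecules:
            if mol.name == name:
                return mol
        raise KeyError(f"no moleculetype named {name!r}")

    def validate(self) -> None:
        type_names = {t.name for t in self.atomtypes}
        for nb in self.nonbond_params:
            for t in (nb.type_a, nb.type_b):
                if type_names and t not in type_names:
                    raise ValueError(f"nonbond_params references unknown type {t!r}")
        for mol in self.molecules:
            n = len(mol.atoms)
            ids = {a.index for a in mol.atoms}
            if ids != set(range(1, n + 1)):
                raise ValueError(
                    f"molecule {mol.name!r}: atom indices must be 1..{n}")
            def check(i, what):
                if i not in ids:
                    raise ValueError(
                        f"molecule {mol.name!r}: {what} references atom {i}")
            for b in mol.bonds:
                check(b.i, "bond"); check(b.j, "bond")
            for c in mol.constraints:
                check(c.i, "constraint"); check(c.j, "constraint")
            for a in mol.angles:
                check(a.i, "angle"); check(a.j, "angle"); check(a.k_atom, "angle")
            for v in mol.virtual_sitesn:
                check(v.site, "virtual site")
                for i in v.constructing:
                    check(i, "virtual site")


# --- parser / writer -----------------------------------------------------------


class TopologyParseError(ValueError):
    """A topology file could not be parsed."""


_KNOWN_SECTIONS = {
    "defaults", "atomtypes", "nonbond_params", "moleculetype", "atoms",
    "bonds", "constraints", "angles", "virtual_sitesn", "exclusions",
    "system", "molecules",
}
_MOLECULE_SECTIONS = {"atoms", "bonds", "constraints", "angles",
                      "virtual_sitesn", "exclusions"}


def _strip_comment(line: str) -> str:
    return line.split(";", 1)[0].strip()


def parse_topology(path: str | Path) -> CGTopology:
    """Parse a GROMACS-dialect .itp/.top file.  Unknown sections raise
    TopologyParseError naming the section and line."""
    path = Path(path)
    top = CGTopology()
    current: str | None = None
    mol: MoleculeBlock | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = _strip_comment(raw)
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise TopologyParseError(
                    f"{path}:{lineno}: malformed section header {raw!r}")
            section = line[1:-1].strip().lower()
            if section not in _KNOWN_SECTIONS:
                raise TopologyParseError(
                    f"{path}:{lineno}: unknown section [{section}]")
            if section in _MOLECULE_SECTIONS and mol is None:
                raise TopologyParseError(
                    f"{path}:{lineno}: [{section}] outside a moleculetype")
            current = section
            continue
        tok = line.split()
        try:
            if current == "defaults":
                top.defaults = tuple(tok)
            elif current == "atomtypes":
                # name mass charge ptype sigma epsilon
                top.atomtypes.append(AtomType(
                    tok[0], float(tok[1]), float(tok[2]), tok[3],
                    float(tok[4]), float(tok[5])))
            elif current == "nonbond_params":
                top.nonbond_params.append(NonbondParam(
                    tok[0], tok[1], int(tok[2]),
                    float(tok[3]), float(tok[4])))
            elif current == "moleculetype":
                mol = MoleculeBlock(name=tok[0], nrexcl=int(tok[1]))
                top.molecules.append(mol)
            elif current == "atoms":
                mol.atoms.append(TopAtom(
                    int(tok[0]), tok[1], int(tok[2]), tok[3], tok[4],
                    int(tok[5]),
                    float(tok[6]) if len(tok) > 6 else 0.0,
                    float(tok[7]) if len(tok) > 7 else 0.0))
            elif current == "bonds":
                mol.bonds.append(Bond(int(tok[0]), int(tok[1]), int(tok[2]),
                                      float(tok[3]), float(tok[4])))
            elif current == "constraints":
                mol.constraints.append(Constraint(
                    int(tok[0]), int(tok[1]), int(tok[2]), float(tok[3])))
            elif current == "angles":
                mol.angles.append(Angle(
                    int(tok[0]), int(tok[1]), int(tok[2]), int(tok[3]),
                    float(tok[4]), float(tok[5])))
            elif current == "virtual_sitesn":
                mol.virtual_sitesn.append(VirtualSiteN(
                    int(tok[0]), int(tok[1]),
                    tuple(int(t) for t in tok[2:])))
            elif current == "exclusions":
                mol.exclusions.append(Exclusion(tuple(int(t) for t in tok)))
            elif current == "system":
                top.system_name = line
            elif current == "molecules":
                top.molecule_counts.append((tok[0], int(tok[1])))
            else:
                raise TopologyParseError(
                    f"{path}:{lineno}: data before any section header")
        except (ValueError, IndexError) as exc:
            if isinstance(exc, TopologyParseError):
                raise
            raise TopologyParseError(
                f"{path}:{lineno}: cannot parse [{current}] record "
                f"{raw!r} ({exc})") from exc
    top.validate()
    return top


_F = "{:.6f}"


def _fmt(x: float) -> str:
    """Fixed 8-significant-digit format: stable round trips."""
    return f"{x:.8g}"


def write_topology(top: CGTopology, path: str | Path) -> None:
    """Write a CGTopology in the GROMACS dialect.  Column layout:
    whitespace-separated fields in the canonical section order; floats in
    %.8g so parse(write(parse(f))) is a fixed point."""
    lines: list[str] = []
    if top.defaults is not None:
        lines += ["[ defaults ]", " ".join(str(t) for t in top.defaults), ""]
    if top.atomtypes:
        lines.append("[ atomtypes ]")
        lines.append("; name mass charge ptype sigma epsilon")
        for t in top.atomtypes:
            lines.append(f"{t.name:>6} {_fmt(t.mass):>10} {_fmt(t.charge):>8} "
                         f"{t.ptype:>2} {_fmt(t.sigma):>12} {_fmt(t.epsilon):>12}")
        lines.append("")
    if top.nonbond_params:
        lines.append("[ nonbond_params ]")
        lines.append("; type_a type_b funct sigma epsilon")
        for nb in top.nonbond_params:
            lines.append(f"{nb.type_a:>6} {nb.type_b:>6} {nb.funct:>2} "
                         f"{_fmt(nb.sigma):>12} {_fmt(nb.epsilon):>12}")
        lines.append("")
    for mol in top.molecules:
        lines += ["[ moleculetype ]", f"{mol.name} {mol.nrexcl}", ""]
        lines.append("[ atoms ]")
        lines.append("; nr type resnr resname atom cgnr charge mass")
        for a in mol.atoms:
            lines.append(f"{a.index:>5} {a.type:>6} {a.resnr:>5} "
                         f"{a.resname:>5} {a.name:>5} {a.cgnr:>5} "
                         f"{_fmt(a.charge):>9} {_fmt(a.mass):>10}")
        lines.append("")
        if mol.bonds:
            lines.append("[ bonds ]")
            for b in mol.bonds:
                lines.append(f"{b.i:>5} {b.j:>5} {b.funct:>2} "
                             f"{_fmt(b.r0):>10} {_fmt(b.k):>10}")
            lines.append("")
        if mol.constraints:
            lines.append("[ constraints ]")
            for c in mol.constraints:
                lines.append(f"{c.i:>5} {c.j:>5} {c.funct:>2} {_fmt(c.r0):>10}")
            lines.append("")
        if mol.angles:
            lines.append("[ angles ]")
            for a in mol.angles:
                lines.append(f"{a.i:>5} {a.j:>5} {a.k_atom:>5} {a.funct:>2} "
                             f"{_fmt(a.theta0):>10} {_fmt(a.k):>10}")
            lines.append("")
        if mol.virtual_sitesn:
            lines.append("[ virtual_sitesn ]")
            for v in mol.virtual_sitesn:
                constructing = " ".join(f"{i:>4}" for i in v.constructing)
                lines.append(f"{v.site:>5} {v.funct:>2} {constructing}")
            lines.append("")
        if mol.exclusions:
            lines.append("[ exclusions ]")
            for e in mol.exclusions:
                lines.append(" ".join(f"{i:>4}" for i in e.atoms))
            lines.append("")
    if top.system_name is not None:
        lines += ["[ system ]", top.system_name, ""]
    if top.molecule_counts:
        lines.append("[ molecules ]")
        for name, count in top.molecule_counts:
            lines.append(f"{name:>10} {count:>6}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# --- elastic network -----------------------------------------------------------

DEFAULT_EN_FORCE_CONSTANT = 700.0   # kJ mol^-1 nm^-2
DEFAULT_EN_CUTOFF_NM = 0.9


@dataclass(frozen=True)
class ElasticBond:
    i: int              # particle indices into the structure (0-based)
    j: int
    r0: float           # nm
    k: float            # kJ mol^-1 nm^-2


def build_elastic_network(structure: BeadStructure,
                          backbone_selector: Callable[[str], bool] | None = None,
                          k: float = DEFAULT_EN_FORCE_CONSTANT,
                          cutoff: float = DEFAULT_EN_CUTOFF_NM
                          ) -> list[ElasticBond]:
    """Harmonic springs between backbone beads closer than the cutoff,
    excluding directly bonded (sequence-adjacent) neighbors; intra-chain
    only.  Equilibrium length is the observed distance; one bond per
    unordered pair (i < j).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if backbone_selector is None:
        backbone_selector = lambda name: name.upper() in ("BB", "CA")
    bb = np.flatnonzero([backbone_selector(str(n)) for n in structure.names])
    if bb.size == 0:
        raise ValueError("no backbone beads found")
    coords = structure.coords[bb]
    chains = structure.chain_ids[bb]
    resnums = structure.residue_numbers[bb]
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    bonds = []
    for a, b in sorted(tree.query_pairs(r=cutoff)):
        if chains[a] != chains[b]:
            continue
        if abs(int(resnums[a]) - int(resnums[b])) <= 1:
            continue  # directly bonded neighbors carry real bonds
        r0 = float(np.linalg.norm(coords[b] - coords[a]))
        if r0 >= cutoff:
            continue
        bonds.append(ElasticBond(int(bb[a]), int(bb[b]), r0, float(k)))
    return bonds


def elastic_energy(bonds: Sequence[ElasticBond], coords: np.ndarray) -> float:
    """Total harmonic energy 1/2 k (r - r0)^2 over the network (kJ/mol)."""
    e = 0.0
    for b in bonds:
        r = float(np.linalg.norm(coords[b.j] - coords[b.i]))
        e += 0.5 * b.k * (r - b.r0) ** 2
    return e


# --- hydrogen-bond virtual-site patch -------------------------------------------

HB_SIGMA_NM = 0.39630469
HB_EPSILON_KJ_MOL = 22.76096
HB_SITE_TYPE = "VSHB"
HB_SITE_NAME = "VHB"


@dataclass(frozen=True)
class HBTerm:
    """One added hydrogen-bonding LJ pair term on side-chain virtual sites."""

    residue_numbers: tuple[int, ...] = (702,)
    residue_name: str = "ASN"
    sigma: float = HB_SIGMA_NM
    epsilon: float = HB_EPSILON_KJ_MOL
    intermolecular_only: bool = True
    site_type: str = HB_SITE_TYPE

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")


class PatchError(ValueError):
    """The topology patch cannot be applied."""


def lj_pair_energy(r: float | np.ndarray, sigma: float,
                   epsilon: float) -> float | np.ndarray:
    """Lennard-Jones 12-6 energy V(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]
    in kJ/mol; minimum -epsilon at r = 2^(1/6) sigma."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    sr6 = (sigma / r) ** 6
    v = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return float(v) if v.ndim == 0 else v


SIDECHAIN_PREFIXES = ("SC",)


def _sidechain_atoms(mol: MoleculeBlock, resnr: int) -> list[TopAtom]:
    return [a for a in mol.atoms
            if a.resnr == resnr and a.name.upper().startswith(SIDECHAIN_PREFIXES)]


def add_hb_virtual_site_term(top: CGTopology, term: HBTerm = HBTerm()
                             ) -> CGTopology:
    """Return a patched copy with the hydrogen-bonding virtual-site term.

    For every selected residue in every molecule block: verifies the
    residue name (refusing, e.g., a Thr at position 702 after the N702T
    mutation), appends one massless virtual site built as the
    mass-weighted center of the side-chain beads, and registers a new
    particle type whose LJ interaction is (sigma, epsilon) with itself
    and exactly zero against every pre-existing type.  All pre-existing
    entries are left untouched.
    """
    existing = {t.name for t in top.atomtypes}
    if term.site_type in existing:
        raise PatchError(f"type {term.site_type!r} already present")
    patched = top.copy()

    n_sites = 0
    for mol in patched.molecules:
        res_present = {a.resnr for a in mol.atoms}
        for resnr in term.residue_numbers:
            if resnr not in res_present:
                continue
            resname = next(a.resname.upper() for a in mol.atoms
                           if a.resnr == resnr)
            if resname != term.residue_name.upper():
                raise PatchError(
                    f"molecule {mol.name!r}: residue {resnr} is {resname}, "
                    f"not {term.residue_name.upper()}; the added term models "
                    "an asparagine side-chain hydrogen bond and does not "
                    "apply to a mutated residue (e.g. N702T)"
                )
            sc = _sidechain_atoms(mol, resnr)
            if not sc:
                raise PatchError(
                    f"molecule {mol.name!r}: residue {resnr} has no "
                    "side-chain bead to host the virtual site"
                )
            site_index = len(mol.atoms) + 1
            mol.atoms.append(TopAtom(
                index=site_index, type=term.site_type, resnr=resnr,
                resname=resname, name=HB_SITE_NAME,
                cgnr=sc[0].cgnr, charge=0.0, mass=0.0))
            mol.virtual_sitesn.append(VirtualSiteN(
                site=site_index, funct=2,
                constructing=tuple(a.index for a in sc)))
            mol.exclusions.append(Exclusion(
                (site_index, *(a.index for a in sc))))
            n_sites += 1
    if n_sites == 0:
        raise PatchError(
            f"no molecule contains residues {term.residue_numbers}")

    patched.atomtypes.append(AtomType(
        name=term.site_type, mass=0.0, charge=0.0, ptype="V",
        sigma=0.0, epsilon=0.0))
    patched.nonbond_params.append(NonbondParam(
        term.site_type, term.site_type, 1, term.sigma, term.epsilon))
    for other in sorted(existing):
        patched.nonbond_params.append(NonbondParam(
            term.site_type, other, 1, 0.0, 0.0))
    patched.validate()
    return patched


def hb_site_positions(structure: BeadStructure, term: HBTerm = HBTerm()
                      ) -> dict[tuple[str, int], np.ndarray]:
    """Mass-weighted side-chain center per selected residue per chain,
    applying the same residue-name check as the topology patch."""
    sites: dict[tuple[str, int], np.ndarray] = {}
    for chain, resnum in structure.residue_keys():
        if resnum not in term.residue_numbers:
            continue
        idx = structure.particle_indices(chain, resnum)
        resname = str(structure.residue_names[idx[0]]).upper()
        if resname != term.residue_name.upper():
            raise PatchError(
                f"chain {chain} residue {resnum} is {resname}, not "
                f"{term.residue_name.upper()}"
            )
        sc = [i for i in idx
              if str(structure.names[i]).upper().startswith(SIDECHAIN_PREFIXES)]
        if not sc:
            raise PatchError(
                f"chain {chain} residue {resnum} has no side-chain bead")
        masses = structure.masses[sc]
        if masses.sum() <= 0:
            com = structure.coords[sc].mean(axis=0)
        else:
            com = (structure.coords[sc] * masses[:, None]).sum(0) / masses.sum()
        sites[(chain, resnum)] = com
    if not sites:
        raise PatchError(f"no residues {term.residue_numbers} in structure")
    return sites


def added_hb_energy(structure: BeadStructure, term: HBTerm = HBTerm()
                    ) -> float:
    """Total energy contributed by the added term on a (multi-chain)
    structure: LJ over all site pairs on distinct chains (or all pairs if
    the term is not intermolecular-only)."""
    sites = hb_site_positions(structure, term)
    keys = sorted(sites)
    e = 0.0
    for a in range(len(keys)):
        for b in range(a + 1, len(keys)):
            if term.intermolecular_only and keys[a][0] == keys[b][0]:
                continue
            r = float(np.linalg.norm(sites[keys[b]] - sites[keys[a]]))
            e += lj_pair_energy(r, term.sigma, term.epsilon)
    return e


@dataclass(frozen=True)
class FlatBottomRestraint:
    """Configurable flat-bottom position restraint record (no default
    radius/force constant is asserted; both must be supplied)."""

    residue_range: tuple[int, int]
    radius: float       # nm
    k: float            # kJ mol^-1 nm^-2

    def energy(self, displacement: float) -> float:
        over = max(0.0, abs(displacement) - self.radius)
        return 0.5 * self.k * over ** 2
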