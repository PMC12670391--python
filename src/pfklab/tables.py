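"""Reference tables: maximum per-residue SASA, residue classification,
van der Waals and coarse-bead radii, amino-acid codes, and the packaged
PFKL filament-interface residue selections.

All lengths are nm and all areas nm**2 throughout the package.
"""

from __future__ import annotations

# --- amino-acid codes -------------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA3 = frozenset(AA3_TO_1)

# --- maximum solvent accessibility (Tien et al. 2013), nm^2 -----------------
# "theoretical" = analytic Gly-X-Gly maxima; "empirical" = observed maxima.
# Published in A^2; stored here in nm^2 (divide by 100).

MAX_SASA_THEORETICAL_NM2 = {
    "ALA": 1.290, "ARG": 2.740, "ASN": 1.950, "ASP": 1.930, "CYS": 1.670,
    "GLN": 2.250, "GLU": 2.230, "GLY": 1.040, "HIS": 2.240, "ILE": 1.970,
    "LEU": 2.010, "LYS": 2.360, "MET": 2.240, "PHE": 2.400, "PRO": 1.590,
    "SER": 1.550, "THR": 1.720, "TRP": 2.850, "TYR": 2.630, "VAL": 1.740,
}

MAX_SASA_EMPIRICAL_NM2 = {
    "ALA": 1.210, "ARG": 2.650, "ASN": 1.870, "ASP": 1.870, "CYS": 1.480,
    "GLN": 2.140, "GLU": 2.140, "GLY": 0.970, "HIS": 2.160, "ILE": 1.950,
    "LEU": 1.910, "LYS": 2.300, "MET": 2.030, "PHE": 2.280, "PRO": 1.540,
    "SER": 1.430, "THR": 1.630, "TRP": 2.640, "TYR": 2.550, "VAL": 1.650,
}

MAX_SASA_TABLES = {
    "theoretical": MAX_SASA_THEORETICAL_NM2,
    "empirical": MAX_SASA_EMPIRICAL_NM2,
}

# --- radii ------------------------------------------------------------------
# Element van der Waals radii (Bondi), nm — used for atomistic inputs.

VDW_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152,
    "S": 0.180, "P": 0.180, "F": 0.147, "CL": 0.175,
    "BR": 0.185, "I": 0.198, "SE": 0.190,
}

# Coarse-bead radii by size class: half the LJ sigma of the bead class
# (regular 0.47 nm, small 0.41 nm, tiny 0.34 nm).  Keyed by the leading
# size prefix of the bead-type name; override per analysis via config.

CG_BEAD_RADII_NM = {
    "regular": 0.235,
    "small": 0.205,
    "tiny": 0.170,
}

DEFAULT_BEAD_RADIUS_NM = CG_BEAD_RADII_NM["regular"]


def bead_radius_for_type(type_name: str) -> float:
    """Radius for a coarse bead type name following the S*/T* size prefix
    convention; anything else gets the regular-bead radius."""
    if type_name[:1] in ("S", "s"):
        return CG_BEAD_RADII_NM["small"]
    if type_name[:1] in ("T", "t"):
        return CG_BEAD_RADII_NM["tiny"]
    return CG_BEAD_RADII_NM["regular"]


# --- residue classification (Pommie et al. 2004, IMGT) ----------------------
# Three axes: charge, polarity, hydropathy.  One-letter keys.

CHARGE_CLASS = {}
for _aa in "KRH":
    CHARGE_CLASS[_aa] = "positive"
for _aa in "DE":
    CHARGE_CLASS[_aa] = "negative"
for _aa in "ANCQGILMFPSTWYV":
    CHARGE_CLASS[_aa] = "uncharged"

POLARITY_CLASS = {}
for _aa in "RNDCEQGHKSTY":
    POLARITY_CLASS[_aa] = "polar"
for _aa in "AILMFPWV":
    POLARITY_CLASS[_aa] = "nonpolar"

HYDROPATHY_CLASS = {}
for _aa in "ACILMFWV":
    HYDROPATHY_CLASS[_aa] = "hydrophobic"
for _aa in "GHPSTY":
    HYDROPATHY_CLASS[_aa] = "neutral"
for _aa in "RNDQEK":
    HYDROPATHY_CLASS[_aa] = "hydrophilic"

CLASS_AXES = {
    "charge": CHARGE_CLASS,
    "polarity": POLARITY_CLASS,
    "hydropathy": HYDROPATHY_CLASS,
}

# --- packaged PFKL filament interface selections ----------------------------
# Author numbering of the deposited PFKL filament model.  Interface 1
# comprises Glu396-Ser401, Gln476-His490, Loop 1 (Ala510-Ile519) and
# Loop 2 (Val693-Asp705); Interface 2 comprises Ala327-Lys356,
# Gln372-Ser377 and Leu712-Ala718.

PFKL_INTERFACE1_RANGES = ((396, 401), (476, 490), (510, 519), (693, 705))
PFKL_INTERFACE2_RANGES = ((327, 356), (372, 377), (712, 718))
PFKL_LOOP1_RANGE = (510, 519)
PFKL_LOOP2_RANGE = (693, 705)

# The fragment used for interface free-energy work: the 237 residues in
# close proximity to Interface 1.
PFKL_FRAGMENT_RANGES = ((375, 540), (670, 740))

KB_KJ_PER_MOL_K = 0.0083144626
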