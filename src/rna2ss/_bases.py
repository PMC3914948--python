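"""Standard nucleobase geometry and chemistry tables.

Coordinates are the standard reference-frame base geometries of Olson et
al. (the frame convention used throughout nucleic-acid structure analysis):
each base lies in the z = 0 plane, the +y axis points along the
Watson-Crick edge toward the backbone, and a Watson-Crick partner is
obtained by the 2-fold rotation about x, ``(x, y, z) -> (x, -y, -z)``.
Units are angstroms.
"""

from __future__ import annotations

import numpy as np

# Base-frame atom coordinates (x, y, z) for the four standard ribonucleobases,
# including C1' so glycosidic-bond geometry is available.
STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "U": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.131, 0.000),
        "O2": (-2.563, 2.608, 0.000),
        "N3": (-0.302, 2.397, 0.000),
        "C4": (0.989, 2.884, 0.000),
        "O4": (1.935, 2.094, 0.000),
        "C5": (1.089, 4.311, 0.000),
        "C6": (-0.024, 5.053, 0.000),
    },
}

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})

# Ring atoms in perimeter order (used for frame fitting and ring polygons).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

# Glycosidic nitrogen per base.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

# Hydrogen-bond capable heavy atoms on the base moiety.
POLAR_ATOMS: dict[str, frozenset[str]] = {
    "A": frozenset({"N1", "N3", "N6", "N7"}),
    "G": frozenset({"N1", "N2", "N3", "N7", "O6"}),
    "C": frozenset({"O2", "N3", "N4"}),
    "U": frozenset({"O2", "N3", "O4"}),
}

# Leontis-Westhof interaction edges: which polar atoms present each edge.
# Some atoms legitimately sit on two edges (e.g. U O4 on both WC and
# Hoogsteen); edge assignment counts contacts per edge and breaks ties
# by WC > Hoogsteen > Sugar priority.
EDGE_ATOMS: dict[str, dict[str, frozenset[str]]] = {
    "A": {
        "WC": frozenset({"N1", "N6"}),
        "Hoogsteen": frozenset({"N6", "N7"}),
        "Sugar": frozenset({"N3"}),
    },
    "G": {
        "WC": frozenset({"N1", "N2", "O6"}),
        "Hoogsteen": frozenset({"O6", "N7"}),
        "Sugar": frozenset({"N2", "N3"}),
    },
    "C": {
        "WC": frozenset({"O2", "N3", "N4"}),
        "Hoogsteen": frozenset({"N4"}),
        "Sugar": frozenset({"O2"}),
    },
    "U": {
        "WC": frozenset({"O2", "N3", "O4"}),
        "Hoogsteen": frozenset({"O4"}),
        "Sugar": frozenset({"O2"}),
    },
}

EDGE_PRIORITY = ("WC", "Hoogsteen", "Sugar")

# Parent bases of commonly deposited modified ribonucleotides.  Pairing
# geometry follows the parent base; residues with codes outside this table
# and outside {A,C,G,U} are excluded from analysis with a warning.
MODIFIED_PARENT: dict[str, str] = {
    "PSU": "U",  # pseudouridine
    "H2U": "U",  # dihydrouridine
    "4SU": "U",  # 4-thiouridine
    "OMU": "U",  # 2'-O-methyluridine
    "UR3": "U",  # 3-methyluridine
    "5MU": "U",  # ribothymidine
    "3MU": "U",
    "1MA": "A",  # 1-methyladenosine
    "2MA": "A",
    "MA6": "A",  # dimethyladenosine
    "A2M": "A",  # 2'-O-methyladenosine
    "6MZ": "A",
    "5MC": "C",  # 5-methylcytidine
    "OMC": "C",  # 2'-O-methylcytidine
    "4OC": "C",
    "1MG": "G",  # 1-methylguanosine
    "2MG": "G",
    "M2G": "G",  # N2,N2-dimethylguanosine
    "7MG": "G",  # 7-methylguanosine
    "G7M": "G",
    "OMG": "G",  # 2'-O-methylguanosine
    "QUO": "G",  # queuosine
    "YG": "G",   # wybutosine
}

STANDARD_BASES = frozenset({"A", "C", "G", "U"})

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Unordered parent-base combinations accepted as canonical when the pair is
# cis Watson-Crick / Watson-Crick (A-U, G-C and the G-U wobble).
CANONICAL_COMBOS = frozenset(
    {frozenset({"A", "U"}), frozenset({"G", "C"}), frozenset({"G", "U"})}
)


def parent_base(residue_name: str) -> str | None:
    """Return A/C/G/U for a standard or recognized modified residue code."""
    name = residue_name.strip().upper()
    if name in STANDARD_BASES:
        return name
    return MODIFIED_PARENT.get(name)


def template_coords(base: str, atom_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Stack standard-frame coordinates for `atom_names` of `base`."""
    table = STANDARD_BASE_COORDS[base]
    if atom_names is None:
        atom_names = RING_ATOMS[base]
    return np.array([table[a] for a in atom_names], dtype=float)
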