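"""Curated structural annotations for human Ras-family complexes.

Binding interfaces of twenty-one Ras complex groups (PDB entries sharing an
interface are grouped under the first code), given as residue labels in shared
HRas-equivalent numbering, together with the twenty-two positions specifically
conserved among divergent-but-interacting Ras pairs and the classical Ras
functional regions.

Curation notes:

* Group members listed in ``COMPLEX_MEMBERS`` are sequence-identical deposits
  sharing one interface definition.
* The Exo84–RalA interface (1ZC3) is deposited in RalA numbering; its buried
  aromatic F82 corresponds to HRas Y71 (RalA numbering runs eleven ahead of
  HRas in this region) and is stored here as position 71.
* The residue letters label the HRas-equivalent position; for non-HRas family
  members the deposited residue type can differ.
"""

from __future__ import annotations

import re

__all__ = [
    "COMPLEX_INTERFACES",
    "COMPLEX_MEMBERS",
    "COMPLEX_CATEGORIES",
    "DIRP_POSITIONS",
    "FUNCTIONAL_REGIONS",
    "parse_position",
]

_LABEL = re.compile(r"^([A-Z])?\s*(\d+)$")


def parse_position(label: str | int) -> int:
    """Residue number of a position label ('Y32' or 32 -> 32)."""
    if isinstance(label, int):
        return label
    m = _LABEL.match(label.strip())
    if not m:
        raise ValueError(f"unparseable residue label {label!r}")
    return int(m.group(2))


#: Interface residues of each complex group (HRas-equivalent labels).
COMPLEX_INTERFACES: dict[str, list[str]] = {
    "1LFD": [
        "G12", "Y32", "D33", "P34", "I36", "E37", "D38", "S39", "Y40",
        "Q61", "E62", "E63", "Y64", "S65", "A66", "M67",
    ],
    "1NVU": [
        "S17", "T20", "I21", "Q22", "I24", "N26", "H27", "D30", "E31", "Y32",
        "D33", "P34", "I36", "E37", "D38", "Y40", "K42", "Q43", "V44", "D54",
        "I55", "D57", "A59", "G60", "Q61", "E63", "Y64", "S65", "A66", "M67",
        "D69", "Q70", "Y71", "R73", "R102", "R149",
    ],
    "1XD2": [
        "Q22", "I24", "N26", "H27", "D33", "P34", "I36", "E37", "D38", "K42",
        "Q43", "V44", "L56", "E63", "Y64", "A66", "M67", "Q70", "Y71", "R149",
    ],
    "1BKD": [
        "S17", "I21", "Y32", "P34", "Y40", "D54", "I55", "D57", "A59", "G60",
        "Q61", "E63", "Y64", "S65", "A66", "M67", "D69", "Q70", "Y71", "R73",
        "R102",
    ],
    "3CF6": [
        "S17", "T20", "I21", "H27", "Y32", "P34", "E37", "Y40", "D54", "I55",
        "L56", "D57", "A59", "G60", "Q61", "Y64", "A66", "M67", "D69", "Q70",
        "Y71", "Q99",
    ],
    "1WQ1": [
        "A11", "G12", "G13", "I21", "Y32", "D33", "P34", "I36", "E37", "D38",
        "S39", "Y40", "G60", "Q61", "E62", "E63", "Y64", "K88", "D92",
    ],
    "2UZI": ["I21", "V29", "D33", "P34", "I36", "E37", "D38", "Y40", "Q61", "Y64"],
    "2VH5": [
        "I21", "V29", "D33", "P34", "I36", "E37", "D38", "Y40", "D57", "Q61",
        "Y64",
    ],
    "3DDC": ["I24", "Q25", "I36", "D38", "Y40", "Y64", "M67"],
    "1HE8": ["I21", "D33", "I36", "E37", "D38", "S39", "Y40"],
    "3KUC": ["I21", "D33", "I36", "E37", "D38", "S39", "Y40", "R41"],
    "3KUD": ["I21", "E37", "D38", "S39", "Y40", "R41"],
    "1K8R": ["I36", "E37", "D38", "S39", "Y40", "R41", "D54"],
    "1C1Y": ["I21", "I36", "E37", "D38", "S39", "Y40", "R41"],
    # F82 in RalA numbering == HRas Y71; see module docstring.
    "1ZC3": [
        "D47", "G48", "E49", "T50", "C51", "L52", "M67", "G75", "F78", "V81",
        "Y71",
    ],
    "2A9K": [
        "T20", "I21", "Q22", "L23", "D69", "Y71", "M72", "G75", "L79", "A83",
        "V103", "S106", "D107", "P110",
    ],
    "2C5L": [
        "I24", "Q25", "I36", "D38", "S39", "Y40", "D47", "S127", "Q131",
        "A134", "Y141", "I142", "E143", "D154", "R161", "R164", "Q165",
    ],
    "4DXA": ["Q25", "H27", "I36", "E37", "D38", "S39", "Y40", "Q43", "M67"],
    "3T5G": ["T2", "D57", "G178", "P179", "G180"],
    "2BOV": ["I139", "P140", "E143"],
    "1UAD": ["I36", "G48", "E49", "T50", "C51"],
}

#: Sequence-identical deposits grouped under each interface definition.
COMPLEX_MEMBERS: dict[str, list[str]] = {
    "1NVU": ["1NVU", "1NVX", "1NVW", "1NVV"],
    "3KUC": ["3KUC", "1GUA"],
    "1ZC3": ["1ZC3", "1ZC4"],
    "2A9K": ["2A9K", "2A78"],
}

#: Functional category of each complex group.
COMPLEX_CATEGORIES: dict[str, str] = {
    "1LFD": "RasGef",
    "1NVU": "RasGef",
    "1XD2": "RasGef",
    "1BKD": "RasGef",
    "3CF6": "RapGef",
    "1WQ1": "RasGap",
    "2UZI": "Antibody",
    "2VH5": "Antibody",
    "3DDC": "Effector RBD",
    "1HE8": "Effector RBD",
    "3KUC": "Effector RBD",
    "3KUD": "Effector RBD",
    "1K8R": "Effector RBD",
    "1C1Y": "Effector RBD",
    "1ZC3": "Other",
    "2A9K": "Other",
    "2C5L": "Other",
    "4DXA": "Other",
    "3T5G": "Other",
    "2BOV": "Other",
    "1UAD": "Other",
}

#: The 22 positions specifically conserved in divergent-but-interacting pairs
#: (HRas numbering; 21 hyper-conserved, I139 hyper-variable).
DIRP_POSITIONS: list[str] = [
    "G12", "T20", "Q22", "F28", "Y32", "D33", "P34", "T35", "I36", "D54",
    "T58", "A59", "G60", "Y64", "A66", "R68", "Y71", "G77", "V103", "I139",
    "E153", "C186",
]

#: Classical Ras functional regions (inclusive residue sets, HRas numbering).
#: Multi-membership is allowed (e.g. T35 sits in Switch I and the nucleotide
#: site); positions outside every region are classed as inert.
FUNCTIONAL_REGIONS: dict[str, frozenset[int]] = {
    "Switch I (effector binding site)": frozenset(range(30, 39)),
    "Switch II": frozenset(range(60, 77)),
    "C-terminal hypervariable region": frozenset(range(166, 190)),
    "Nucleotide (GDP/GTP) binding site": frozenset(
        list(range(10, 18)) + [28, 35] + list(range(57, 61))
        + list(range(116, 121)) + list(range(145, 148))
    ),
}
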