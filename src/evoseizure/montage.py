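"""The 19-electrode 10-20 scalp montage: labels, lobes, regions, adjacency.

Every electrode maps to exactly one lobe (frontal, central, parietal,
occipital, temporal) and one region (left hemisphere, central line, right
hemisphere).  The adjacency graph encodes physical scalp neighbourhood and
drives the unitary-step mutation of the electrode gene.
"""

from __future__ import annotations

ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

LOBES: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F7": "frontal", "F3": "frontal",
    "Fz": "frontal", "F4": "frontal", "F8": "frontal",
    "C3": "central", "Cz": "central", "C4": "central",
    "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "O1": "occipital", "O2": "occipital",
}

# odd index -> left hemisphere, even -> right, z -> central line
REGIONS: dict[str, str] = {
    e: ("central" if e.endswith("z")
        else "left" if int(e[-1]) % 2 == 1
        else "right")
    for e in ELECTRODES
}

# Physical scalp adjacency (symmetric).
ADJACENCY: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3", "Fz"),
    "Fp2": ("Fp1", "Fz", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "Fz", "F8", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "Cz", "T4", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "Pz", "O2"),
    "O2": ("P4", "Pz", "T6", "O1"),
}


def lobes_of(electrodes) -> set[str]:
    """Set of lobes covered by an electrode collection."""
    return {LOBES[e] for e in electrodes}


def regions_of(electrodes) -> set[str]:
    return {REGIONS[e] for e in electrodes}


def is_standard_label(label: str) -> bool:
    """Case-insensitive membership test against the 19 10-20 labels."""
    return label.strip().lower() in {e.lower() for e in ELECTRODES}


def canonical_label(label: str) -> str:
    lut = {e.lower(): e for e in ELECTRODES}
    return lut[label.strip().lower()]
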