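"""Named antecedent subsets.

Besides the computed selections (total / centre histogram distance on the
training data at hand), the module carries the fixed reference subsets that
the histogram-distance selection identified on the public MICCAI colonoscopy
databases (CVC-Colon, ETIS-Larib, CVC-Clinic).  They are useful as drop-in
presets when replicating that study on the real databases and as regression
anchors for the selection code.  All indices are 1-based positions in the
canonical 99-antecedent order.
"""

from __future__ import annotations

from .features import ANTECEDENT_NAMES, ENTROPY_INDICES, GRADIENT_INDICES

#: Antecedents whose polyp / no_polyp triangle total distance exceeded 0.2
#: on the reference databases, in decreasing order of that distance.
REFERENCE_TOTAL_DISTANCE_02 = (
    51, 4, 61, 19, 85, 29, 73, 27, 35, 34, 32, 82, 97, 43, 72, 64, 13, 12,
    94, 28, 36, 99, 78, 49, 84, 91, 31, 48, 80, 63, 79, 45, 74, 75, 44,
)

#: The stricter 0.35 total-distance subset (13 antecedents).
REFERENCE_TOTAL_DISTANCE_035 = (
    12, 28, 36, 44, 45, 49, 74, 75, 78, 79, 80, 91, 99,
)

#: Antecedents whose class histogram centres were far apart on the
#: reference databases.
REFERENCE_CENTER_DISTANCE = (
    2, 3, 5, 10, 11, 12, 13, 17, 18, 20, 25, 26, 27, 28, 37, 38, 39, 52,
    53, 54, 62, 63, 64, 68, 69, 72, 73, 77, 79, 83, 85, 86, 89, 91, 95, 97,
)

#: Very narrow triangle rules found empirically on the reference databases;
#: excluding them improves every inference variant there.
REFERENCE_NARROW = (31, 48, 61, 63, 84, 94)

PRESETS = {
    "all99": tuple(range(1, 100)),
    "entropy": ENTROPY_INDICES,
    "total02": REFERENCE_TOTAL_DISTANCE_02,
    "total035": REFERENCE_TOTAL_DISTANCE_035,
    "center": REFERENCE_CENTER_DISTANCE,
}


def preset_indices(name: str, exclude_narrow: bool = False,
                   exclude_gradients: bool = False) -> tuple:
    """Resolve a preset name to its 1-based antecedent indices.

    ``exclude_narrow`` drops the reference narrow-triangle antecedents;
    ``exclude_gradients`` drops the 24 gradient statistics (indices 76-99).
    """
    try:
        indices = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    if exclude_narrow:
        indices = tuple(i for i in indices if i not in REFERENCE_NARROW)
    if exclude_gradients:
        indices = tuple(i for i in indices if i not in GRADIENT_INDICES)
    if not indices:
        raise ValueError("preset filtering removed every antecedent")
    return indices


def describe(indices) -> list:
    """Human-readable names of a set of 1-based antecedent indices."""
    return [f"{i}: {ANTECEDENT_NAMES[i - 1]}" for i in indices]
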