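"""Radionuclide physical decay."""

from __future__ import annotations

import math

#: physical half-lives in minutes
HALF_LIFE_MIN = {"F18": 109.77, "Ga68": 67.71}


def decay_factor(radionuclide: str, elapsed_min: float) -> float:
    """exp(-ln2 * t / T1/2) for the given nuclide and elapsed time in minutes."""
    if radionuclide == "none":
        return 1.0
    try:
        half_life = HALF_LIFE_MIN[radionuclide]
    except KeyError:
        raise ValueError(f"unknown radionuclide {radionuclide!r}; "
                         f"known: {sorted(HALF_LIFE_MIN)}") from None
    if elapsed_min < 0:
        raise ValueError("elapsed time must be >= 0")
    return math.exp(-math.log(2.0) * elapsed_min / half_life)
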