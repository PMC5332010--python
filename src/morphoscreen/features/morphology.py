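"""Morphology features of a region mask.

Conventions: area in px^2, roundness = 4*pi*A/P^2 with the Crofton
perimeter, and length/width as the major/minor axes of the image-moment
ellipse (so a 100 x 20 rectangle reports a length slightly above 100, a
documented property of the moment convention).
"""

from __future__ import annotations

import numpy as np
from skimage.measure import perimeter_crofton, regionprops


def morphology_of_mask(mask: np.ndarray) -> dict[str, float]:
    """area, roundness, width, length, width_to_length of one mask."""
    area = float(mask.sum())
    if area == 0:
        return {k: np.nan for k in ("area", "roundness", "width", "length", "width_to_length")}
    props = regionprops(mask.astype(np.uint8))[0]
    per = float(perimeter_crofton(mask, directions=4))
    roundness = 4 * np.pi * area / per**2 if per > 0 else np.nan
    length = float(props.axis_major_length)
    width = float(props.axis_minor_length)
    return {
        "area": area,
        "roundness": float(roundness) if np.isfinite(roundness) else np.nan,
        "width": width,
        "length": length,
        "width_to_length": width / length if length > 0 else np.nan,
    }
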