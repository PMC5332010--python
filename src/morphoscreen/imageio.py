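"""Field images and multi-page TIFF I/O.

A field is stored as one multi-page TIFF, one page per channel, with the
channel name carried in each page's ImageDescription tag.  Label masks are
written as 16-bit single-page TIFFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Canonical channel order: nuclear stain, microtubules, F-actin, YAP/TAZ.
CHANNELS = ("dna", "tubulin", "actin", "yaptaz")


@dataclass
class FieldImage:
    """One imaged field: named 2-D channel rasters plus pixel size (um/px)."""

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_field(path, img: FieldImage) -> None:
    with tifffile.TiffWriter(path) as tw:
        for name, arr in img.channels.items():
            tw.write(
                arr.astype(np.float32),
                description=name,
                metadata=None,
                contiguous=False,
            )


def read_field(path, pixel_size: float = 1.0) -> FieldImage:
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = (page.description or "").strip() or f"channel{i}"
            channels[name] = page.asarray()
    return FieldImage(channels=channels, pixel_size=pixel_size)


def write_labels(path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
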