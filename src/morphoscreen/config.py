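"""Pipeline configuration.

Every tunable used by the segmentation, region-geometry, feature-extraction,
classification and screen-statistics stages lives here, with defaults that
reproduce the published analysis parameters (region borders 10 / -5 and
40 / 20 percent, 2 percent nuclear erosion, texture scales {0, 1} px,
hit threshold 1.5).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class SegmentationConfig:
    #: Gaussian pre-smoothing sigma (px) applied to the nuclear channel.
    nucleus_smooth_sigma: float = 2.0
    #: Global threshold method for the nuclear channel ("otsu" or a float).
    nucleus_threshold: str | float = "otsu"
    #: Minimum nucleus area in px^2; smaller components are discarded.
    min_nucleus_area: int = 50
    #: Minimum separation (px) between watershed seed maxima.
    peak_min_distance: int = 10
    #: Gaussian smoothing of the distance map before peak detection.
    peak_smooth_sigma: float = 3.0
    #: Gaussian smoothing sigma for the tubulin channel before cell watershed.
    cell_smooth_sigma: float = 2.0
    #: Threshold method for tubulin foreground ("otsu" or a float).
    cell_threshold: str | float = "otsu"
    #: Minimum cell area in px^2 for the cytoplasm-first multinucleate pass.
    min_cell_area: int = 100


@dataclass
class RegionConfig:
    #: Protrusion membrane-region borders, percent of edge-to-centroid
    #: distance measured inward from the cell edge (negative = outside).
    protrusion_inner_pct: float = 10.0
    protrusion_outer_pct: float = -5.0
    #: Ring-region inner border (percent, 100 = whole cell).
    ring_inner_pct: float = 40.0
    #: Ring outer border as a fraction of the edge-to-inner-border distance.
    ring_outer_frac: float = 0.20
    #: Reading of the ring outer border: if True the outer border sits at
    #: depth ring_inner_pct * ring_outer_frac measured from the cell edge
    #: (default); if False it is measured inward from the inner border.
    ring_outer_from_edge: bool = True
    #: Nuclear erosion, percent of the equivalent radius.
    erode_pct: float = 2.0
    #: Angular resolution of the radial coordinate field.
    n_theta: int = 720


@dataclass
class FeatureConfig:
    #: Grey levels for co-occurrence quantisation.
    glcm_levels: int = 64
    #: Co-occurrence pixel distance.
    glcm_distance: int = 1
    #: Base sigma of the Gaussian-derivative (SER) kernels; scale s uses
    #: sigma = ser_sigma0 + s px.
    ser_sigma0: float = 0.5
    ser_scales: tuple[int, ...] = (0, 1)
    #: Gabor wavelength in px (frequency = 1 / wavelength) and orientations.
    gabor_wavelength: float = 4.0
    gabor_orientations: int = 8


@dataclass
class ClassifyConfig:
    #: "ridge" = regularised one-vs-rest linear discriminant (default);
    #: "logistic" = multinomial logistic regression.
    model: str = "ridge"
    alpha: float = 1.0
    #: Optional confidence threshold; cells below it are labelled
    #: "unclassified". Off (None) by default: every cell is classified once.
    confidence_threshold: float | None = None


@dataclass
class ScreenConfig:
    #: |Z| threshold for hit calling.
    hit_threshold: float = 1.5
    #: Use median/MAD instead of mean/sd for plate normalisation.
    robust: bool = False
    #: Compute control Z-scores on plate-normalised values (True, following
    #: the published order of operations) or on raw values.
    zscore_on_normalised: bool = True


@dataclass
class Config:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    regions: RegionConfig = field(default_factory=RegionConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["features"]["ser_scales"] = list(d["features"]["ser_scales"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Config":
        kw: dict[str, Any] = {}
        for f in dataclasses.fields(cls):
            sub = d.get(f.name, {})
            subcls = f.default_factory  # type: ignore[union-attr]
            if f.name == "features" and "ser_scales" in sub:
                sub = dict(sub)
                sub["ser_scales"] = tuple(sub["ser_scales"])
            kw[f.name] = subcls().__class__(**sub) if sub else subcls()
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
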