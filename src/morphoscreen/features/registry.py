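"""The fixed per-cell feature registry.

Exactly 126 per-cell features, organised as:

* 16 morphology: area, roundness (4*pi*A/P^2), length and width (moment
  ellipse axes) and width:length for nucleus, cell and cytoplasm, plus the
  protrusion membrane-region area;
* 7 region-mean intensities: YAP/TAZ over nucleus, ring, cell, cytoplasm;
  nuclear stain over nucleus; tubulin over cytoplasm and cell;
* 8 ratios: nucleus:ring and eroded-nucleus:ring YAP/TAZ with their log10
  versions, nuclear-stain and nuclear-YAP/TAZ per nuclear area, and cell /
  nuclear area per whole-cell YAP/TAZ;
* 80 SER (Gaussian-derivative) textures: 8 responses x 5 stain-region
  pairs (tubulin & actin on cytoplasm; nuclear stain, tubulin & actin on
  nucleus) x 2 scales (0 and 1 px);
* 12 Haralick features: correlation, contrast, variance, homogeneity for
  tubulin-cytoplasm, tubulin-nucleus and actin-nucleus;
* 3 Gabor features: mean, min and max over 8 orientations, actin cytoplasm.

The well profile is the per-feature mean over cells plus the neighbour
fraction: 127 well-level features.  Membrane-band areas, the raw /
calibrated neighbour fraction and total YAP/TAZ are carried as auxiliary
per-cell columns outside the registry.
"""

from __future__ import annotations

from dataclasses import dataclass

SHAPE_CLASSES = ("spindly", "large_spread", "triangular", "fan", "small_round")

SER_RESPONSES = ("spot", "hole", "edge", "ridge", "valley", "saddle", "bright", "dark")
SER_PAIRS = (
    ("tubulin", "cytoplasm"),
    ("actin", "cytoplasm"),
    ("dna", "nucleus"),
    ("tubulin", "nucleus"),
    ("actin", "nucleus"),
)
SER_SCALES = (0, 1)
HARALICK_FEATURES = ("correlation", "contrast", "variance", "homogeneity")
HARALICK_PAIRS = (
    ("tubulin", "cytoplasm"),
    ("tubulin", "nucleus"),
    ("actin", "nucleus"),
)
GABOR_STATS = ("mean", "min", "max")

MORPH_REGIONS = ("nucleus", "cell", "cytoplasm")
MORPH_PROPS = ("area", "roundness", "width", "length", "width_to_length")

INTENSITY_FEATURES = (
    "yap_nucleus_mean",
    "yap_ring_mean",
    "yap_cell_mean",
    "yap_cytoplasm_mean",
    "dna_nucleus_mean",
    "tubulin_cytoplasm_mean",
    "tubulin_cell_mean",
)

RATIO_FEATURES = (
    "yap_ratio_nuc_ring",
    "yap_ratio_nuc_ring_log10",
    "yap_ratio_eroded_ring",
    "yap_ratio_eroded_ring_log10",
    "dna_nucleus_per_area",
    "yap_nucleus_per_area",
    "cell_area_per_yap_cell",
    "nucleus_area_per_yap_cell",
)

#: Auxiliary per-cell columns (outside the 126-feature registry).
AUX_COLUMNS = (
    "membrane1_area",
    "membrane2_area",
    "neighbour_fraction_raw",
    "neighbour_fraction",
    "total_yaptaz",
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    group: str  # morphology / intensity / ratio / ser / haralick / gabor
    channel: str | None = None
    region: str | None = None
    scale: int | None = None


def build_registry() -> list[FeatureDescriptor]:
    reg: list[FeatureDescriptor] = []
    for region in MORPH_REGIONS:
        for prop in MORPH_PROPS:
            reg.append(FeatureDescriptor(f"{region}_{prop}", "morphology", region=region))
    reg.append(
        FeatureDescriptor("membrane_protrusion_area", "morphology", region="membrane_protrusion")
    )
    for name in INTENSITY_FEATURES:
        reg.append(FeatureDescriptor(name, "intensity"))
    for name in RATIO_FEATURES:
        reg.append(FeatureDescriptor(name, "ratio"))
    for scale in SER_SCALES:
        for channel, region in SER_PAIRS:
            for resp in SER_RESPONSES:
                reg.append(
                    FeatureDescriptor(
                        f"ser_{resp}_{channel}_{region}_s{scale}",
                        "ser",
                        channel=channel,
                        region=region,
                        scale=scale,
                    )
                )
    for channel, region in HARALICK_PAIRS:
        for feat in HARALICK_FEATURES:
            reg.append(
                FeatureDescriptor(
                    f"haralick_{feat}_{channel}_{region}",
                    "haralick",
                    channel=channel,
                    region=region,
                )
            )
    for stat in GABOR_STATS:
        reg.append(
            FeatureDescriptor(
                f"gabor_{stat}_actin_cytoplasm", "gabor", channel="actin", region="cytoplasm"
            )
        )
    names = [d.name for d in reg]
    assert len(names) == len(set(names)), "registry names must be unique"
    return reg


REGISTRY = build_registry()
REGISTRY_NAMES = tuple(d.name for d in REGISTRY)

N_CELL_FEATURES = len(REGISTRY)  # 126
#: Well-level features: per-cell means plus the neighbour fraction.
N_WELL_FEATURES = N_CELL_FEATURES + 1  # 127
NEIGHBOUR_FRACTION = "neighbour_fraction"
WELL_FEATURE_NAMES = REGISTRY_NAMES + (NEIGHBOUR_FRACTION,)
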