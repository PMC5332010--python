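"""End-to-end screen pipeline over synthetic plates.

Drives the full chain: plate simulation -> segmentation -> region geometry
-> feature extraction -> well aggregation -> shape classification ->
plate normalisation -> control Z-scores -> hit calling -> QC.  Every step
is the library function; this module only sequences them and writes the
tabular artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Config
from .features import REGISTRY_NAMES, aggregate_well, extract_all
from .features.registry import SHAPE_CLASSES
from .plate import (
    ROLE_DILUTION,
    ROLE_ECT2,
    ROLE_LATS1,
    ROLE_MOCK,
    ROLE_YAP,
    PlateLayout,
    default_layout,
    write_plate_map,
)
from .qc import replicate_correlation, zprime
from .screen import call_hits, density_regression, plate_normalise, zscore_to_controls
from .segmentation import (
    detect_multinucleate,
    filter_border,
    segment_cells,
    segment_nuclei,
)
from .shape_classify import ShapeModel, classify, shape_counts, train
from .synth import PlateSimSpec, WellEffect, reference_shapes, render_cell, simulate_well
from .tables import write_feature_table

log = logging.getLogger(__name__)

#: Features taken through hit calling: the five shape proportions, the
#: YAP/TAZ ratio and total YAP/TAZ (plus the multinucleate percentage,
#: the transfection-control readout).
HIT_FEATURES = [f"shape_frac_{c}" for c in SHAPE_CLASSES] + [
    "yap_ratio_nuc_ring_log10",
    "total_yaptaz",
    "multinucleate_pct",
]

#: Readout used to assess each positive-control role.
CONTROL_READOUTS = {
    ROLE_LATS1: "yap_ratio_nuc_ring_log10",
    ROLE_YAP: "total_yaptaz",
    ROLE_ECT2: "multinucleate_pct",
}


def demo_layout(n_sample: int = 8) -> PlateLayout:
    """A small plate subset exercising every role (<= 48 wells)."""
    full = default_layout("1A")
    wells = []
    wells += [f"{r}12" for r in "CDEF"]  # mock
    sample_wells = [f"{r}{c}" for c in (5, 6) for r in "CDEFGH"]
    wells += sample_wells[:n_sample]
    wells += [f"{r}23" for r in "BCDE"]  # siLATS1-like
    wells += [f"{r}23" for r in "FGHI"]  # siYAP-like
    wells += [f"{r}23" for r in "JKLM"]  # siECT2-like
    wells += [f"{r}1" for r in "ABCDEFGH"]  # dilution series
    return full.subset(wells)


def training_table(
    n_per_class: int, seed: int, config: Config | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Labelled single-cell training fixture.

    Renders cells of each reference shape on their own patch and extracts
    the full registry features from the noiseless render with ground-truth
    masks (emulating the manually curated training cells).
    """
    from .imageio import FieldImage

    cfg = config or Config()
    rng = np.random.default_rng(seed)
    shapes = reference_shapes()
    rows = []
    labels = []
    # tile isolated same-class cells onto shared canvases (tile sized to the
    # class) so the field-wide response maps amortise over many cells
    def flush(cls, batch):
        tile = max(max(r.cell_mask.shape[0] for r in batch),
                   max(r.cell_mask.shape[1] for r in batch)) + 4
        tile = int(np.ceil(tile / 16)) * 16  # stable sizes keep FFT plans cached
        grid = min(6, max(1, int(np.ceil(np.sqrt(len(batch))))))
        side = tile * grid
        cells = np.zeros((side, side), np.int32)
        nuclei = np.zeros((side, side), np.int32)
        chans = {
            name: np.zeros((side, side), np.float32)
            for name in ("dna", "tubulin", "actin", "yaptaz")
        }
        for idx, r in enumerate(batch):
            gr, gc = divmod(idx, grid)
            ph, pw = r.cell_mask.shape
            r0 = gr * tile + (tile - ph) // 2
            c0 = gc * tile + (tile - pw) // 2
            sub = (slice(r0, r0 + ph), slice(c0, c0 + pw))
            m = r.cell_mask
            cells[sub][m] = idx + 1
            nuclei[sub][r.nucleus_mask] = idx + 1
            for name, patch in r.channels.items():
                chans[name][sub][m] = patch[m]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = extract_all(FieldImage(chans), cells, nuclei, cfg)
        for _, row in df.iterrows():
            rows.append(row)
            labels.append(cls)

    for cls, spec in shapes.items():
        pending = []
        for _ in range(n_per_class):
            pending.append(render_cell(spec, rng))
            if len(pending) == 36:
                flush(cls, pending)
                pending = []
        if pending:
            flush(cls, pending)
    table = pd.DataFrame(rows).reset_index(drop=True)
    return table, pd.Series(labels, name="shape_class")


def mixture_population_table(
    weights: dict[str, float],
    n_cells: int,
    seed: int,
    config: Config | None = None,
    cells_per_field: int = 110,
    image_shape: tuple[int, int] = (1000, 1000),
) -> tuple[pd.DataFrame, pd.Series]:
    """Render a held-out population from a shape-class mixture.

    Fields are rendered until ``n_cells`` cells are collected; features are
    extracted with ground-truth masks (no segmentation), so the result
    isolates the classifier from segmentation error.  Returns the per-cell
    feature table and the true class labels.
    """
    from .synth import FieldSpec, render_field

    cfg = config or Config()
    shapes = reference_shapes()
    mix = [(shapes[c], w) for c, w in weights.items() if w > 0]
    tables = []
    labels = []
    collected = 0
    field_i = 0
    while collected < n_cells:
        fseed = int(
            np.random.SeedSequence([seed, field_i]).generate_state(1)[0] % 2**31
        )
        fspec = FieldSpec(
            image_shape=image_shape,
            n_cells=min(cells_per_field, n_cells - collected),
            rng_seed=fseed,
            strict=False,
        )
        img, gt = render_field(fspec, mix)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = extract_all(img, gt.cells, gt.nuclei, cfg)
        truth = gt.records.set_index("label").loc[t["cell"], "shape_class"]
        tables.append(t)
        labels.append(truth.reset_index(drop=True))
        collected += len(t)
        field_i += 1
    table = pd.concat(tables, ignore_index=True).iloc[:n_cells]
    truth = pd.concat(labels, ignore_index=True).iloc[:n_cells]
    return table, truth


@dataclass
class WellResult:
    well: str
    profile: pd.Series
    cell_table: pd.DataFrame
    n_cells_segmented: int


def process_field(img, config: Config) -> tuple[pd.DataFrame, float, np.ndarray, np.ndarray]:
    """Segment one field and extract its per-cell features.

    Returns (cell table, multinucleate percentage, cells, nuclei labels).
    """
    nuclei = segment_nuclei(img["dna"], config.segmentation)
    cells = segment_cells(img["tubulin"], nuclei, config.segmentation)
    cells, nuclei = filter_border(cells, nuclei)
    _, multi_pct = detect_multinucleate(img["tubulin"], nuclei, config.segmentation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = extract_all(img, cells, nuclei, config)
    return table, multi_pct, cells, nuclei


def process_well(
    spec: PlateSimSpec, well: str, model: ShapeModel, config: Config
) -> WellResult:
    img, _, _ = simulate_well(spec, well)
    table, multi_pct, _, _ = process_field(img, config)
    profile = aggregate_well(table)
    if len(table):
        labels = classify(
            model, table, confidence_threshold=config.classify.confidence_threshold
        )["shape_class"]
        profile = pd.concat([profile, shape_counts(labels).drop(index="n_cells")])
    profile["multinucleate_pct"] = multi_pct
    rec = spec.layout[well]
    meta = pd.Series(
        {
            "well": well,
            "plate": spec.layout.plate_id,
            "role": rec.role,
            "gene": str(rec.cells_plated) if rec.role == ROLE_DILUTION else rec.gene,
            "cells_plated": rec.cells_plated,
        }
    )
    return WellResult(well, pd.concat([meta, profile]), table, len(table))


@dataclass
class RunResult:
    well_tables: dict[str, pd.DataFrame]  # plate id -> well table
    zscores: pd.DataFrame
    hits: pd.DataFrame
    qc_summary: dict
    density: dict
    model: ShapeModel
    config_hash: str


def run_all(
    out_dir: str | Path,
    seed: int = 0,
    config: Config | None = None,
    layout: PlateLayout | None = None,
    plates: tuple[str, ...] = ("1A", "1B"),
    n_cells: int = 40,
    image_shape: tuple[int, int] = (512, 512),
    n_train_per_class: int = 60,
    sample_effects: dict[str, WellEffect] | None = None,
) -> RunResult:
    """The full pipeline on a (demo-sized) synthetic screen.

    Simulates ``plates`` replicate plates of the given layout, runs every
    downstream stage and writes feature tables, shape counts, hit lists and
    a QC report under ``out_dir``.  Deterministic for a fixed seed.
    """
    cfg = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    config_hash = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
    log.info("run-all: seed=%d config=%s", seed, config_hash)

    if layout is None:
        layout = demo_layout()
    if sample_effects is None:
        # two designed sample hits so the hit list is non-trivial
        samples = [w.well for w in layout.by_role("sample")]
        sample_effects = {}
        if len(samples) >= 2:
            sample_effects[samples[0]] = WellEffect(log_ratio_shift=0.4)
            sample_effects[samples[1]] = WellEffect(
                multinucleate_fraction=0.45,
                mixture={
                    "spindly": 0.10,
                    "large_spread": 0.45,
                    "triangular": 0.10,
                    "fan": 0.10,
                    "small_round": 0.25,
                },
            )

    model_seed = int(np.random.SeedSequence([seed, 999]).generate_state(1)[0] % 2**31)
    table, labels = training_table(n_train_per_class, model_seed, cfg)
    model = train(table, labels, cfg.classify)
    model.save(out / "shape_model.txt")
    log.info("shape model trained: accuracy=%s", model.training_accuracy)

    well_tables: dict[str, pd.DataFrame] = {}
    for pi, plate_id in enumerate(plates):
        plate_layout = PlateLayout(wells=layout.wells, plate_id=plate_id)
        pseed = int(np.random.SeedSequence([seed, pi]).generate_state(1)[0] % 2**31)
        spec = PlateSimSpec(
            layout=plate_layout,
            image_shape=image_shape,
            n_cells=n_cells,
            effects=sample_effects,
            rng_seed=pseed,
        )
        rows = []
        for well in plate_layout.wells:
            res = process_well(spec, well, model, cfg)
            rows.append(res.profile)
        df = pd.DataFrame(rows).reset_index(drop=True)
        well_tables[plate_id] = df
        write_feature_table(df, out / f"well_table_{plate_id}.tsv")
        write_plate_map(plate_layout, out / f"plate_map_{plate_id}.csv")

    combined = pd.concat(well_tables.values(), ignore_index=True)
    normalised = plate_normalise(combined, cfg.screen)
    zsc = zscore_to_controls(
        normalised if cfg.screen.zscore_on_normalised else combined,
        control_roles=(ROLE_MOCK,),
    )
    hit_feats = [f for f in HIT_FEATURES if f in combined.columns]
    hits = call_hits(
        zsc,
        combined,
        hit_feats,
        threshold=cfg.screen.hit_threshold,
        fold_feature_map={"yap_ratio_nuc_ring_log10": "yap_ratio_nuc_ring"},
    )
    write_feature_table(zsc, out / "zscores.tsv")
    hits.to_csv(out / "hits.csv", index=False)

    # density-dependence regression on the dilution wells
    dil = combined[combined["role"] == ROLE_DILUTION]
    density: dict = {}
    if dil["cells_plated"].nunique() >= 3:
        fit = density_regression(dil["cells_plated"], dil["yap_ratio_nuc_ring_log10"])
        density = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_value": fit.r_value,
            "p_value": fit.p_value,
            "n": fit.n,
        }
        with open(out / "density_fit.txt", "w") as fh:
            for k, v in density.items():
                fh.write(f"{k}\t{v}\n")

    # QC: replicate-plate correlation and per-control Z'
    qc_summary: dict = {}
    if len(plates) >= 2:
        feats = [c for c in REGISTRY_NAMES if combined[c].notna().all()]
        rep = replicate_correlation(
            well_tables[plates[0]], well_tables[plates[1]], feats
        )
        qc_summary["replicate_median_diagonal"] = rep.median_diagonal
        qc_summary["replicate_median_off_diagonal"] = rep.median_off_diagonal
        qc_summary["replicate_p_value"] = rep.p_value
    mock_vals = combined[combined["role"] == ROLE_MOCK]
    for role, feat in CONTROL_READOUTS.items():
        pos = combined[combined["role"] == role][feat].dropna()
        neg = mock_vals[feat].dropna()
        if len(pos) >= 3 and len(neg) >= 3:
            z, band = zprime(pos, neg)
            qc_summary[f"zprime_{role}"] = z
            qc_summary[f"zprime_{role}_band"] = band
    with open(out / "qc_summary.txt", "w") as fh:
        fh.write(f"seed\t{seed}\nconfig\t{config_hash}\n")
        for k, v in qc_summary.items():
            fh.write(f"{k}\t{v}\n")

    return RunResult(
        well_tables=well_tables,
        zscores=zsc,
        hits=hits,
        qc_summary=qc_summary,
        density=density,
        model=model,
        config_hash=config_hash,
    )
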