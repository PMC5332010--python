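"""384-well plate geometry, well roles and plate-map I/O.

The screen layout follows the documented convention: samples (one SMARTpool
per well) occupy the plate interior, mock-transfected negative controls sit
within columns 3-22 in the central row band, positive controls (siLATS1-like,
siYAP-like, siECT2-like) occupy columns 23-24 with at least 4 wells per
control, and a cell-density dilution series runs down columns 1, 2, 23
and 24.  Replicate plates are named 1A, 1B, 2A, 2B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_COLS = 24
N_WELLS = len(ROWS) * N_COLS

#: Well roles.
ROLE_SAMPLE = "sample"
ROLE_MOCK = "mock"
ROLE_LATS1 = "control_lats1"
ROLE_YAP = "control_yap"
ROLE_ECT2 = "control_ect2"
ROLE_DILUTION = "dilution"
ROLES = (ROLE_SAMPLE, ROLE_MOCK, ROLE_LATS1, ROLE_YAP, ROLE_ECT2, ROLE_DILUTION)
POSITIVE_CONTROL_ROLES = (ROLE_LATS1, ROLE_YAP, ROLE_ECT2)

REPLICATE_PLATES = ("1A", "1B", "2A", "2B")


def well_id(row: str, col: int) -> str:
    return f"{row}{col}"


def parse_well_id(well: str) -> tuple[str, int]:
    row, col = well[0].upper(), int(well[1:])
    if row not in ROWS or not 1 <= col <= N_COLS:
        raise ValueError(f"invalid well id {well!r}")
    return row, col


@dataclass
class WellRecord:
    well: str
    role: str
    gene: str = ""
    cells_plated: int | None = None

    def __post_init__(self) -> None:
        parse_well_id(self.well)
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for well {self.well}")


@dataclass
class PlateLayout:
    wells: dict[str, WellRecord] = field(default_factory=dict)
    plate_id: str = "1A"

    def add(self, rec: WellRecord) -> None:
        if rec.well in self.wells:
            raise ValueError(f"duplicate well {rec.well}")
        self.wells[rec.well] = rec

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, well: str) -> WellRecord:
        return self.wells[well]

    def by_role(self, *roles: str) -> list[WellRecord]:
        return [w for w in self.wells.values() if w.role in roles]

    def subset(self, wells) -> "PlateLayout":
        sub = PlateLayout(plate_id=self.plate_id)
        for w in wells:
            sub.add(self.wells[w])
        return sub

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "well": w.well,
                    "role": w.role,
                    "gene": w.gene,
                    "cells_plated": w.cells_plated,
                }
                for w in self.wells.values()
            ]
        )


#: Cells plated for the density-dilution series, increasing down the column.
DILUTION_SERIES = (250, 500, 750, 1000, 1500, 2000, 2500, 3000)


def default_layout(plate_id: str = "1A", n_genes: int = 142) -> PlateLayout:
    """The bundled 384-well layout.

    Columns 1-2 carry the density dilution series; columns 23-24 carry the
    three positive controls (4 wells each) with the remaining rows used for
    the dilution series; mock wells sit in columns 3-22 within rows C-N;
    all other interior wells are samples (gene SMARTpools, duplicated
    within the plate as in the screens).
    """
    layout = PlateLayout(plate_id=plate_id)
    genes = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    gene_iter = iter(genes * 4)  # duplicate arraying; recycle as needed
    control_rows = {
        ROLE_LATS1: ("B", "C", "D", "E"),
        ROLE_YAP: ("F", "G", "H", "I"),
        ROLE_ECT2: ("J", "K", "L", "M"),
    }
    mock_wells = {well_id(r, c) for r in "CDEFGHIJKLMN" for c in (12, 13)}
    for ri, row in enumerate(ROWS):
        for col in range(1, N_COLS + 1):
            w = well_id(row, col)
            if col in (1, 2):
                layout.add(
                    WellRecord(
                        w,
                        ROLE_DILUTION,
                        cells_plated=DILUTION_SERIES[ri % len(DILUTION_SERIES)],
                    )
                )
            elif col in (23, 24):
                role = next(
                    (r for r, rows_ in control_rows.items() if row in rows_), None
                )
                if role is not None:
                    layout.add(WellRecord(w, role, gene=role.split("_")[1].upper()))
                else:
                    layout.add(
                        WellRecord(
                            w,
                            ROLE_DILUTION,
                            cells_plated=DILUTION_SERIES[ri % len(DILUTION_SERIES)],
                        )
                    )
            elif w in mock_wells:
                layout.add(WellRecord(w, ROLE_MOCK, gene="MOCK"))
            else:
                try:
                    gene = next(gene_iter)
                except StopIteration:
                    gene = "MOCK"
                layout.add(WellRecord(w, ROLE_SAMPLE, gene=gene))
    assert len(layout) == N_WELLS
    return layout


def write_plate_map(layout: PlateLayout, path) -> None:
    df = layout.to_frame()
    df.insert(0, "plate", layout.plate_id)
    df.to_csv(path, index=False)


def read_plate_map(path) -> PlateLayout:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty plate map: {path}")
    plate_id = str(df["plate"].iloc[0]) if "plate" in df.columns else "1A"
    layout = PlateLayout(plate_id=plate_id)
    for i, row in df.iterrows():
        cells = row.get("cells_plated")
        cells = None if pd.isna(cells) else int(cells)
        try:
            layout.add(
                WellRecord(
                    str(row["well"]),
                    str(row["role"]),
                    gene="" if pd.isna(row.get("gene")) else str(row["gene"]),
                    cells_plated=cells,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path} line {i + 2}: {e}") from e
    return layout
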