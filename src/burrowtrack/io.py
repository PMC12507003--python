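"""Readers and writers for the pipeline's tabular artifacts.

All tables are plain CSV with fixed headers; readers validate the schema
and name the offending column on mismatch.  Round-trip identity
(write then read) holds for every table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .layout import UNKNOWN, cell_coords
from .events import StayEvent
from .tracking import LocationSeries
from .dyads import DyadResult


class SchemaError(ValueError):
    """Raised when an input table does not match its expected schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _read_csv(path, columns: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=list(columns))
    # keep literal "NA" category strings; only empty fields are missing
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if df.empty and list(df.columns) == []:
        return pd.DataFrame(columns=list(columns))
    _check_columns(df, columns, what)
    return df


# -- detections ------------------------------------------------------------

DETECTION_COLUMNS = ["time_s", "tag", "reader"]


def write_detections(df: pd.DataFrame, path) -> None:
    _check_columns(df, DETECTION_COLUMNS, "detection log")
    df[DETECTION_COLUMNS].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    return _read_csv(path, DETECTION_COLUMNS, "detection log")


# -- locations -------------------------------------------------------------

def write_locations(series: LocationSeries, path) -> None:
    """Per-tick location CSV ``tick,cell_row,cell_col`` (blank = unknown)."""
    cells = series.cells
    rows = np.where(cells == UNKNOWN, -1, cells // 5)
    cols = np.where(cells == UNKNOWN, -1, cells % 5)
    df = pd.DataFrame({
        "tick": np.arange(cells.size),
        "cell_row": pd.array(rows, dtype="Int64"),
        "cell_col": pd.array(cols, dtype="Int64"),
    })
    df.loc[cells == UNKNOWN, ["cell_row", "cell_col"]] = pd.NA
    df.to_csv(path, index=False)


def read_locations(path, individual=None, tick_s: float = 0.1) -> LocationSeries:
    df = _read_csv(path, ["tick", "cell_row", "cell_col"], "location series")
    cells = np.full(len(df), UNKNOWN, dtype=np.int16)
    ok = df["cell_row"].notna().to_numpy()
    cells[ok] = (
        df.loc[ok, "cell_row"].to_numpy(dtype=int) * 5
        + df.loc[ok, "cell_col"].to_numpy(dtype=int)
    )
    return LocationSeries(individual=individual, tick_s=tick_s, cells=cells)


# -- stay events -----------------------------------------------------------

EVENT_COLUMNS = ["individual", "start_s", "end_s", "row", "col", "category"]


def events_to_frame(events_by_individual: Mapping[object, Sequence[StayEvent]]) -> pd.DataFrame:
    rows = []
    for ind, evs in events_by_individual.items():
        for ev in evs:
            r, c = (None, None) if ev.cell == UNKNOWN else cell_coords(ev.cell)
            rows.append({
                "individual": ind, "start_s": ev.start_s, "end_s": ev.end_s,
                "row": r, "col": c, "category": ev.category,
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> dict[object, list[StayEvent]]:
    _check_columns(df, EVENT_COLUMNS, "events table")
    out: dict[object, list[StayEvent]] = {}
    for row in df.itertuples():
        cell = UNKNOWN if pd.isna(row.row) else int(row.row) * 5 + int(row.col)
        cat = None if pd.isna(row.category) else row.category
        out.setdefault(row.individual, []).append(
            StayEvent(row.individual, float(row.start_s), float(row.end_s), cell, cat)
        )
    return out


def write_events(events_by_individual, path) -> None:
    events_to_frame(events_by_individual).to_csv(path, index=False)


def read_events(path) -> dict[object, list[StayEvent]]:
    return frame_to_events(_read_csv(path, EVENT_COLUMNS, "events table"))


# -- dyad results ----------------------------------------------------------

DYAD_COLUMNS = ["a", "b", "n_actual", "mean", "sd", "index", "p", "class"]


def dyads_to_frame(results: Sequence[DyadResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "a": r.a, "b": r.b, "n_actual": r.n_actual,
            "mean": r.surrogate_mean, "sd": r.surrogate_sd,
            "index": r.index, "p": r.p, "class": r.klass,
        } for r in results],
        columns=DYAD_COLUMNS,
    )


def write_dyads(results: Sequence[DyadResult], path) -> None:
    dyads_to_frame(results).to_csv(path, index=False)


def read_dyads(path) -> pd.DataFrame:
    return _read_csv(path, DYAD_COLUMNS, "dyad table")


# -- individual attributes -------------------------------------------------

ATTRIBUTE_COLUMNS = ["individual", "colony", "caste", "sex", "age_days", "body_weight_g"]
CASTES = ("breeder", "nonbreeder")
SEXES = ("female", "male")


def read_attributes(path) -> pd.DataFrame:
    """Individual-attribute table: colony, caste, sex, age, body weight.

    Individuals must be unique; caste and sex come from controlled
    vocabularies (breeder/nonbreeder, female/male).
    """
    df = _read_csv(path, ATTRIBUTE_COLUMNS, "attribute table")
    if df["individual"].duplicated().any():
        dup = df.loc[df["individual"].duplicated(), "individual"].iloc[0]
        raise SchemaError(f"attribute table: duplicate individual {dup!r}")
    bad_caste = set(df["caste"]) - set(CASTES)
    if bad_caste:
        raise SchemaError(f"attribute table: caste must be one of {CASTES}, got {sorted(bad_caste)}")
    bad_sex = set(df["sex"]) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"attribute table: sex must be one of {SEXES}, got {sorted(bad_sex)}")
    return df


def write_attributes(df: pd.DataFrame, path) -> None:
    _check_columns(df, ATTRIBUTE_COLUMNS, "attribute table")
    df[ATTRIBUTE_COLUMNS].to_csv(path, index=False)


# -- misc tables -----------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path, columns: Sequence[str], what: str = "table") -> pd.DataFrame:
    return _read_csv(path, columns, what)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(nx.relabel_nodes(net, {n: str(n) for n in net.nodes}), path)


# -- configuration ---------------------------------------------------------

def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_manifest(path, **entries) -> None:
    """JSON manifest of seeds, parameters and per-stage record counts."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=_default, sort_keys=True)
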