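"""Configuration files and long-format CSV output.

Experiment configurations are plain YAML: a ``preset:`` key naming one of
the experiment-matrix rows plus any field overrides, e.g. ::

    preset: standard
    n_levels: 20
    dust_flux: 1.0e-12
    cycling:
      k_scavenge: 2.0e-5

Run output is written as long-format CSV with one row per
(month, depth, tracer): columns ``month, depth_m, tracer, fe56, fe54,
delta_permil`` plus the run's diagnostic flux profiles in a parallel
table.  The CSV round-trips back into the in-memory dataset.
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .column import ColumnState, ExperimentConfig, preset

__all__ = ["load_config", "dataset_to_frame", "write_run_csv", "read_run_csv"]


def load_config(source) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file, path, or dict."""
    if isinstance(source, ExperimentConfig):
        return source
    if isinstance(source, dict):
        data = dict(source)
    else:
        data = yaml.safe_load(Path(source).read_text())
        if data is None:
            data = {}
    if not isinstance(data, dict):
        raise ValueError("experiment config must be a mapping")
    name = data.pop("preset", "standard")
    valid = {f.name for f in dataclass_fields(ExperimentConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "margin_levels" in data and isinstance(data["margin_levels"], list):
        data["margin_levels"] = tuple(data["margin_levels"])
    return preset(name, **data)


def dataset_to_frame(ds: xr.Dataset) -> pd.DataFrame:
    """Flatten a run dataset into the long (month, depth, tracer) table."""
    std = float(ds.attrs["reference_ratio"])
    rows = []
    months = ds["month"].values
    z = ds["z"].values
    for tracer in ColumnState.TRACERS:
        fe56 = ds[f"{tracer}_fe56"].values
        fe54 = ds[f"{tracer}_fe54"].values
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(fe54 > 0, (fe56 / np.where(fe54 > 0, fe54, 1.0)) / std * 1000.0 - 1000.0, np.nan)
        for i, m in enumerate(months):
            rows.append(
                pd.DataFrame(
                    {
                        "month": int(m),
                        "depth_m": z,
                        "tracer": tracer,
                        "fe56": fe56[i],
                        "fe54": fe54[i],
                        "delta_permil": delta[i],
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_run_csv(ds: xr.Dataset, path) -> None:
    """Write a run dataset as long-format CSV (plus a diagnostics table)."""
    path = Path(path)
    frame = dataset_to_frame(ds)
    header = (
        f"# experiment={ds.attrs.get('experiment', '?')} "
        f"reference_ratio={ds.attrs.get('reference_ratio')}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)
    diag = pd.DataFrame(
        {
            "depth_m": ds["z"].values,
            "dz_m": ds["dz"].values,
            "remin_fe56": ds["remin_fe56"].values,
            "remin_fe54": ds["remin_fe54"].values,
            "removal_fe56": ds["removal_fe56"].values,
            "removal_fe54": ds["removal_fe54"].values,
        }
    )
    diag_path = path.with_name(path.stem + "_diagnostics.csv")
    diag.to_csv(diag_path, index=False)


def read_run_csv(path) -> xr.Dataset:
    """Rebuild the in-memory dataset from the long-format CSV pair."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        attrs = {}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    attrs[k] = v
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    ratio = float(attrs.get("reference_ratio", 15.67))
    months = np.sort(frame["month"].unique())
    z = np.sort(frame["depth_m"].unique())
    data = {}
    for tracer, sub in frame.groupby("tracer"):
        pivot56 = sub.pivot_table(index="month", columns="depth_m", values="fe56").loc[months, z]
        pivot54 = sub.pivot_table(index="month", columns="depth_m", values="fe54").loc[months, z]
        data[f"{tracer}_fe56"] = (("month", "z"), pivot56.to_numpy())
        data[f"{tracer}_fe54"] = (("month", "z"), pivot54.to_numpy())
    dfe56 = data["dfe_fe56"][1]
    dfe54 = data["dfe_fe54"][1]
    data["dfe"] = (("month", "z"), dfe56 + dfe54)
    data["delta_dfe"] = (("month", "z"), (dfe56 / dfe54 / ratio - 1.0) * 1000.0)
    ds = xr.Dataset(
        data,
        coords={"month": months, "z": z},
        attrs={"experiment": attrs.get("experiment", "?"), "reference_ratio": ratio},
    )
    diag_path = path.with_name(path.stem + "_diagnostics.csv")
    if diag_path.exists():
        diag = pd.read_csv(diag_path)
        ds = ds.assign_coords(dz=("z", diag["dz_m"].to_numpy()))
        for col in ("remin_fe56", "remin_fe54", "removal_fe56", "removal_fe54"):
            ds[col] = ("z", diag[col].to_numpy())
    return ds
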