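"""CSV/YAML round-tripping for the pipeline's tables.

Genotype calls are written as ``A/A``, ``A/B``, ``B/B`` with ``./.``
for missing and ``x/x`` for invalidated calls; coordinates in meters
(planar projection, RT90-style) with one row per fecal sample.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .markers import CALL_STRINGS, STRING_CALLS, MarkerPanel
from .qc import GenotypeTable
from .simulate import SimulationConfig


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [[CALL_STRINGS[int(c)] for c in row] for row in table.calls],
        columns=table.locus_ids,
    )
    df.insert(0, "group_id", table.group_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False)


def read_genotypes(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str)
    locus_ids = [c for c in df.columns if c not in ("sample_id", "group_id")]
    calls = np.array(
        [[STRING_CALLS[v] for v in row] for row in df[locus_ids].to_numpy()],
        dtype=np.int8,
    )
    return GenotypeTable(
        sample_ids=list(df["sample_id"]), group_ids=list(df["group_id"]),
        calls=calls, locus_ids=locus_ids,
    )


def write_coordinates(samples: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(dict(
        sample_id=samples["sample_id"],
        x_m=(samples["x_km"] * 1000.0).round(1),
        y_m=(samples["y_km"] * 1000.0).round(1),
    ))
    out.to_csv(path, index=False)


def read_coordinates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return pd.DataFrame(dict(
        sample_id=df["sample_id"], x_km=df["x_m"] / 1000.0, y_km=df["y_m"] / 1000.0,
    ))


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    pd.DataFrame(dict(
        locus_id=panel.locus_ids, locus_class=panel.classes, freq_a=panel.freq_a,
    )).to_csv(path, index=False)


def read_panel(path: str | Path) -> MarkerPanel:
    df = pd.read_csv(path)
    return MarkerPanel(
        locus_ids=list(df["locus_id"]),
        classes=df["locus_class"].to_numpy(dtype=object),
        freq_a=df["freq_a"].to_numpy(dtype=float),
    )


def write_truth_pedigree(individuals: pd.DataFrame, path: str | Path) -> None:
    cols = ["id", "sex", "mother_id", "father_id", "generation", "x_km", "y_km",
            "sampled", "cub_litter"]
    individuals[[c for c in cols if c in individuals.columns]].to_csv(path, index=False)


def read_truth_pedigree(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("mother_id", "father_id"):
        df[c] = df[c].where(df[c].notna(), None)
    return df


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "samples_per_ind_dist" in raw:
        raw["samples_per_ind_dist"] = np.asarray(raw["samples_per_ind_dist"], float)
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    d = asdict(config)
    d["samples_per_ind_dist"] = [float(v) for v in d["samples_per_ind_dist"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
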