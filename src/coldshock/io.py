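"""Delimited-text readers and writers for the pipeline's tables.

LFC tables are TSV with columns gene_id, condition, time_min, lfc, pvalue.
Flow-cytometry samples are per-sample CSV event tables (column ``intensity``)
referenced from a manifest TSV (gene_id, condition, time_min, events_path,
background_path).  Kinetic rates live in YAML keyed by the RateSet field
names.  Moment summaries and Omega series go to TSV with headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd
import yaml

from .cytometry import FlowSample
from .dynamics import OmegaSeries
from .stochastic import MomentSummary, RateSet, ModelVariant

__all__ = [
    "read_lfc_table", "write_lfc_table",
    "load_rates", "dump_rates",
    "read_flow_manifest", "write_flow_samples",
    "write_moment_summary", "read_omega_series", "write_omega_series",
]

_LFC_COLUMNS = ["gene_id", "condition", "time_min", "lfc", "pvalue"]


def read_lfc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_LFC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"LFC table missing columns: {sorted(missing)}")
    bad = df[(df["pvalue"] <= 0) | (df["pvalue"] > 1)]
    if len(bad):
        raise ValueError("p-values must lie in (0, 1]")
    if not np.isfinite(df["lfc"]).all():
        raise ValueError("LFC values must be finite")
    return df


def write_lfc_table(df: pd.DataFrame, path) -> None:
    df[_LFC_COLUMNS].to_csv(path, sep="\t", index=False)


def load_rates(path) -> RateSet:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RateSet.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown rate names: {sorted(unknown)}")
    return RateSet(**{k: float(v) for k, v in data.items()})


def dump_rates(rates: RateSet, path) -> None:
    data = {k: getattr(rates, k) for k in RateSet.__dataclass_fields__
            if getattr(rates, k) != 0.0}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_flow_manifest(path) -> List[FlowSample]:
    manifest = pd.read_csv(path, sep="\t")
    base = Path(path).parent
    samples = []
    for row in manifest.itertuples():
        events = pd.read_csv(base / row.events_path)["intensity"].to_numpy()
        background = pd.read_csv(base / row.background_path)["intensity"].to_numpy()
        samples.append(FlowSample(gene_id=row.gene_id, condition=row.condition,
                                  time_min=row.time_min, events=events,
                                  background_events=background))
    return samples


def write_flow_samples(samples: Iterable[FlowSample], directory) -> Path:
    """Write per-sample event CSVs plus the manifest; returns the manifest path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        stem = f"{s.gene_id}_{s.condition}_{s.time_min:g}"
        ev, bg = f"{stem}_events.csv", f"{stem}_background.csv"
        pd.DataFrame({"intensity": s.events}).to_csv(d / ev, index=False)
        pd.DataFrame({"intensity": s.background_events}).to_csv(d / bg, index=False)
        rows.append({"gene_id": s.gene_id, "condition": s.condition,
                     "time_min": s.time_min, "events_path": ev,
                     "background_path": bg})
    manifest = d / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def write_moment_summary(summary: MomentSummary, variant, path) -> None:
    variant = ModelVariant.parse(variant)
    pd.DataFrame([{"variant": variant.value, "M": summary.M,
                   "variance": summary.variance, "cv2": summary.cv2,
                   "skewness": summary.skewness, "omega": summary.omega,
                   "sem_cv2": summary.sem_cv2}]
                 ).to_csv(path, sep="\t", index=False)


def read_omega_series(path) -> OmegaSeries:
    df = pd.read_csv(path, sep="\t")
    se = df["se"].to_numpy() if "se" in df else None
    condition = str(df["condition"].iloc[0]) if "condition" in df else ""
    return OmegaSeries(times=df["time_min"].to_numpy(),
                       omega_rel=df["omega_rel"].to_numpy(), se=se,
                       condition=condition)


def write_omega_series(series: OmegaSeries, path) -> None:
    df = pd.DataFrame({"time_min": series.times, "omega_rel": series.omega_rel})
    if series.se is not None:
        df["se"] = series.se
    df["condition"] = series.condition
    df.to_csv(path, sep="\t", index=False)
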