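"""TSV/JSON readers and writers for the pipeline's tables.

All tables are plain TSV with headers:

* PSM table: ``psm_id  protein_id  snr  purity  ch_01 ... ch_NN``
* plex design: ``channel_id  genotype  replicate  treatment  day``
* annotations: ``protein_id  organelle  er_class  tm_count``
* truth table: ``protein_id  baseline_log2  step1..step4  atg12_effect  noise_sd``
* flow events: one row per event (CSV also accepted)
* fits: ``protein_id  beta0  beta1..beta4  se1..se4  p1..p4  q1..q4  sigma2  df``

Floats are written at repr (shortest round-trip) precision, so reading a
table back and rewriting it unchanged is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    # round_trip parsing keeps written doubles bit-identical on re-read
    return pd.read_csv(
        path, sep=sep, index_col=index_col, float_precision="round_trip"
    )


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"psm_id", "protein_id", "snr", "purity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PSM table {path} lacks columns {sorted(missing)}")
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"channel_id", "genotype", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table {path} lacks columns {sorted(missing)}")
    if "treatment" not in df.columns:
        df["treatment"] = "none"
    if "day" not in df.columns:
        df["day"] = 0
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"protein_id", "organelle"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path} lacks columns {sorted(missing)}")
    if "er_class" not in df.columns:
        df["er_class"] = ""
    df["er_class"] = df["er_class"].fillna("")
    if "tm_count" not in df.columns:
        df["tm_count"] = 0
    return df


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
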