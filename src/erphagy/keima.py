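"""Ratiometric Keima flux from flow-cytometry event tables.

Keima's excitation maximum shifts from neutral (445 nm) to acidic (561 nm)
environments, so the ratio of mean acidic-excitation signal to mean
neutral-excitation signal over gated cells measures how much reporter has
reached the lysosome.  Samples treated with Bafilomycin A1 (which blocks
lysosomal acidification) define the zero-flux baseline; dividing a sample's
raw ratio by its matched BafA ratio gives the fold-type flux statistic.

Event tables are DataFrames with one row per event and columns
``neutral_signal, acidic_signal, scatter_a, scatter_b, keima_level``.
Gating is rectangular: a live-cell scatter gate, a singlet scatter gate,
and a Keima-positive threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .synthetic import DEFAULT_GATES


@dataclass(frozen=True)
class GateConfig:
    """Rectangular live / singlet / Keima-positive gates."""

    scatter_a_min: float = DEFAULT_GATES["scatter_a_min"]
    scatter_a_max: float = DEFAULT_GATES["scatter_a_max"]
    scatter_b_min: float = DEFAULT_GATES["scatter_b_min"]
    scatter_b_max: float = DEFAULT_GATES["scatter_b_max"]
    keima_min: float = DEFAULT_GATES["keima_min"]

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"gate threshold {name} must be finite")


@dataclass
class GateReport:
    """Per-gate attrition bookkeeping."""

    n_input: int
    n_fail_live: int
    n_fail_singlet: int
    n_fail_keima: int
    n_gated: int


@dataclass
class FluxResult:
    """Ratiometric flux for one sample."""

    sample_id: str
    n_gated: int
    raw_ratio: float
    normalized_flux: float | None = None  # filled by normalize_to_bafa


def gate_events(
    events: pd.DataFrame, gates: GateConfig | None = None
) -> tuple[pd.DataFrame, GateReport]:
    """Apply live, singlet, and Keima-positive gates sequentially.

    Attrition is attributed to the first failed gate in that order.
    """
    g = gates or GateConfig()
    live = events["scatter_a"].between(g.scatter_a_min, g.scatter_a_max)
    singlet = events["scatter_b"].between(g.scatter_b_min, g.scatter_b_max)
    keima_pos = events["keima_level"] >= g.keima_min
    keep = live & singlet & keima_pos
    report = GateReport(
        n_input=len(events),
        n_fail_live=int((~live).sum()),
        n_fail_singlet=int((live & ~singlet).sum()),
        n_fail_keima=int((live & singlet & ~keima_pos).sum()),
        n_gated=int(keep.sum()),
    )
    return events.loc[keep], report


def compute_ratio(events: pd.DataFrame) -> float:
    """Acidic/neutral ratio: mean acidic signal over mean neutral signal."""
    if len(events) < 1:
        raise ValueError("cannot compute a ratio over zero gated events")
    neutral_mean = float(events["neutral_signal"].mean())
    if neutral_mean <= 0:
        raise ValueError("mean neutral signal must be positive")
    return float(events["acidic_signal"].mean()) / neutral_mean


def analyze_sample(
    events: pd.DataFrame,
    sample_id: str,
    gates: GateConfig | None = None,
) -> FluxResult:
    """Gate one sample's events and compute its raw acidic/neutral ratio."""
    gated, report = gate_events(events, gates)
    if report.n_gated == 0:
        raise ValueError(f"sample {sample_id!r}: no events survive gating")
    return FluxResult(
        sample_id=sample_id,
        n_gated=report.n_gated,
        raw_ratio=compute_ratio(gated),
    )


def normalize_to_bafa(
    sample: FluxResult,
    bafa: FluxResult,
    mode: str = "divide",
) -> float:
    """Normalize a sample's ratio to its matched BafA (zero-flux) sample.

    Division (default) yields a fold-over-baseline flux; subtraction is
    available behind ``mode="subtract"`` for an absolute-excess reading.
    A BafA sample normalized against itself gives exactly 1 (or 0).
    """
    if bafa.raw_ratio <= 0:
        raise ValueError("BafA reference ratio must be positive")
    if mode == "divide":
        flux = sample.raw_ratio / bafa.raw_ratio
    elif mode == "subtract":
        flux = sample.raw_ratio - bafa.raw_ratio
    else:
        raise ValueError(f"mode must be 'divide' or 'subtract' (got {mode!r})")
    sample.normalized_flux = flux
    return flux


def flux_table(
    samples: dict[str, pd.DataFrame],
    bafa_of: dict[str, str],
    gates: GateConfig | None = None,
    mode: str = "divide",
) -> pd.DataFrame:
    """Flux for a set of samples, each normalized to its matched BafA sample.

    ``bafa_of`` maps sample_id -> the id of its BafA-treated counterpart
    (missing mapping for a non-BafA sample is an error).  Returns one row
    per sample: ``sample_id, n_gated, raw_ratio, normalized_flux``.
    """
    results = {sid: analyze_sample(ev, sid, gates) for sid, ev in samples.items()}
    rows = []
    for sid, res in results.items():
        ref_id = bafa_of.get(sid, sid if sid in bafa_of.values() else None)
        if ref_id is None:
            raise ValueError(f"no matched BafA sample for {sid!r}")
        normalize_to_bafa(res, results[ref_id], mode=mode)
        rows.append(
            {
                "sample_id": sid,
                "n_gated": res.n_gated,
                "raw_ratio": res.raw_ratio,
                "normalized_flux": res.normalized_flux,
            }
        )
    return pd.DataFrame(rows)
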