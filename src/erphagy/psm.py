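"""PSM-level quality filtering, channel sum normalization, protein roll-up.

The processing contract for isobaric (TMT) reporter quantification:

1. *Filter*: keep PSMs with summed signal-to-noise strictly above 200 and
   isolation purity strictly above 0.5 (co-isolation interference control).
2. *Normalize*: equalize channel loading by scaling every channel so its
   total PSM intensity matches the median channel total across the plex.
3. *Roll up*: protein x channel quantification is the plain sum of the
   normalized intensities of the protein's surviving PSMs, which weights
   peptides by their signal (a weighted-average quantification).

PSM tables are DataFrames with columns ``psm_id, protein_id, snr, purity``
followed by the reporter intensity columns (any column starting ``ch_``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default thresholds
SNR_MIN = 200.0
PURITY_MIN = 0.5

META_COLUMNS = ("psm_id", "protein_id", "snr", "purity")


def channel_columns(psms: pd.DataFrame) -> list[str]:
    """Reporter intensity columns of a PSM table (prefix ``ch_``)."""
    return [c for c in psms.columns if c.startswith("ch_")]


@dataclass
class FilterReport:
    """Bookkeeping for one filter pass."""

    n_input: int
    n_fail_snr: int
    n_fail_purity: int
    n_removed: int  # union of the two criteria
    n_surviving: int
    snr_min: float
    purity_min: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_psms(
    psms: pd.DataFrame,
    snr_min: float = SNR_MIN,
    purity_min: float = PURITY_MIN,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop PSMs at or below the SNR / isolation-purity thresholds.

    Both inequalities are strict: a PSM at exactly ``snr_min`` or exactly
    ``purity_min`` is removed.  Row order of survivors is preserved.
    """
    snr_ok = psms["snr"].to_numpy() > snr_min
    purity_ok = psms["purity"].to_numpy() > purity_min
    keep = snr_ok & purity_ok
    report = FilterReport(
        n_input=len(psms),
        n_fail_snr=int((~snr_ok).sum()),
        n_fail_purity=int((~purity_ok).sum()),
        n_removed=int((~keep).sum()),
        n_surviving=int(keep.sum()),
        snr_min=snr_min,
        purity_min=purity_min,
    )
    return psms.loc[keep].copy(), report


def normalize_channels(
    psms: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum-normalize channels to the median channel total.

    Per channel ``c`` with pre-normalization total ``T_c``, the scale
    factor is ``median_c(T) / T_c``; every intensity in the channel is
    multiplied by it, so every post-normalization channel total equals the
    pre-normalization median total (for an even plex size the median is the
    mean of the two middle totals).

    Returns the normalized table and the per-channel factors.
    Raises ``ValueError`` naming the channel if any channel total is zero.
    """
    if len(psms) < 1:
        raise ValueError("cannot normalize an empty PSM table")
    chans = channel_columns(psms)
    if len(chans) < 2:
        raise ValueError("channel normalization needs at least 2 channels")
    totals = psms[chans].sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(
            f"cannot normalize: channel(s) {zero} have zero total intensity"
        )
    factors = totals.median() / totals
    out = psms.copy()
    out[chans] = psms[chans] * factors
    return out, factors


@dataclass
class ProteinQuant:
    """Protein-level quantification matrix with provenance.

    ``matrix`` is proteins x channels of summed input-normalized reporter
    intensities.  Proteins with zero surviving PSMs are absent rather than
    zero-filled.  ``provenance`` records how the matrix was produced.
    """

    matrix: pd.DataFrame
    psm_counts: pd.Series
    provenance: dict = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def channels(self) -> list[str]:
        return self.matrix.columns.tolist()


def rollup_proteins(
    psms: pd.DataFrame,
    filtered: bool = True,
    normalized: bool = True,
) -> ProteinQuant:
    """Sum each protein's PSM intensities per channel.

    The ``filtered`` / ``normalized`` flags record (in provenance) whether
    the upstream stages ran; the roll-up itself is a plain group-by sum.
    """
    chans = channel_columns(psms)
    grouped = psms.groupby("protein_id", sort=True)
    matrix = grouped[chans].sum()
    counts = grouped.size().rename("n_psms")
    return ProteinQuant(
        matrix=matrix,
        psm_counts=counts,
        provenance={
            "filtered": filtered,
            "normalized": normalized,
            "n_psms_used": int(len(psms)),
        },
    )


def process_psms(
    psms: pd.DataFrame,
    snr_min: float = SNR_MIN,
    purity_min: float = PURITY_MIN,
    filter_first: bool = True,
) -> tuple[ProteinQuant, dict]:
    """Full filter -> normalize -> roll-up chain.

    ``filter_first=True`` (default) computes normalization totals on
    surviving PSMs only, matching the stated processing order; with
    ``False`` the channels are normalized on the full table before
    filtering.  Returns the protein quantification and a JSON-ready report
    (filter counts plus normalization factors).
    """
    if filter_first:
        kept, report = filter_psms(psms, snr_min, purity_min)
        normed, factors = normalize_channels(kept)
    else:
        normed, factors = normalize_channels(psms)
        normed, report = filter_psms(normed, snr_min, purity_min)
    quant = rollup_proteins(normed)
    quant.provenance["filter_first"] = filter_first
    info = {
        "filter": report.to_dict(),
        "normalization_factors": {k: float(v) for k, v in factors.items()},
        "filter_first": filter_first,
        "n_proteins": len(quant.matrix),
    }
    return quant, info
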