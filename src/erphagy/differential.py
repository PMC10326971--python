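"""WT-centered relative abundance, pairwise Student's t-tests, BH correction.

Protein reporter intensities are log2-transformed and centered to the mean
of the designated reference replicates (typically wild-type, day 12), giving
the response used both for mutant-vs-WT comparisons and for the allelic
linear model.  Pairwise comparisons use the pooled-variance (Student's)
two-sample t-test; p-values are adjusted with the Benjamini-Hochberg
step-up across all proteins of one contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DesignError

ALPHA_DEFAULT = 0.05


@dataclass
class NormalizedAbundance:
    """Log2 intensities centered to the reference-replicate mean per protein.

    ``data`` is proteins x channels; per protein, the mean over the
    reference channels is 0 by construction.  ``dropped`` lists proteins
    removed because some channel intensity was non-positive (log undefined;
    no imputation is attempted).
    """

    data: pd.DataFrame
    reference: str
    reference_channels: list[str]
    dropped: list[str] = field(default_factory=list)


def log2_relative_to_reference(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    reference_genotype: str = "WT",
) -> NormalizedAbundance:
    """Center log2 protein intensities on the reference genotype's mean.

    ``matrix`` is a protein x channel intensity matrix (e.g.
    ``ProteinQuant.matrix``); ``design`` maps ``channel_id`` to genotype.
    Only design channels present in the matrix are used.  Proteins with any
    non-positive intensity in the used channels are dropped and reported.
    """
    ref_channels = design.loc[
        design["genotype"] == reference_genotype, "channel_id"
    ].tolist()
    ref_channels = [c for c in ref_channels if c in matrix.columns]
    if len(ref_channels) == 0:
        raise DesignError(
            f"reference genotype {reference_genotype!r} absent from the design"
        )
    if len(ref_channels) < 2:
        raise DesignError(
            f"reference genotype {reference_genotype!r} needs >=2 replicate "
            f"channels (found {len(ref_channels)})"
        )
    used = [c for c in design["channel_id"] if c in matrix.columns]
    sub = matrix[used]
    positive = (sub > 0).all(axis=1)
    dropped = sub.index[~positive].tolist()
    logged = np.log2(sub.loc[positive])
    centered = logged.sub(logged[ref_channels].mean(axis=1), axis=0)
    return NormalizedAbundance(
        data=centered,
        reference=reference_genotype,
        reference_channels=ref_channels,
        dropped=dropped,
    )


# Backwards-friendly alias: the usual reference is the WT control.
log2_relative_to_wt = log2_relative_to_reference


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    Standard step-up: sort ascending, q_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1.  Values outside [0, 1] raise ``ValueError``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def pairwise_test(
    norm: NormalizedAbundance,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-protein pooled-variance t-test between two channel groups.

    ``log2fc`` is mean(group_a) - mean(group_b) of the centered log2
    values.  Degenerate proteins with zero variance in both groups get
    p = 1 when the means are equal (nothing to detect) and p = 0 when they
    differ (infinitely strong evidence under the pooled model); both are
    conventions for a case the t statistic leaves undefined.

    Returns a DataFrame indexed by protein with columns
    ``log2fc, t, p, q``; q-values are BH-adjusted across all tested
    proteins of this contrast.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise DesignError("both groups need >=2 samples")
    if set(group_a) & set(group_b):
        raise DesignError(
            f"groups overlap: {sorted(set(group_a) & set(group_b))}"
        )
    a = norm.data[group_a].to_numpy()
    b = norm.data[group_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    diff = a.mean(axis=1) - b.mean(axis=1)

    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = degenerate & np.isclose(diff, 0.0)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    unequal = degenerate & ~equal_means
    t = np.where(unequal, np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(unequal, 0.0, p)

    out = pd.DataFrame(
        {"log2fc": diff, "t": t, "p": p},
        index=norm.data.index,
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def summarize_contrast(results: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> dict:
    """JSON-ready summary of one pairwise contrast."""
    sig = results["q"] < alpha
    return {
        "n_tested": int(len(results)),
        "alpha": alpha,
        "n_significant": int(sig.sum()),
        "n_up": int((sig & (results["log2fc"] > 0)).sum()),
        "n_down": int((sig & (results["log2fc"] < 0)).sum()),
    }
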