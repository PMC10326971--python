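"""Cumulative-indicator linear model over the nested knockout allelic series.

For each protein, the WT-centered log2 abundance Y of sample *i* is modeled
as

    Y_i = b0 + b1*x_i1 + b2*x_i2 + b3*x_i3 + b4*x_i4 + e_i

where x_ik = 1 when sample *i* "contains" the receptor knockouts added at
step *k* of the series (WT->DKO, DKO->TKO, TKO->QKO, QKO->PKO) and 0
otherwise.  Because deeper mutants contain every earlier deletion, the
indicators nest (x1 >= x2 >= x3 >= x4 row-wise) and the coding is lower
triangular over genotype group means: in a balanced design each b_k is
exactly the successive group-mean difference (DKO-WT, TKO-DKO, QKO-TKO,
PKO-QKO), i.e. the average log2 fold change attributable to the receptor(s)
deleted at that step.

Fits are per-protein ordinary least squares with coefficient standard
errors from the residual variance and the normal-equations inverse,
two-sided t-distribution p-values on residual_df = n - 5, and
Benjamini-Hochberg q-values computed across proteins separately for each of
the four coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ALPHA_DEFAULT, NormalizedAbundance, bh_adjust
from .errors import DesignError
from .genotypes import ALLELIC_SERIES, GENOTYPE_INDICATORS, STEP_LABELS, STEP_RECEPTORS

X_COLUMNS = ("intercept", "x1", "x2", "x3", "x4")

BETA_COLUMNS = ["beta1", "beta2", "beta3", "beta4"]
SE_COLUMNS = ["se1", "se2", "se3", "se4"]
P_COLUMNS = ["p1", "p2", "p3", "p4"]
Q_COLUMNS = ["q1", "q2", "q3", "q4"]


@dataclass
class AllelicDesign:
    """Design matrix for the allelic subset of one plex.

    ``X`` is samples x (intercept, x1..x4) of 0/1; ``genotypes`` gives the
    genotype per retained sample; ``excluded`` lists (channel, reason) for
    samples outside the allelic series (single KOs, ATG12 control, treated
    samples).
    """

    X: pd.DataFrame
    genotypes: pd.Series
    excluded: pd.DataFrame
    fit_intercept: bool = True

    @property
    def n_samples(self) -> int:
        return len(self.X)


def build_design(
    design: pd.DataFrame,
    treatments_allowed: tuple[str, ...] = ("none",),
) -> AllelicDesign:
    """Build the cumulative-indicator design matrix from a plex design table.

    Channels whose genotype is outside {WT, DKO, TKO, QKO, PKO} or whose
    treatment is not allowed are excluded and reported.  Requesting the
    model with any of the five series genotypes missing (or below 2
    replicates) is a design error naming the genotype.
    """
    rows = []
    excluded = []
    for _, r in design.iterrows():
        g = r["genotype"]
        treatment = r.get("treatment", "none")
        if g not in GENOTYPE_INDICATORS:
            excluded.append((r["channel_id"], f"genotype {g} outside allelic series"))
            continue
        if treatment not in treatments_allowed:
            excluded.append((r["channel_id"], f"treatment {treatment} excluded"))
            continue
        x = GENOTYPE_INDICATORS[g]
        rows.append((r["channel_id"], g, 1, *x))

    kept = pd.DataFrame(
        rows, columns=["channel_id", "genotype", *X_COLUMNS]
    ).set_index("channel_id")
    counts = kept["genotype"].value_counts()
    for g in ALLELIC_SERIES:
        if counts.get(g, 0) == 0:
            raise DesignError(f"allelic model requires genotype {g!r}: absent")
        if counts.get(g, 0) < 2:
            raise DesignError(
                f"allelic model requires >=2 replicates of {g!r} "
                f"(found {counts.get(g, 0)})"
            )
    return AllelicDesign(
        X=kept[list(X_COLUMNS)].astype(float),
        genotypes=kept["genotype"],
        excluded=pd.DataFrame(excluded, columns=["channel_id", "reason"]),
    )


def fit_allelic_model(
    norm: NormalizedAbundance,
    design: AllelicDesign,
    fit_intercept: bool = True,
) -> pd.DataFrame:
    """Per-protein OLS fit of the cumulative-indicator model.

    The response is the WT-centered log2 abundance of the allelic-subset
    channels.  With ``fit_intercept=False`` the intercept column is dropped
    (the centered WT mean is ~0, so this variant changes little; it exists
    for comparison).

    Returns a DataFrame indexed by protein with columns ``beta0,
    beta1..beta4, se1..se4, p1..p4, sigma2, df`` (q-values are added by
    :func:`adjust_coefficients`).  When residual_df is 0, coefficients are
    returned with SE/p set to NaN.
    """
    channels = [c for c in design.X.index if c in norm.data.columns]
    missing = [c for c in design.X.index if c not in norm.data.columns]
    if missing:
        raise DesignError(f"design channels missing from abundance matrix: {missing}")
    X = design.X.loc[channels].to_numpy()
    if not fit_intercept:
        X = X[:, 1:]
    n, k = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < k:
        raise DesignError("rank-deficient allelic design matrix")
    xtx_inv = np.linalg.inv(xtx)
    hat = xtx_inv @ X.T  # k x n; betas = hat @ y

    Y = norm.data[channels].to_numpy()  # proteins x n
    betas = Y @ hat.T  # proteins x k
    resid = Y - betas @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    df = n - k
    if df > 0:
        sigma2 = rss / df
        se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = betas / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        # zero residual variance: exact fit, treat nonzero betas as certain
        exact = sigma2 == 0
        if exact.any():
            p[exact] = np.where(betas[exact] == 0.0, 1.0, 0.0)
    else:
        sigma2 = np.full(Y.shape[0], np.nan)
        se = np.full_like(betas, np.nan)
        p = np.full_like(betas, np.nan)

    cols: dict[str, np.ndarray] = {}
    offset = 1 if fit_intercept else 0
    cols["beta0"] = betas[:, 0] if fit_intercept else np.zeros(Y.shape[0])
    for j in range(4):
        cols[BETA_COLUMNS[j]] = betas[:, offset + j]
    for j in range(4):
        cols[SE_COLUMNS[j]] = se[:, offset + j]
    for j in range(4):
        cols[P_COLUMNS[j]] = p[:, offset + j]
    cols["sigma2"] = sigma2
    cols["df"] = np.full(Y.shape[0], df)
    out = pd.DataFrame(cols, index=norm.data.index)
    out.attrs["fit_intercept"] = fit_intercept
    out.attrs["n_samples"] = n
    return out


def adjust_coefficients(fits: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust p-values across proteins, one family per coefficient.

    Each of the four step coefficients forms its own multiple-testing
    family (matching how individual coefficients are called significant);
    q-values are monotone in p within each family.
    """
    out = fits.copy()
    for pc, qc in zip(P_COLUMNS, Q_COLUMNS):
        p = out[pc].to_numpy()
        ok = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = bh_adjust(p[ok])
        out[qc] = q
    return out


@dataclass
class StepSummary:
    """Interpretation of one fitted step coefficient."""

    protein_id: str
    step: int
    label: str  # e.g. "WT->DKO"
    receptor: str  # receptor(s) whose deletion the step adds
    beta: float
    q: float
    direction: str  # "up" | "down" | "ns"
    alpha: float = ALPHA_DEFAULT


def interpret_step(
    fits: pd.DataFrame,
    protein_id: str,
    step: int,
    alpha: float = ALPHA_DEFAULT,
) -> StepSummary:
    """Label one coefficient with its receptor and significance direction.

    Step k attributes the average fold change between consecutive mutants
    to the receptor deleted at that step (1: FAM134A/C, 2: FAM134B,
    3: TEX264, 4: CCPG1).  Direction is the sign of beta when q < alpha,
    otherwise "ns".
    """
    if step not in (1, 2, 3, 4):
        raise ValueError(f"step must be in 1..4 (got {step})")
    row = fits.loc[protein_id]
    beta = float(row[f"beta{step}"])
    q = float(row[f"q{step}"])
    if not np.isnan(q) and q < alpha and beta != 0:
        direction = "up" if beta > 0 else "down"
    else:
        direction = "ns"
    return StepSummary(
        protein_id=protein_id,
        step=step,
        label=STEP_LABELS[step - 1],
        receptor=STEP_RECEPTORS[step],
        beta=beta,
        q=q,
        direction=direction,
        alpha=alpha,
    )


def fitted_genotype_means(fits: pd.DataFrame) -> pd.DataFrame:
    """Fitted mean per allelic genotype: beta0 plus the cumulative betas.

    By the telescoping structure, the WT fitted mean is beta0 and the PKO
    fitted mean is beta0 + beta1 + beta2 + beta3 + beta4.
    """
    cum = fits[BETA_COLUMNS].cumsum(axis=1)
    out = pd.DataFrame(index=fits.index)
    out["WT"] = fits["beta0"]
    for g, col in zip(("DKO", "TKO", "QKO", "PKO"), BETA_COLUMNS):
        out[g] = fits["beta0"] + cum[col]
    return out
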