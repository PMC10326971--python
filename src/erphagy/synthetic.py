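"""Synthetic TMT proteomics and Keima flow-cytometry data with planted truth.

Every downstream stage of the pipeline (PSM filtering, channel
normalization, protein roll-up, WT-centered differential abundance, the
allelic-series linear model, category aggregation, and the ratiometric flux
statistic) is testable against data generated here, where the ground truth
— per-protein baseline abundance, per-step log2 effects, noise level, gate
membership, acidic-population fraction — is known exactly.

Generative model
----------------
For protein ``p`` in channel ``c`` carrying genotype ``g``:

    log2 E[I_pc] = baseline_p + effect_p(g) + log2(loading_c)

where ``effect_p(g)`` is the cumulative sum of planted step effects up to
``g`` for allelic-series genotypes, the ATG12 effect for the autophagy-dead
control, and a per-genotype lookup for single knockouts.  Biological
replicate noise is additive Gaussian on the log2 scale at the protein x
channel level.  The protein's channel intensity is then partitioned across
its PSMs with multiplicative lognormal share noise (shares renormalized so
PSM intensities sum exactly to the protein intensity, mirroring summed
roll-up being the inverse of the split).

Flow-cytometry events come from a two-component mixture of neutral-dominant
and acidic-dominant cells; a configurable fraction of events is planted
outside the live/single/Keima-positive gates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotypes import (
    ALLELIC_SERIES,
    ATG12_KO,
    GENOTYPE_INDICATORS,
    SINGLE_KOS,
)

# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

#: er_class labels recognised for ER proteins.
ER_CLASSES: tuple[str, ...] = ("curvature", "associated", "membrane", "lumen", "receptor")

#: Default organelle / ER-subcompartment proportions.  ER classes are keyed
#: as "ER:<class>"; the ER share mirrors an ER proteome of a few hundred
#: proteins inside a few-thousand-protein neuronal proteome.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "ER:curvature": 0.024,
    "ER:associated": 0.054,
    "ER:membrane": 0.135,
    "ER:lumen": 0.075,
    "ER:receptor": 0.012,
    "mitochondria": 0.15,
    "lysosome": 0.05,
    "Golgi": 0.05,
    "peroxisome": 0.02,
    "nucleus": 0.18,
    "cytosol": 0.25,
}

#: ER-class proportions used when generating an ER-only annotation table.
ER_ONLY_PROPORTIONS: dict[str, float] = {
    "ER:curvature": 0.08,
    "ER:associated": 0.18,
    "ER:membrane": 0.45,
    "ER:lumen": 0.25,
    "ER:receptor": 0.04,
}


def _split_category(key: str) -> tuple[str, str]:
    """'ER:lumen' -> ('ER', 'lumen'); 'cytosol' -> ('cytosol', '')."""
    if ":" in key:
        organelle, er_class = key.split(":", 1)
        if organelle != "ER":
            raise ConfigurationError(
                f"subcompartment syntax is reserved for ER (got {key!r})"
            )
        if er_class not in ER_CLASSES:
            raise ConfigurationError(f"unknown ER class {er_class!r} in {key!r}")
        return organelle, er_class
    return key, ""


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of ``n`` items to categories by largest remainder.

    Deterministic and seed-free: floor every expectation, then hand the
    leftover units to the largest fractional remainders, breaking ties by
    category name order.
    """
    total = sum(proportions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ConfigurationError(
            f"class proportions must sum to 1 (got {total!r} for {proportions!r})"
        )
    names = sorted(proportions)
    floors = {k: int(math.floor(n * proportions[k])) for k in names}
    leftover = n - sum(floors.values())
    remainders = sorted(
        names, key=lambda k: (-(n * proportions[k] - floors[k]), k)
    )
    for k in remainders[:leftover]:
        floors[k] += 1
    return floors


def generate_annotations(
    n_proteins: int,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a protein annotation table.

    Returns a DataFrame with columns ``protein_id, organelle, er_class,
    tm_count``.  Category counts follow the deterministic largest-remainder
    allocation; the seed only randomizes transmembrane-segment counts.
    """
    if n_proteins < 0:
        raise ConfigurationError("n_proteins must be non-negative")
    props = dict(class_proportions or DEFAULT_PROPORTIONS)
    counts = largest_remainder_counts(n_proteins, props)
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    idx = 0
    for key in sorted(props):
        organelle, er_class = _split_category(key)
        for _ in range(counts[key]):
            idx += 1
            rows.append(
                {
                    "protein_id": f"P{idx:05d}",
                    "organelle": organelle,
                    "er_class": er_class,
                    "tm_count": _draw_tm_count(rng, organelle, er_class),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "organelle", "er_class", "tm_count"]
    )


def _draw_tm_count(rng: np.random.Generator, organelle: str, er_class: str) -> int:
    # Lumenal/associated proteins are soluble (0 TM); membrane-embedded
    # classes carry 1+ segments, curvature hairpins typically 2-4.
    if er_class in ("lumen", "associated"):
        return 0
    if er_class == "curvature":
        return int(rng.integers(2, 5))
    if er_class in ("membrane", "receptor"):
        return int(1 + rng.geometric(0.45))
    if organelle in ("cytosol", "nucleus"):
        return 0
    return int(rng.integers(0, 3))


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

#: columns of a truth table
TRUTH_COLUMNS = [
    "protein_id",
    "baseline_log2",
    "step1",
    "step2",
    "step3",
    "step4",
    "atg12_effect",
    "noise_sd",
]

STEP_COLUMNS = ["step1", "step2", "step3", "step4"]


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect for one (er_class, step) cell of the configuration."""

    mean: float
    sd: float
    fraction: float  # fraction of the class's proteins that are affected

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(
                f"fraction_affected must be in [0, 1] (got {self.fraction})"
            )
        if self.sd < 0:
            raise ConfigurationError("effect sd must be non-negative")


EffectConfig = dict[tuple[str, int], EffectSpec]


def plant_effects(
    annotations: pd.DataFrame,
    effect_config: EffectConfig,
    noise_sd: float = 0.2,
    seed: int = 0,
    baseline_mean: float = 16.0,
    baseline_sd: float = 1.5,
    atg12_mimics_pko: bool = True,
    single_ko_effects: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Assign planted per-protein step effects given a class-level config.

    ``effect_config`` maps ``(er_class, step)`` (step in 1..4) to an
    :class:`EffectSpec`.  Within a configured class, each protein is affected
    with probability ``fraction``; affected proteins draw a Normal(mean, sd)
    log2 effect at that step, unaffected ones carry exactly 0.  The ATG12
    control effect defaults to the cumulative sum of all four steps (a full
    autophagy block approximates the penta knockout for ER cargo).

    ``single_ko_effects`` optionally maps a single-KO genotype label to a
    ``{protein_id: effect}`` dict; unspecified proteins get 0.

    Returns the truth table (one row per protein) with columns
    ``protein_id, baseline_log2, step1..step4, atg12_effect, noise_sd`` plus
    one ``sko_<genotype>`` column per configured single knockout.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    known_classes = set(annotations["er_class"].unique()) - {""}
    for (er_class, step) in effect_config:
        if er_class not in known_classes:
            raise ConfigurationError(
                f"effect_config references er_class {er_class!r} absent from "
                f"the annotation table (present: {sorted(known_classes)})"
            )
        if step not in (1, 2, 3, 4):
            raise ConfigurationError(f"step must be in 1..4 (got {step})")

    rng = np.random.default_rng(seed)
    n = len(annotations)
    truth = pd.DataFrame(
        {
            "protein_id": annotations["protein_id"].to_numpy(),
            "baseline_log2": rng.normal(baseline_mean, baseline_sd, n),
            "step1": 0.0,
            "step2": 0.0,
            "step3": 0.0,
            "step4": 0.0,
            "atg12_effect": 0.0,
            "noise_sd": noise_sd,
        }
    )
    er_class_arr = annotations["er_class"].to_numpy()
    for (er_class, step), spec in sorted(effect_config.items()):
        members = np.flatnonzero(er_class_arr == er_class)
        affected = members[rng.random(members.size) < spec.fraction]
        effects = rng.normal(spec.mean, spec.sd, affected.size)
        truth.loc[affected, f"step{step}"] += effects

    if atg12_mimics_pko:
        truth["atg12_effect"] = truth[STEP_COLUMNS].sum(axis=1)

    for genotype, per_protein in (single_ko_effects or {}).items():
        col = f"sko_{genotype}"
        truth[col] = truth["protein_id"].map(per_protein).fillna(0.0)

    truth.attrs["seed"] = seed
    return truth


def genotype_effect(truth: pd.DataFrame, genotype: str) -> np.ndarray:
    """Expected log2 effect vs WT for every protein under ``genotype``."""
    if genotype == "WT":
        return np.zeros(len(truth))
    if genotype in GENOTYPE_INDICATORS:
        x = GENOTYPE_INDICATORS[genotype]
        return sum(
            x[k] * truth[f"step{k + 1}"].to_numpy() for k in range(4)
        )
    if genotype == ATG12_KO:
        return truth["atg12_effect"].to_numpy()
    col = f"sko_{genotype}"
    if col in truth.columns:
        return truth[col].to_numpy()
    if genotype in SINGLE_KOS:
        return np.zeros(len(truth))
    raise ConfigurationError(f"unknown genotype {genotype!r}")


# ---------------------------------------------------------------------------
# Plex designs
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["channel_id", "genotype", "replicate", "treatment", "day"]


def make_design(
    genotypes: list[str] | None = None,
    replicates: int = 3,
    treatment: str = "none",
    day: int = 12,
) -> pd.DataFrame:
    """Build a plex-design table: channel -> (genotype, replicate, treatment, day).

    The default is an 18-plex-style layout of the five allelic-series
    genotypes plus the ATG12 control at 3 replicates each.
    """
    if genotypes is None:
        genotypes = list(ALLELIC_SERIES) + [ATG12_KO]
    rows = []
    ch = 0
    for g in genotypes:
        for r in range(1, replicates + 1):
            ch += 1
            rows.append(
                {
                    "channel_id": f"ch_{ch:02d}",
                    "genotype": g,
                    "replicate": r,
                    "treatment": treatment,
                    "day": day,
                }
            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def allelic_design(replicates: int = 4, day: int = 12) -> pd.DataFrame:
    """Design containing only the five allelic-series genotypes."""
    return make_design(list(ALLELIC_SERIES), replicates=replicates, day=day)


# ---------------------------------------------------------------------------
# Protein-level and PSM-level simulation
# ---------------------------------------------------------------------------


def expected_log2_matrix(
    truth: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Noise-free expected log2 intensity per protein x channel (loading 1)."""
    cols = {}
    for _, row in design.iterrows():
        cols[row["channel_id"]] = (
            truth["baseline_log2"].to_numpy() + genotype_effect(truth, row["genotype"])
        )
    return pd.DataFrame(cols, index=truth["protein_id"].to_numpy())


def simulate_protein_matrix(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Protein-level log2 intensities: expectation + Gaussian replicate noise.

    This bypasses the PSM/normalization layer and is the generator of choice
    for estimator-calibration studies where the response should carry only
    the planted mean structure and i.i.d. log2 noise.
    """
    rng = np.random.default_rng(seed)
    mat = expected_log2_matrix(truth, design)
    noise = rng.normal(
        0.0, truth["noise_sd"].to_numpy()[:, None], mat.shape
    )
    return mat + noise


@dataclass(frozen=True)
class PsmSimConfig:
    """Tunables of the PSM-level measurement simulation."""

    psms_per_protein: int | tuple[int, int] = 3  # fixed, or inclusive uniform range
    psm_split_sd: float = 0.5  # lognormal sigma of PSM share weights
    snr_scale: float = 6e-3  # summed SNR = snr_scale * summed intensity * noise
    snr_noise_sd: float = 0.4  # lognormal sigma on SNR
    snr_fixed: float | None = None  # overrides the proportional model
    purity_beta: tuple[float, float] = (8.0, 2.0)
    purity_fixed: float | None = None
    low_snr_fraction: float = 0.05  # planted below the SNR threshold
    low_purity_fraction: float = 0.05  # planted below the purity threshold


def simulate_psm_table(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    config: PsmSimConfig | None = None,
    channel_loading: np.ndarray | str = "random",
    loading_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a PSM-level reporter-intensity table for one plex.

    Returns a DataFrame with columns ``psm_id, protein_id, snr, purity``
    followed by one intensity column per design channel.  The expected
    per-channel protein log2 signal is baseline + genotype effect +
    log2(loading); the protein intensity is partitioned across its PSMs with
    multiplicative lognormal share noise (shares sum to 1, so summed roll-up
    recovers the protein intensity exactly).  A configurable fraction of
    PSMs is planted below the SNR / purity thresholds so the filter stage is
    never vacuous.
    """
    if len(truth) == 0:
        raise ConfigurationError("truth table is empty")
    cfg = config or PsmSimConfig()
    channels = design["channel_id"].tolist()
    n_ch = len(channels)
    rng = np.random.default_rng(seed)

    if isinstance(channel_loading, str):
        if channel_loading != "random":
            raise ConfigurationError(f"unknown loading spec {channel_loading!r}")
        loading = np.exp(rng.normal(0.0, loading_sd * math.log(2), n_ch))
    else:
        loading = np.asarray(channel_loading, dtype=float)
        if loading.shape != (n_ch,):
            raise ConfigurationError(
                f"channel_loading length {loading.size} != plex size {n_ch}"
            )
        if np.any(loading <= 0):
            raise ConfigurationError("channel loading factors must be positive")

    log2_expect = expected_log2_matrix(truth, design).to_numpy()
    noise_sd = truth["noise_sd"].to_numpy()[:, None]
    log2_protein = (
        log2_expect
        + rng.normal(0.0, 1.0, log2_expect.shape) * noise_sd
        + np.log2(loading)[None, :]
    )
    protein_intensity = np.power(2.0, log2_protein)

    if isinstance(cfg.psms_per_protein, int):
        n_psms = np.full(len(truth), cfg.psms_per_protein, dtype=int)
    else:
        lo, hi = cfg.psms_per_protein
        n_psms = rng.integers(lo, hi + 1, len(truth))
    if np.any(n_psms < 1):
        raise ConfigurationError("psms_per_protein must be >= 1")

    rows_protein: list[str] = []
    shares: list[np.ndarray] = []
    for i, pid in enumerate(truth["protein_id"]):
        k = n_psms[i]
        if cfg.psm_split_sd > 0 and k > 1:
            w = np.exp(rng.normal(0.0, cfg.psm_split_sd, k))
        else:
            w = np.ones(k)
        shares.append(w / w.sum())
        rows_protein.extend([pid] * k)
    share_vec = np.concatenate(shares)
    protein_row_idx = np.repeat(np.arange(len(truth)), n_psms)
    intensities = protein_intensity[protein_row_idx] * share_vec[:, None]

    summed = intensities.sum(axis=1)
    if cfg.snr_fixed is not None:
        snr = np.full(summed.size, float(cfg.snr_fixed))
    else:
        snr = cfg.snr_scale * summed * np.exp(
            rng.normal(0.0, cfg.snr_noise_sd, summed.size)
        )
    if cfg.purity_fixed is not None:
        purity = np.full(summed.size, float(cfg.purity_fixed))
    else:
        a, b = cfg.purity_beta
        purity = rng.beta(a, b, summed.size)

    # Planted filter fodder: force a random subset below each threshold.
    if cfg.low_snr_fraction > 0 and cfg.snr_fixed is None:
        mask = rng.random(summed.size) < cfg.low_snr_fraction
        snr[mask] = rng.uniform(10.0, 200.0, mask.sum())
    if cfg.low_purity_fraction > 0 and cfg.purity_fixed is None:
        mask = rng.random(summed.size) < cfg.low_purity_fraction
        purity[mask] = rng.uniform(0.0, 0.5, mask.sum())

    table = pd.DataFrame(
        {
            "psm_id": [f"psm_{i + 1:06d}" for i in range(summed.size)],
            "protein_id": rows_protein,
            "snr": snr,
            "purity": purity,
        }
    )
    for j, ch in enumerate(channels):
        table[ch] = intensities[:, j]
    table.attrs["seed"] = seed
    table.attrs["channel_loading"] = loading.tolist()
    return table


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowCondition:
    """Mixture parameters for one (genotype, treatment, day) flow sample."""

    acidic_fraction: float
    neutral_hi: float = 1000.0  # neutral-channel mean of neutral-dominant cells
    neutral_lo: float = 300.0  # neutral-channel mean of acidic-dominant cells
    acidic_hi: float = 2000.0  # acidic-channel mean of acidic-dominant cells
    acidic_lo: float = 200.0  # acidic-channel mean of neutral-dominant cells
    cv: float = 0.25  # lognormal coefficient of variation within a component

    def __post_init__(self) -> None:
        if not 0.0 <= self.acidic_fraction <= 1.0:
            raise ConfigurationError("acidic_fraction must be in [0, 1]")


#: Acidic fraction floor applied to lysosome-inhibited (BafA) samples.
BAFA_FLOOR = 0.02

#: Rectangular gates matching the generator's in-gate event distributions.
DEFAULT_GATES = {
    "scatter_a_min": 20000.0,
    "scatter_a_max": 80000.0,
    "scatter_b_min": 20000.0,
    "scatter_b_max": 80000.0,
    "keima_min": 100.0,
}

FLOW_COLUMNS = [
    "neutral_signal",
    "acidic_signal",
    "scatter_a",
    "scatter_b",
    "keima_level",
    "true_component",
    "true_in_gate",
]


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = math.log(mean) - sigma**2 / 2
    return rng.lognormal(mu, sigma, n)


def simulate_flow_sample(
    condition: FlowCondition,
    n_events: int = 10000,
    ungated_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one flow sample as a two-component Keima mixture.

    At least 10,000 events per sample is the default acquisition floor.
    Columns ``true_component`` ("neutral"/"acidic") and ``true_in_gate``
    record the planted labels for verification; real event tables simply
    lack them.
    """
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")
    rng = np.random.default_rng(seed)
    p = condition.acidic_fraction
    is_acidic = rng.random(n_events) < p
    n_ac = int(is_acidic.sum())
    n_ne = n_events - n_ac

    neutral = np.empty(n_events)
    acidic = np.empty(n_events)
    neutral[~is_acidic] = _lognormal_around(rng, condition.neutral_hi, condition.cv, n_ne)
    acidic[~is_acidic] = _lognormal_around(rng, condition.acidic_lo, condition.cv, n_ne)
    neutral[is_acidic] = _lognormal_around(rng, condition.neutral_lo, condition.cv, n_ac)
    acidic[is_acidic] = _lognormal_around(rng, condition.acidic_hi, condition.cv, n_ac)

    scatter_a = rng.normal(50000.0, 8000.0, n_events).clip(21000.0, 79000.0)
    scatter_b = rng.normal(50000.0, 8000.0, n_events).clip(21000.0, 79000.0)
    keima = _lognormal_around(rng, 5000.0, 0.5, n_events) + 200.0

    out = rng.random(n_events) < ungated_fraction
    which = rng.integers(0, 3, n_events)
    scatter_a[out & (which == 0)] = 5000.0  # debris: fails the live gate
    scatter_b[out & (which == 1)] = 95000.0  # doublets: fail the singlet gate
    keima[out & (which == 2)] = 10.0  # Keima-negative cells

    return pd.DataFrame(
        {
            "neutral_signal": neutral,
            "acidic_signal": acidic,
            "scatter_a": scatter_a,
            "scatter_b": scatter_b,
            "keima_level": keima,
            "true_component": np.where(is_acidic, "acidic", "neutral"),
            "true_in_gate": ~out,
        }
    )


def simulate_flow_events(
    genotype_params: dict[tuple[str, str], FlowCondition],
    n_events: int = 10000,
    ungated_fraction: float = 0.05,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate one event table per (genotype, treatment) sample.

    BafA-treated samples have their acidic fraction forced to the
    lysosome-inhibition floor regardless of the configured value, since
    blocking acidification removes the acidic Keima population.
    Returns ``{sample_id: events}`` with ``sample_id = "<genotype>_<treatment>"``;
    each table carries ``genotype`` and ``treatment`` in ``attrs``.
    """
    tables: dict[str, pd.DataFrame] = {}
    for i, ((genotype, treatment), cond) in enumerate(sorted(genotype_params.items())):
        if treatment == "BafA" and cond.acidic_fraction > BAFA_FLOOR:
            cond = FlowCondition(
                BAFA_FLOOR,
                cond.neutral_hi,
                cond.neutral_lo,
                cond.acidic_hi,
                cond.acidic_lo,
                cond.cv,
            )
        sample_id = f"{genotype}_{treatment}"
        events = simulate_flow_sample(
            cond, n_events=n_events, ungated_fraction=ungated_fraction,
            seed=seed + i,
        )
        events.attrs.update(
            sample_id=sample_id, genotype=genotype, treatment=treatment
        )
        tables[sample_id] = events
    return tables


# ---------------------------------------------------------------------------
# Paper-like preset
# ---------------------------------------------------------------------------

#: Class-level planted effects emulating the observed remodeling pattern:
#: ER-membrane proteins accumulate once FAM134A/C are lost (positive step 1),
#: a lumenal subset additionally accumulates only when CCPG1 is removed
#: (positive step 4), and a small curvature subset is depleted at step 1.
PAPER_LIKE_EFFECTS: EffectConfig = {
    ("membrane", 1): EffectSpec(mean=0.62, sd=0.15, fraction=0.55),
    ("lumen", 1): EffectSpec(mean=0.40, sd=0.10, fraction=0.60),
    ("lumen", 4): EffectSpec(mean=0.275, sd=0.10, fraction=0.40),
    ("associated", 1): EffectSpec(mean=0.30, sd=0.10, fraction=0.40),
    ("curvature", 1): EffectSpec(mean=0.45, sd=0.10, fraction=0.40),
    ("receptor", 1): EffectSpec(mean=0.40, sd=0.10, fraction=0.50),
}

#: Named sentinel proteins planted on top of the class-level preset.
#: FAM134A-like: deleted in the DKO, so step 1 is strongly negative and the
#: remaining steps are 0.  REEP-like curvature proteins are depleted rather
#: than stabilized once FAM134A/C are lost.
SENTINEL_STEP_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "FAM134A": (-2.5, 0.0, 0.0, 0.0),
    "REEP1L": (-1.5, -0.3, 0.0, 0.0),
    "REEP3L": (-1.3, 0.0, 0.0, 0.0),
    "REEP4L": (-1.2, 0.0, 0.0, 0.0),
}


@dataclass
class PaperLikeDataset:
    """Bundle returned by :func:`paper_like_dataset`."""

    annotations: pd.DataFrame
    truth: pd.DataFrame
    design: pd.DataFrame
    psms: pd.DataFrame
    seed: int
    sentinels: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )


def paper_like_dataset(
    n_proteins: int = 1000,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    psm_config: PsmSimConfig | None = None,
) -> PaperLikeDataset:
    """Generate the default study-conditions dataset end to end.

    Annotations follow :data:`DEFAULT_PROPORTIONS`, effects follow
    :data:`PAPER_LIKE_EFFECTS`, and four named sentinel proteins (a
    FAM134A-like receptor deleted at step 1 and three REEP-like curvature
    proteins depleted at step 1) are planted with fixed step effects.  The
    design is the 18-plex-style layout: five allelic genotypes plus the
    ATG12 control at ``replicates`` channels each.
    """
    annotations = generate_annotations(n_proteins, DEFAULT_PROPORTIONS, seed=seed)
    truth = plant_effects(
        annotations, PAPER_LIKE_EFFECTS, noise_sd=noise_sd, seed=seed + 1
    )

    # Rename one receptor and three curvature proteins to the sentinels and
    # overwrite their step effects with the fixed planted values.
    sentinel_class = {"FAM134A": "receptor", "REEP1L": "curvature",
                      "REEP3L": "curvature", "REEP4L": "curvature"}
    used: list[int] = []
    for name, steps in SENTINEL_STEP_EFFECTS.items():
        members = annotations.index[
            (annotations["er_class"] == sentinel_class[name])
            & ~annotations.index.isin(used)
        ]
        if len(members) == 0:
            raise ConfigurationError(
                f"annotation table too small to host sentinel {name!r}"
            )
        i = members[0]
        used.append(i)
        annotations.loc[i, "protein_id"] = name
        truth.loc[i, "protein_id"] = name
        truth.loc[i, STEP_COLUMNS] = steps
        # sentinels are well-detected proteins: pin them at the typical
        # baseline so the SNR filter never removes them
        truth.loc[i, "baseline_log2"] = 16.0
    truth["atg12_effect"] = truth[STEP_COLUMNS].sum(axis=1)

    design = make_design(replicates=replicates)
    psms = simulate_psm_table(
        truth, design, config=psm_config, seed=seed + 2
    )
    return PaperLikeDataset(
        annotations=annotations,
        truth=truth,
        design=design,
        psms=psms,
        seed=seed,
        sentinels=dict(SENTINEL_STEP_EFFECTS),
    )


#: Keima flux study conditions for the WT differentiation time course.
#: Acidic fractions rise with differentiation day; the BafA floor defines
#: the zero-flux baseline.
PAPER_LIKE_FLOW: dict[tuple[str, str], FlowCondition] = {
    ("WT_day0", "none"): FlowCondition(acidic_fraction=0.05),
    ("WT_day0", "BafA"): FlowCondition(acidic_fraction=BAFA_FLOOR),
    ("WT_day4", "none"): FlowCondition(acidic_fraction=0.179),
    ("WT_day4", "BafA"): FlowCondition(acidic_fraction=BAFA_FLOOR),
    ("WT_day12", "none"): FlowCondition(acidic_fraction=0.307),
    ("WT_day12", "BafA"): FlowCondition(acidic_fraction=BAFA_FLOOR),
    ("ATG12_KO_day12", "none"): FlowCondition(acidic_fraction=0.05),
    ("ATG12_KO_day12", "BafA"): FlowCondition(acidic_fraction=BAFA_FLOOR),
}
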