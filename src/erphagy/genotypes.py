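"""Genotype labels for the ER-phagy receptor knockout allelic series.

The allelic series is a nested set of mutants in which each line adds one
more receptor deletion to the previous one:

    WT -> DKO (FAM134A/C) -> TKO (+FAM134B) -> QKO (+TEX264) -> PKO (+CCPG1)

Samples outside the series (single knockouts, ATG12-null autophagy-dead
controls) are quantified by the pairwise differential machinery but never
enter the allelic linear model.
"""

from __future__ import annotations

#: Ordered allelic series, WT first.
ALLELIC_SERIES: tuple[str, ...] = ("WT", "DKO", "TKO", "QKO", "PKO")

#: Receptor whose deletion is added at each step of the series (1-based).
STEP_RECEPTORS: dict[int, str] = {
    1: "FAM134A/C",
    2: "FAM134B",
    3: "TEX264",
    4: "CCPG1",
}

#: Human-readable step labels matching the coefficient order.
STEP_LABELS: tuple[str, ...] = ("WT->DKO", "DKO->TKO", "TKO->QKO", "QKO->PKO")

#: Cumulative 0/1 indicator pattern (x1..x4) for each allelic genotype.
#: A genotype gets x_k = 1 when it *contains* the knockouts of step k, so
#: deeper mutants switch on every indicator up to their own step.
GENOTYPE_INDICATORS: dict[str, tuple[int, int, int, int]] = {
    "WT": (0, 0, 0, 0),
    "DKO": (1, 0, 0, 0),
    "TKO": (1, 1, 0, 0),
    "QKO": (1, 1, 1, 0),
    "PKO": (1, 1, 1, 1),
}

#: Single-receptor knockout genotype labels.
SINGLE_KOS: tuple[str, ...] = (
    "FAM134A_KO",
    "FAM134B_KO",
    "FAM134C_KO",
    "TEX264_KO",
    "CCPG1_KO",
)

#: Autophagy-conjugation-dead control.
ATG12_KO: str = "ATG12_KO"

#: Treatments understood by the generators and the flux module.
TREATMENTS: tuple[str, ...] = ("none", "BafA", "VPS34i", "Torin1")
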