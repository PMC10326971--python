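"""End-to-end orchestration: simulate/load -> process -> fit -> summarize.

A :class:`RunConfig` drives one deterministic run; every stage writes its
table under the output directory and the run manifest records the config
hash, seeds, and per-stage row counts, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import aggregate, allelic, differential, io, keima, psm, synthetic
from .errors import ConfigurationError


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    When ``psm_path`` / ``design_path`` / ``annotation_path`` are unset the
    synthetic paper-like preset is generated with ``n_proteins`` proteins
    and ``replicates`` channels per genotype.
    """

    out_dir: str = "erphagy_run"
    seed: int = 0
    # inputs (None -> generate synthetically)
    psm_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    # generator settings
    n_proteins: int = 1000
    replicates: int = 3
    noise_sd: float = 0.2
    # processing thresholds
    snr_min: float = psm.SNR_MIN
    purity_min: float = psm.PURITY_MIN
    filter_first: bool = True
    # model settings
    reference_genotype: str = "WT"
    fit_intercept: bool = True
    alpha: float = differential.ALPHA_DEFAULT
    # flux
    run_flux: bool = True
    flow_events: int = 10000

    def validate(self) -> None:
        if self.snr_min < 0 or not (0 <= self.purity_min <= 1):
            raise ConfigurationError("thresholds outside their domain")
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_proteins <= 0 or self.replicates < 2:
            raise ConfigurationError(
                "need n_proteins > 0 and >=2 replicates per genotype"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and return the manifest dict.

    Stages: generate (or load) tables -> PSM filter + sum normalization +
    roll-up -> WT-centered log2 -> allelic fit + per-coefficient BH ->
    category summaries and significant counts -> (optionally) Keima flux on
    the synthetic differentiation series.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- inputs -----------------------------------------------------------
    if config.psm_path is None:
        ds = synthetic.paper_like_dataset(
            n_proteins=config.n_proteins,
            replicates=config.replicates,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        psms, design, annotations = ds.psms, ds.design, ds.annotations
        io.write_table(ds.truth, out / "truth.tsv")
        io.write_table(psms, out / "psms.tsv")
        io.write_table(design, out / "design.tsv")
        io.write_table(annotations, out / "annotations.tsv")
        manifest["stages"]["simulate"] = {
            "n_proteins": len(annotations),
            "n_psms": len(psms),
            "n_channels": len(design),
        }
    else:
        if config.design_path is None or config.annotation_path is None:
            raise ConfigurationError(
                "psm_path requires design_path and annotation_path"
            )
        psms = io.read_psm_table(config.psm_path)
        design = io.read_design(config.design_path)
        annotations = io.read_annotations(config.annotation_path)
        manifest["stages"]["load"] = {
            "n_proteins": annotations["protein_id"].nunique(),
            "n_psms": len(psms),
            "n_channels": len(design),
        }

    # --- PSM processing ---------------------------------------------------
    quant, proc_info = psm.process_psms(
        psms,
        snr_min=config.snr_min,
        purity_min=config.purity_min,
        filter_first=config.filter_first,
    )
    io.write_table(quant.matrix.reset_index(), out / "protein_quant.tsv")
    io.write_json(proc_info, out / "processing_report.json")
    manifest["stages"]["process"] = {
        "n_psms_in": proc_info["filter"]["n_input"],
        "n_psms_removed": proc_info["filter"]["n_removed"],
        "n_psms_surviving": proc_info["filter"]["n_surviving"],
        "n_proteins_quantified": len(quant.matrix),
    }

    # --- normalization to reference + allelic fit -------------------------
    norm = differential.log2_relative_to_reference(
        quant.matrix, design, reference_genotype=config.reference_genotype
    )
    adesign = allelic.build_design(design)
    fits = allelic.fit_allelic_model(norm, adesign, fit_intercept=config.fit_intercept)
    fits = allelic.adjust_coefficients(fits)
    io.write_table(fits.reset_index(names="protein_id"), out / "allelic_fits.tsv")
    manifest["stages"]["fit"] = {
        "n_proteins_fit": len(fits),
        "n_proteins_dropped_nonpositive": len(norm.dropped),
        "n_channels_excluded": len(adesign.excluded),
        "residual_df": int(fits["df"].iloc[0]) if len(fits) else None,
    }

    # --- category summaries ----------------------------------------------
    summary_tables = {}
    for step in (1, 2, 3, 4):
        summaries = aggregate.summarize_by_category(
            fits[f"beta{step}"], annotations, grouping="er_class"
        )
        summary_tables[step] = aggregate.summaries_to_frame(summaries)
        io.write_table(summary_tables[step], out / f"category_beta{step}.tsv")
    sig_counts = {
        f"step{step}": aggregate.count_significant(fits, step, alpha=config.alpha)
        for step in (1, 2, 3, 4)
    }
    io.write_json(
        {k: {"n_up": v[0], "n_down": v[1]} for k, v in sig_counts.items()},
        out / "significant_counts.json",
    )
    manifest["stages"]["summarize"] = {
        "alpha": config.alpha,
        "significant": {k: list(v) for k, v in sig_counts.items()},
    }

    # --- Keima flux -------------------------------------------------------
    if config.run_flux:
        flows = synthetic.simulate_flow_events(
            synthetic.PAPER_LIKE_FLOW,
            n_events=config.flow_events,
            seed=config.seed + 100,
        )
        bafa_of = {
            sid: sid.rsplit("_", 1)[0] + "_BafA"
            for sid in flows
            if not sid.endswith("_BafA")
        }
        flux = keima.flux_table(flows, bafa_of)
        io.write_table(flux, out / "keima_flux.tsv")
        manifest["stages"]["flux"] = {
            "n_samples": len(flux),
            "n_events_per_sample": config.flow_events,
        }

    io.write_json(manifest, out / "manifest.json")
    return manifest
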