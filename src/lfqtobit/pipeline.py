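"""Configuration-driven orchestration of the full pipeline.

Stages: synthetic data (or external tables) -> optional peptide-level
quantification -> log10 + quantile normalization per fraction ->
censored Tobit fits with convergence screening -> BH adjustment,
significance calls and report tables.  Every intermediate table is
written to the output directory together with a run manifest recording
the seed and all parameters, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import AbundanceMatrix, NormalizedMatrix
from .io import (
    read_abundance,
    read_annotations,
    read_design,
    write_abundance,
    write_design,
    write_normalized,
    write_table,
)
from .normalize import log10_transform, quantile_normalize
from .quant import assemble_abundance
from .report import (
    add_q_values,
    call_significant,
    classify_fraction_effects,
    export_report,
    filter_supernatant,
    significant_proteins,
)
from .simulate import simulate_abundance, simulate_design, simulate_peptides
from .tobit import fit_all_proteins

logger = logging.getLogger("lfqtobit")


class PipelineError(RuntimeError):
    """A stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    design: pd.DataFrame
    abundance: AbundanceMatrix
    normalized: NormalizedMatrix
    effects: pd.DataFrame
    discards: pd.DataFrame
    counts: dict
    report: pd.DataFrame
    outdir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage of the pipeline described by ``config``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs ---------------------------------------------------
    try:
        sim = config.sim
        if sim.seed != config.seed:
            sim = type(sim)(**{**sim.__dict__, "seed": config.seed})
        if config.design_path is not None:
            if not Path(config.design_path).exists():
                raise FileNotFoundError(f"missing design file: {config.design_path}")
            design = read_design(config.design_path)
        else:
            design = simulate_design(sim)
        truth = None
        if config.abundance_path is not None:
            if not Path(config.abundance_path).exists():
                raise FileNotFoundError(f"missing abundance file: {config.abundance_path}")
            abundance = read_abundance(config.abundance_path, design)
        else:
            abundance, truth_obj = simulate_abundance(design, sim)
            truth = truth_obj.table
        if config.peptide_level:
            logger.info("simulating peptide features and re-quantifying")
            features, _ = simulate_peptides(abundance, sim)
            abundance = assemble_abundance(features, design)
            write_table(features, outdir / "peptides.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise PipelineError("inputs", str(exc)) from exc

    write_design(design, outdir / "design.tsv")
    write_abundance(abundance, outdir / "abundance.tsv")
    if truth is not None:
        write_table(truth, outdir / "ground_truth.tsv")

    # ---- stage: preprocess ----------------------------------------------
    try:
        normalized = quantile_normalize(log10_transform(abundance))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc
    write_normalized(normalized, outdir / "normalized.tsv")

    # ---- stage: censored model ------------------------------------------
    fractions = list(pd.unique(design["fraction"]))
    all_fits, all_discards = [], []
    try:
        for fraction in fractions:
            logger.info("fitting fraction %s", fraction)
            fits, discards = fit_all_proteins(
                normalized,
                design,
                fraction,
                mcmc=config.mcmc,
                hw=config.hw,
                master_seed=config.seed,
            )
            all_fits.append(fits)
            all_discards.append(discards)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("censored_model", str(exc)) from exc
    fits = pd.concat(all_fits, ignore_index=True)
    discards = pd.concat(all_discards, ignore_index=True)
    write_table(discards, outdir / "discard_log.tsv")

    # ---- stage: inference ------------------------------------------------
    try:
        families = ("alpha", "beta", "gamma") if config.include_time_effects else ("alpha", "gamma")
        effects = call_significant(add_q_values(fits, families), config.q_threshold)
        pellet_sig = significant_proteins(effects, fractions[0]) if fractions else set()
        sup_sig = (
            significant_proteins(effects, fractions[1]) if len(fractions) > 1 else set()
        )
        if config.annotation_path is not None and len(fractions) > 1:
            annotations = read_annotations(config.annotation_path)
            retained, lysis = filter_supernatant(sup_sig, annotations)
            sup_sig = retained
            write_table(
                pd.DataFrame(sorted(lysis), columns=["protein_id"]),
                outdir / "lysis_flagged.tsv",
            )
        else:
            annotations = None
        counts = classify_fraction_effects(pellet_sig, sup_sig)
        report = export_report(effects, annotations)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inference_report", str(exc)) from exc

    write_table(effects, outdir / "effects.tsv")
    write_table(report, outdir / "report.tsv")
    with open(outdir / "classification.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)

    manifest = {
        "lfqtobit_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        design=design,
        abundance=abundance,
        normalized=normalized,
        effects=effects,
        discards=discards,
        counts=counts,
        report=report,
        outdir=outdir,
    )
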