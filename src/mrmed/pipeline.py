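"""End-to-end orchestration: data in, harmonization, estimators, report.

A :class:`RunConfig` describes one analysis: either a simulation scenario or
paths to summary-statistics files, the trait roles (one exposure, optional
mediators, one outcome), per-trait SD constants for per-SD scaling, and the
analysis switches.  :func:`run` executes the whole pipeline
deterministically for a given seed and writes tab-delimited result tables,
a run manifest and an audit log of every drop/flip count to the output
directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ValidationError
from .mvmr_mediation import mediation_pipeline, mediation_table
from .power_bias import PowerSpec, instrument_diagnostics, minimum_detectable_or
from .simulate import MediatorSpec, SimulationScenario, SyntheticStudy, \
    simulate_summary_stats
from .summary_stats import (DEFAULT_R2, GENOME_WIDE_P, LDInfo,
                            VariantAssociation, clump, harmonize,
                            read_ld_matrix, read_summary_stats,
                            rescale_to_sd, select_instruments,
                            write_summary_stats)
from .uni_mr import all_estimators

log = logging.getLogger("mrmed")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Provide either ``scenario`` (synthetic data) or per-trait input paths.
    ``sd_constants`` maps trait name to its phenotypic SD for per-SD
    scaling of natural-unit associations (omit for traits already per-SD).
    """

    out_dir: str = "mrmed_run"
    seed: int = 0
    scenario: SimulationScenario | None = None
    exposure_path: str | None = None
    mediator_paths: Mapping[str, str] = field(default_factory=dict)
    outcome_path: str | None = None
    ld_path: str | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    sd_constants: Mapping[str, float] = field(default_factory=dict)
    drop_palindromic: bool = True
    re_model: str = "multiplicative"
    n_boot: int = 1000
    conmix_psi: float | str = "auto"
    p_threshold: float = GENOME_WIDE_P
    r2_threshold: float = DEFAULT_R2

    def __post_init__(self) -> None:
        roles = [self.exposure_name, *self.mediator_paths, self.outcome_name]
        if self.scenario is not None:
            roles = [self.exposure_name,
                     *(m.name for m in self.scenario.mediators),
                     self.outcome_name]
        if len(set(roles)) != len(roles):
            raise ConfigurationError(
                f"trait roles must be distinct, got {roles}")
        if self.scenario is None and (self.exposure_path is None
                                      or self.outcome_path is None):
            raise ConfigurationError(
                "either a simulation scenario or exposure/outcome input "
                "paths are required")
        if not (0 < self.p_threshold <= 1) or not (0 < self.r2_threshold <= 1):
            raise ConfigurationError("thresholds must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            sc = dict(raw["scenario"])
            meds = [MediatorSpec(**m) for m in sc.pop("mediators", [])]
            if "gamma" in sc and sc["gamma"] is not None:
                sc["gamma"] = tuple(sc["gamma"])
            raw["scenario"] = SimulationScenario(mediators=tuple(meds), **sc)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["mediator_paths"] = dict(self.mediator_paths)
        d["sd_constants"] = dict(self.sd_constants)
        return d


def _load_inputs(config: RunConfig, out: Path
                 ) -> tuple[dict[str, list[VariantAssociation]],
                            list[VariantAssociation], LDInfo, dict | None]:
    """Returns (exposure traits incl. mediators, outcome, LD, truth)."""
    if config.scenario is not None:
        sc = dataclasses.replace(config.scenario, seed=config.seed)
        study: SyntheticStudy = simulate_summary_stats(sc)
        traits = {config.exposure_name: study.exposures["exposure"]}
        for name, assocs in study.exposures.items():
            if name != "exposure":
                traits[name] = assocs
        for name, assocs in traits.items():
            write_summary_stats(assocs, out / f"input_{name}.tsv")
        write_summary_stats(study.outcome, out / "input_outcome.tsv")
        (out / "truth.json").write_text(
            json.dumps(study.truth, indent=2, sort_keys=True) + "\n")
        return traits, study.outcome, study.ld, study.truth

    traits = {config.exposure_name: read_summary_stats(config.exposure_path)}
    for name, path in config.mediator_paths.items():
        traits[name] = read_summary_stats(path)
    outcome = read_summary_stats(config.outcome_path)
    all_ids = sorted({a.variant_id for assocs in traits.values()
                      for a in assocs})
    if config.ld_path is not None:
        ld = read_ld_matrix(config.ld_path)
    else:
        log.info("no LD matrix supplied; assuming independent variants")
        ld = LDInfo.identity(all_ids)
    return traits, outcome, ld, None


def run(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline and write artifacts to ``config.out_dir``.

    Produces per-trait harmonized sets, the four-estimator univariable MR
    table, the MVMR mediation table (when mediators are configured),
    instrument diagnostics with minimum detectable ORs, and a manifest
    sufficient to reproduce every table bit for bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        traits, outcome, ld, truth = _load_inputs(config, out)
        case_fraction = (config.scenario.case_fraction
                         if config.scenario is not None else 0.5)
        n_outcome = (config.scenario.n_outcome
                     if config.scenario is not None else
                     max((a.n or 0) for a in outcome) or None)

        est_rows = []
        diag_rows = []
        for name, assocs in traits.items():
            sel = select_instruments(assocs, config.p_threshold)
            if not sel:
                log.warning("%s: no genome-wide-significant instruments", name)
                continue
            sel = clump(sel, ld, config.r2_threshold)
            log.info("%s: %d instruments after selection and clumping",
                     name, len(sel))
            ids = {a.variant_id for a in sel}
            hset = harmonize({name: sel},
                             [a for a in outcome if a.variant_id in ids],
                             drop_palindromic=config.drop_palindromic,
                             outcome_name=config.outcome_name)
            sd = config.sd_constants.get(name)
            if sd is not None:
                hset = rescale_to_sd(hset, [sd])
            hset.write_tsv(out / f"harmonized_{name}.tsv")

            for est in all_estimators(hset, n_boot=config.n_boot,
                                      seed=config.seed, psi=config.conmix_psi,
                                      re_model=config.re_model):
                lo, hi = est.or_ci
                est_rows.append({
                    "exposure": name, "method": est.method,
                    "n_snps": est.n_variants, "beta": est.beta,
                    "se": est.se, "or": est.or_, "or_lci": lo, "or_uci": hi,
                    "q": est.q_statistic,
                    "egger_intercept": est.egger_intercept,
                    "egger_intercept_p": est.egger_intercept_p,
                    "ci_status": est.ci_status,
                })

            n_exp = max((a.n or 0) for a in hset.to_assoc_lists()[0][name]) or None
            diag = instrument_diagnostics(hset, n=max(
                (a.n or 0) for a in sel) or None).iloc[0].to_dict()
            if n_outcome and diag["r2_sum"] == diag["r2_sum"]:  # not NaN
                diag["min_detectable_or"] = minimum_detectable_or(PowerSpec(
                    n=n_outcome, case_fraction=case_fraction,
                    r2=diag["r2_sum"]))
            diag_rows.append(diag)

        estimates = pd.DataFrame(est_rows)
        estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        diagnostics = pd.DataFrame(diag_rows)
        diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)

        tables = {"estimates": estimates, "diagnostics": diagnostics}

        mediator_names = [n for n in traits if n != config.exposure_name]
        if mediator_names:
            results = mediation_pipeline(
                traits[config.exposure_name],
                {n: traits[n] for n in mediator_names},
                outcome, ld, exposure_name=config.exposure_name,
                p_threshold=config.p_threshold,
                r2_threshold=config.r2_threshold,
                drop_palindromic=config.drop_palindromic)
            med = mediation_table(results)
            med.to_csv(out / "mediation.tsv", sep="\t", index=False)
            tables["mediation"] = med

        cfg_json = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
        manifest = {
            "package": "mrmed",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_jsonable(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        return tables
    finally:
        log.removeHandler(handler)
        handler.close()


def sensitivity_suite(config: RunConfig) -> pd.DataFrame:
    """Re-run the pipeline with and without palindromic variants.

    Writes both arms under the run directory and a side-by-side estimates
    table ``sensitivity.tsv`` (column ``arm`` distinguishes them).
    """
    out = Path(config.out_dir)
    arms = {}
    for arm, drop in (("main_no_palindromes", True),
                      ("sensitivity_with_palindromes", False)):
        sub = dataclasses.replace(config, out_dir=str(out / arm),
                                  drop_palindromic=drop)
        arms[arm] = run(sub)["estimates"].assign(arm=arm)
    combined = pd.concat(arms.values(), ignore_index=True)
    out.mkdir(parents=True, exist_ok=True)
    combined.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    return combined
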