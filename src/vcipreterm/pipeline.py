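"""End-to-end orchestration: cohort -> curves -> scores -> models ->
evaluation -> stratification -> survival -> decision curves.

Every artifact is written with a metadata block (config hash, seed, package
version) so a bundle is reproducible from its own outputs. A single global
seed fans out to per-stage seeds by fixed offsets, keeping each stage
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import decision_curve, growth_reference, model_build, model_eval
from . import risk_strata, synthetic_cohort, time_to_event

logger = logging.getLogger("vcipreterm")

# fixed per-stage seed offsets fanned out from the global seed
_STAGE_OFFSETS = {"simulate": 0, "late": 7, "model": 101, "bootstrap": 211}


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    out_dir: str = "vcipreterm_out"
    models: tuple[int, ...] = (1, 2, 3, 4)
    tier_low: float = 0.1
    tier_high: float = 0.3
    dca_thresholds: tuple[float, ...] = decision_curve.DEFAULT_THRESHOLDS
    bootstrap_B: int = 1000
    seed: int = 0
    strict_domain: bool = False
    sim_config: synthetic_cohort.SimConfig | None = None

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "sim_config"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _metadata(config: PipelineConfig) -> dict:
    from . import __version__

    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    payload = {"metadata": _metadata(config), **payload}
    path.write_text(json.dumps(payload, indent=2, default=float))


def _write_csv(path: Path, frame: pd.DataFrame, config: PipelineConfig) -> None:
    meta = _metadata(config)
    header = f"# config_hash={meta['config_hash']} seed={meta['seed']} version={meta['version']}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report bundle (also written to disk).

    Models are fitted on the VCI arm; reference curves come from controls.
    Models 2 and 3 are skipped with a stage error unless late-visit columns
    are present.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    stage = "simulate/load"
    try:
        if config.cohort_path is not None:
            cohort = synthetic_cohort.read_cohort(config.cohort_path)
        else:
            sim = config.sim_config or dataclasses.replace(
                synthetic_cohort.SimConfig(),
                seed=config.seed + _STAGE_OFFSETS["simulate"],
            )
            cohort = synthetic_cohort.generate_cohort(sim)
            cohort = synthetic_cohort.attach_late_visit(cohort, sim)
            _write_csv(out_dir / "cohort.csv", cohort, config)
        logger.info("cohort: n=%d (%s)", len(cohort),
                    cohort.group.value_counts().to_dict())

        stage = "reference curves"
        controls = cohort[cohort["group"] == "control"]
        curves = growth_reference.fit_reference_curves(controls)
        growth_reference.curves_to_json(
            curves, out_dir / "curves.json", metadata=_metadata(config)
        )

        stage = "deviation scores"
        scored = growth_reference.score_cohort(
            cohort, curves, strict=config.strict_domain
        )
        vci = scored[scored["group"] == "vci"].reset_index(drop=True)

        stage = "models"
        reports: dict[int, model_eval.EvaluationReport] = {}
        fitted: dict[int, model_build.FittedModel] = {}
        for mid in config.models:
            fitted[mid] = model_build.build_model(
                mid, vci, seed=config.seed + _STAGE_OFFSETS["model"]
            )
            reports[mid] = model_eval.evaluate_model(
                vci,
                mid,
                B=config.bootstrap_B,
                seed=config.seed + _STAGE_OFFSETS["bootstrap"],
            )
            _write_json(
                out_dir / f"model{mid}.json",
                {"model": fitted[mid].to_dict(),
                 "evaluation": reports[mid].to_dict()},
                config,
            )
            logger.info(
                "model %d: AUC=%.3f bootstrap=%.3f", mid,
                reports[mid].auc, reports[mid].bootstrap_auc_mean,
            )

        stage = "stratification"
        strat = None
        vci_mask = scored["group"] == "vci"
        for mid in fitted:
            scored.loc[vci_mask, f"model{mid}_prob"] = fitted[mid].predicted
        if 4 in fitted:
            strat = risk_strata.stratification_report(
                fitted[4].predicted,
                vci["preterm"],
                controls["preterm"],
                low=config.tier_low,
                high=config.tier_high,
            )
            scored.loc[vci_mask, "risk_tier"] = risk_strata.assign_tier(
                fitted[4].predicted, low=config.tier_low, high=config.tier_high
            )
            _write_json(out_dir / "stratification.json", strat.to_dict(), config)
        _write_csv(out_dir / "scores.csv", scored, config)

        stage = "survival"
        rec = time_to_event.events_from_cohort(cohort)
        inc_table = time_to_event.incidence_table(cohort)
        logrank_chi2, logrank_p = time_to_event.logrank_test(
            rec["time"], rec["code"], rec["group"]
        )
        hr, hr_ci, hr_p, hr_flag = time_to_event.cox_hr(
            rec["time"], rec["code"], (rec["group"] == "vci").astype(int)
        )
        gray_chi2, gray_p = time_to_event.gray_test(
            rec["time"], rec["code"], rec["group"]
        )
        _write_csv(out_dir / "incidence.csv", inc_table, config)
        survival_summary = {
            "logrank_chi2": logrank_chi2,
            "logrank_p": logrank_p,
            "cox_hr": hr,
            "cox_hr_ci": list(hr_ci),
            "cox_hr_p": hr_p,
            "cox_monotone_flag": hr_flag,
            "gray_chi2": gray_chi2,
            "gray_p": gray_p,
        }
        _write_json(out_dir / "survival.json", survival_summary, config)

        stage = "decision curve"
        dca = None
        if 4 in fitted:
            dca = decision_curve.dca_table(
                fitted[4].predicted, vci["preterm"], config.dca_thresholds
            )
            _write_csv(out_dir / "dca.csv", dca, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle.update(
        cohort=cohort,
        scored=scored,
        curves=curves,
        models=fitted,
        evaluations=reports,
        stratification=strat,
        incidence_table=inc_table,
        survival=survival_summary,
        dca=dca,
    )
    return bundle
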