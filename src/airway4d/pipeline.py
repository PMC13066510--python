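"""End-to-end pipeline driver: simulate -> partition -> active learning ->
morphometry -> comparison statistics -> regression.

Each stage writes its outputs plus a ``<stage>.done.json`` marker carrying
the configuration hash; a rerun with an unchanged configuration skips
completed stages, so the pipeline is idempotent and resumable from the last
valid stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as a4io
from .active_learning import CampaignData, CampaignState, run_campaign
from .backend import reference_backend
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .morphometry import cohort_metrics_table
from .partition import assign_roles, cohort_fingerprints, partition_cohort
from .regression import fit_all_outcomes
from .stats import comparison_tables

STAGES = ("simulate", "partition", "al_run", "morpho", "stats", "regress")


class PipelineError(RuntimeError):
    pass


def _marker(out: Path, stage: str) -> Path:
    return out / f"{stage}.done.json"


def _stage_done(out: Path, stage: str, chash: str) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == chash
    except json.JSONDecodeError:
        return False


def _mark(out: Path, stage: str, chash: str, **extra) -> None:
    _marker(out, stage).write_text(json.dumps(
        {"stage": stage, "config_hash": chash, **extra}, sort_keys=True))


def _image_ids(cohort: SyntheticCohort, pids) -> list[str]:
    cfg = cohort.config
    return [f"{pid}|{pos}|{k}" for pid in sorted(pids)
            for pos in cfg.positions for k in range(cfg.n_frames_per_position)]


def campaign_on_cohort(cohort: SyntheticCohort, plan, seed: int = 0,
                       n_generations: int = 4) -> CampaignState:
    """Run the reference-backend active-learning campaign on a cohort.

    Image ids are ``participant|position|frame``; volumes are rasterized on
    demand and memoized, so tiny cohorts stay cheap.
    """
    cache: dict[str, tuple] = {}

    def _frame(image_id: str):
        if image_id not in cache:
            pid, pos, k = image_id.split("|")
            cache[image_id] = cohort.frame(pid, pos, int(k))
        return cache[image_id]

    data = CampaignData(get_image=lambda iid: _frame(iid)[1],
                        get_label=lambda iid: _frame(iid)[0])
    waves = {g: _image_ids(cohort, plan.role_members(f"pool_wave{g}"))
             for g in (2, 3, 4)}
    backend = reference_backend(seed=seed)
    return run_campaign(
        waves=waves,
        initial_train=_image_ids(cohort, plan.role_members("initial_train")),
        validation=_image_ids(cohort, plan.role_members("fixed_validation")),
        holdout=_image_ids(cohort, plan.role_members("holdout_test")),
        backend=backend, data=data, n_generations=n_generations)


def run_pipeline(config: CohortConfig, out_dir: str | Path, seed: int | None = None,
                 n_initial_train: int = 14, n_fixed_validation: int = 4,
                 write_volumes: bool = True) -> dict:
    """Execute all stages; returns a dict of output paths.

    ``write_volumes=False`` skips the on-disk NIfTI tree (the downstream
    stages work from the in-memory cohort either way).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    chash = a4io.config_hash(config.to_dict())
    outputs: dict[str, str] = {}
    cohort = SyntheticCohort(config)

    stage = "simulate"
    try:
        if not _stage_done(out, stage, chash):
            if write_volumes:
                generate_cohort(config, out / "dataset")
                outputs["dataset"] = str(out / "dataset")
            cohort.demographics_frame().to_csv(out / "demographics.csv", index=False)
            _mark(out, stage, chash, n_images=config.n_frames_total)
        outputs["demographics"] = str(out / "demographics.csv")

        stage = "partition"
        plan_path = out / "plan.json"
        if not _stage_done(out, stage, chash):
            fps = cohort_fingerprints(cohort)
            plan = partition_cohort(fps, seed=config.seed)
            plan = assign_roles(plan, seed=config.seed,
                                n_initial_train=n_initial_train,
                                n_fixed_validation=n_fixed_validation)
            plan_path.write_text(json.dumps(
                {"group_of": plan.group_of, "roles": plan.roles,
                 "balance_p": plan.balance_p, "n_attempts": plan.n_attempts,
                 "image_counts": plan.image_counts(config.n_frames_per_position,
                                                   len(config.positions))},
                indent=1, sort_keys=True))
            _mark(out, stage, chash, balance_p=plan.balance_p)
        outputs["plan"] = str(plan_path)

        stage = "al_run"
        log_path = out / "campaign.jsonl"
        if not _stage_done(out, stage, chash):
            from .partition import PartitionPlan
            payload = json.loads(plan_path.read_text())
            plan = PartitionPlan(group_of={k: int(v) for k, v in payload["group_of"].items()},
                                 roles=payload["roles"],
                                 balance_p=payload["balance_p"])
            state = campaign_on_cohort(cohort, plan, seed=config.seed)
            with log_path.open("w") as fh:
                for entry in state.selection_log:
                    fh.write(json.dumps(entry.as_dict(), sort_keys=True) + "\n")
            _mark(out, stage, chash, generations=state.generation)
        outputs["campaign_log"] = str(log_path)

        stage = "morpho"
        metrics_path = out / "metrics.csv"
        if not _stage_done(out, stage, chash):
            cohort_metrics_table(cohort).to_csv(metrics_path, index=False)
            _mark(out, stage, chash)
        outputs["metrics"] = str(metrics_path)

        stage = "stats"
        tables_path = out / "comparisons.csv"
        if not _stage_done(out, stage, chash):
            metrics = pd.read_csv(metrics_path)
            comparison_tables(metrics, seed=config.seed).to_csv(tables_path, index=False)
            _mark(out, stage, chash)
        outputs["comparisons"] = str(tables_path)

        stage = "regress"
        coef_path = out / "regression_coefficients.csv"
        if not _stage_done(out, stage, chash):
            metrics = pd.read_csv(metrics_path)
            matrix, results = fit_all_outcomes(metrics, seed=config.seed)
            matrix.to_csv(coef_path)
            cards = {name: {"selected": list(r.selected),
                            "lambda": None if np.isnan(r.alpha) else r.alpha,
                            "coefficients": r.coefficients,
                            "cluster_robust_se": r.cluster_robust_se,
                            "p_values": r.p_values, "vif": r.vif,
                            "diagnostics": {k: v for k, v in r.diagnostics.items()
                                            if not isinstance(v, list)}}
                     for name, r in results.items()}
            (out / "model_cards.json").write_text(json.dumps(cards, indent=1,
                                                             sort_keys=True))
            _mark(out, stage, chash)
        outputs["regression"] = str(coef_path)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return outputs
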