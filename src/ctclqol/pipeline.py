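"""One-shot replication pipeline: simulate/load, calibrate, and report.

``run_pipeline`` executes the nine-stage evaluation sequence used to
develop the instrument — (1) measurement-model selection, (2) item fit and
purging, (3) unidimensionality, (4) rating-scale performance,
(5) reliability, (6) test information, (7) person-to-item map,
(8) convergent/discriminant validity, (9) differential item functioning —
writing one JSON artifact per stage plus a summary document.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, reliability, scoring, simulate
from .instrument import Instrument, ResponseMatrix, load_responses, published_instrument
from .rasch import ModelKind, fit, lrt_grsm_vs_rsm, icc_overlay

logger = logging.getLogger(__name__)

STAGES = [
    "model_comparison",
    "item_fit",
    "unidimensionality",
    "rating_scale",
    "reliability",
    "test_information",
    "person_item_map",
    "convergent_discriminant",
    "dif",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def _dump(obj, path: Path):
    path.write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))


def config_hash(config: dict) -> str:
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _default_config() -> dict:
    return {
        "seed": 0,
        "simulate": {"preset": "study", "n": None},
        "responses": None,
        "instrument": None,
        "model": "grsm",
        "purge_cutoff": diagnostics.MISFIT_CUTOFF,
        "dif_covariates": ["gender", "age", "race"],
        "plots": False,
    }


def _prepare_data(config: dict):
    """Return (instrument, responses, retest_responses or None)."""
    if config.get("responses"):
        inst = (
            Instrument.from_yaml(config["instrument"])
            if config.get("instrument")
            else published_instrument()
        )
        rm = load_responses(config["responses"], inst)
        return inst, rm, None
    sim = config.get("simulate") or {"preset": "study"}
    if sim.get("preset", "study") != "study":
        raise ValueError(f"unknown simulation preset: {sim['preset']}")
    study = simulate.simulate_study(seed=int(config.get("seed", 0)),
                                    n=sim.get("n"))
    return study["instrument"], study["responses"], study["retest_responses"]


def _dichotomize_age(age: pd.Series) -> pd.Series:
    med = age.median()
    return pd.Series(
        np.where(age <= med, "younger", "older"), index=age.index
    )


def run_pipeline(config: dict | None = None, out_dir: str | Path = "ctclqol_report") -> dict:
    """Run the nine evaluation stages; write one artifact per stage.

    Returns the summary dict.  A stage failure is recorded in the summary
    with a failure marker, the remaining stages are skipped if they depend
    on it, and the summary carries ``"ok": False``.
    """
    cfg = _default_config()
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    summary: dict = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "stages": {},
        "ok": True,
    }

    instrument, responses, retest = _prepare_data(cfg)

    def run_stage(name, fn):
        try:
            artifact = fn()
            _dump(artifact, out / f"{name}.json")
            summary["stages"][name] = {"status": "ok"}
            return artifact
        except Exception as exc:  # pragma: no cover - failure path
            logger.exception("stage %s failed", name)
            summary["stages"][name] = {"status": "failed", "error": str(exc)}
            summary["ok"] = False
            return None

    # (1) optimal measurement model
    state: dict = {}

    def stage_model():
        pcm = fit(responses, instrument, ModelKind.PCM)
        overlay = icc_overlay(pcm, instrument)
        rsm = fit(responses, instrument, ModelKind.RSM)
        grsm = fit(responses, instrument, ModelKind.GRSM)
        lrt = lrt_grsm_vs_rsm(grsm, rsm)
        state["grsm"] = grsm
        return {
            "icc_within_group_dissimilarity": overlay["within_group_dissimilarity"],
            "icc_between_group_dissimilarity": overlay["between_group_dissimilarity"],
            "loglik_rsm": rsm.loglik,
            "loglik_grsm": grsm.loglik,
            "lrt": lrt,
            "selected_model": "grsm" if lrt["p"] < 0.05 else "rsm",
        }

    def stage_item_fit():
        purge = diagnostics.purge_items(
            responses, instrument, cutoff=float(cfg["purge_cutoff"]),
            model_kind=cfg.get("model", "grsm"),
        )
        state["final_instrument"] = instrument.subset(purge["retained"])
        state["final_result"] = purge["final_result"]
        return {
            "retained": purge["retained"],
            "removed": purge["removed"],
            "log": purge["log"],
            "item_fit": purge["final_fit"].item.reset_index()
            .rename(columns={"index": "item"})
            .to_dict(orient="records"),
        }

    def stage_unidim():
        return diagnostics.dimensionality_report(
            state["final_result"], responses, state["final_instrument"]
        )

    def stage_rating_scale():
        res = state["final_result"]
        ordered = diagnostics.thresholds_ordered(res)
        grid = np.linspace(-5, 5, 41)
        curves = {
            g: diagnostics.category_curves(res, g, grid)["probs"]
            for g in res.params.tau
        }
        return {"thresholds": ordered, "grid": grid, "curves": curves}

    def stage_reliability():
        res = state["final_result"]
        p = res.params
        ok_p = np.isfinite(p.theta) & np.isfinite(p.theta_se)
        person_r = reliability.separation_reliability(
            p.theta[ok_p], p.theta_se[ok_p]
        )
        item_r = reliability.separation_reliability(p.delta, p.delta_se)
        art = {"person_reliability": person_r, "item_reliability": item_r}
        if retest is not None:
            from .instrument import ResponseMatrix as _RM, raw_totals

            inst_f = state["final_instrument"]
            rm1 = _RM(values=responses.values[inst_f.item_ids]
                      .loc[retest.values.index])
            rm2 = _RM(values=retest.values[inst_f.item_ids])
            tot1 = raw_totals(rm1, inst_f)
            tot2 = raw_totals(rm2, inst_f)
            both = tot1.notna() & tot2.notna()
            if both.sum() >= 3:
                art["test_retest"] = reliability.test_retest(
                    tot1[both], tot2[both]
                )
        return art

    def stage_info():
        res = state["final_result"]
        grid = np.linspace(-5, 5, 41)
        return diagnostics.test_information(res, grid)

    def stage_map():
        return diagnostics.map_to_dict(
            diagnostics.person_item_map(state["final_result"])
        )

    def stage_validity():
        cov = responses.covariates
        if cov is None or "comparator_qol" not in cov or "stage" not in cov:
            return {"skipped": "no comparator variables available"}
        from .instrument import ResponseMatrix as _RM, raw_totals

        inst_f = state["final_instrument"]
        totals = raw_totals(
            _RM(values=responses.values[inst_f.item_ids]), inst_f
        )
        ok = totals.notna() & cov["comparator_qol"].notna() & cov["stage"].notna()
        return reliability.convergent_discriminant(
            totals[ok], cov.loc[ok, "comparator_qol"], cov.loc[ok, "stage"]
        )

    def stage_dif():
        cov = responses.covariates
        if cov is None:
            return {"skipped": "no demographic covariates available"}
        res = state["final_result"]
        arts = {}
        for name in cfg["dif_covariates"]:
            if name not in cov:
                continue
            g = cov[name]
            if name == "age":
                g = _dichotomize_age(g)
            try:
                rep = diagnostics.dif(responses, res, g)
                arts[name] = {
                    "flagged_items": rep.flagged_items,
                    "table": rep.table.to_dict(orient="records"),
                }
            except Exception as exc:
                arts[name] = {"skipped": str(exc)}
        return arts

    stage_fns = {
        "model_comparison": stage_model,
        "item_fit": stage_item_fit,
        "unidimensionality": stage_unidim,
        "rating_scale": stage_rating_scale,
        "reliability": stage_reliability,
        "test_information": stage_info,
        "person_item_map": stage_map,
        "convergent_discriminant": stage_validity,
        "dif": stage_dif,
    }
    for name in STAGES:
        if not summary["ok"] and name in (
            "unidimensionality", "rating_scale", "reliability",
            "test_information", "person_item_map", "dif",
        ) and "final_result" not in state:
            summary["stages"][name] = {"status": "skipped"}
            continue
        run_stage(name, stage_fns[name])

    if cfg.get("plots"):
        try:
            from . import plots

            plots.render_all(state["final_result"], out)
            summary["plots"] = True
        except Exception as exc:  # pragma: no cover
            summary["plots"] = f"failed: {exc}"

    _dump(summary, out / "summary.json")
    return summary
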