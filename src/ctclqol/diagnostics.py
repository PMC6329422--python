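"""Item fit, purging, dimensionality, rating-scale and targeting diagnostics.

These are the quality checks applied after a Rasch calibration:

* infit/outfit mean-squares (information-weighted and unweighted averages
  of squared standardized residuals; ~1 under fit, > 1.33 conventionally
  flags misfit);
* iterative item purging at that cutoff;
* principal components analysis of the standardized residuals, whose first
  eigenvalue ("first contrast") screens for a second dimension;
* Andrich-threshold ordering and category response curves;
* the test information function and conditional SEM;
* the person-to-item (Wright) map with a targeting summary;
* anchored differential item functioning contrasts by demographic group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CtclQolError, InsufficientDataError, ParameterError
from .instrument import Instrument, ResponseMatrix
from .rasch import (
    CalibrationResult,
    ModelKind,
    _cumtau_per_item,
    _probs_grid,
    _KS,
    category_probs,
    fit,
    item_variance,
)

logger = logging.getLogger(__name__)

MISFIT_CUTOFF = 1.33  # conventional mean-square cutoff for item misfit


# ---------------------------------------------------------------------------
# Residuals and fit statistics
# ---------------------------------------------------------------------------

def standardized_residuals(
    result: CalibrationResult,
    responses: ResponseMatrix,
    instrument: Instrument | None = None,
) -> pd.DataFrame:
    """Standardized residuals z = (x - E)/sqrt(Var) for observed cells.

    Recomputed directly from the category probabilities at the estimates;
    cells that are missing (or "does not apply") are NaN.  Zero-variance
    cells are excluded with a warning.
    """
    if instrument is None:
        instrument = result.instrument
    p = result.params
    scored = responses.scored(instrument)[p.item_ids]
    scored = scored.loc[[pid for pid in p.person_ids if pid in scored.index]]
    x = scored.to_numpy(dtype=float)
    theta = result.theta.loc[scored.index].to_numpy()
    e, v = result.expected_and_variance(theta)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - e) / np.sqrt(v)
    degenerate = ~np.isnan(x) & (v < 1e-12)
    if degenerate.any():
        logger.warning(
            "%d zero-variance cells excluded from residuals",
            int(degenerate.sum()),
        )
        z[degenerate] = np.nan
    return pd.DataFrame(z, index=scored.index, columns=p.item_ids)


@dataclass
class FitReport:
    """Per-item and per-person infit/outfit mean-squares."""

    item: pd.DataFrame  # columns: infit, outfit
    person: pd.DataFrame


def item_fit(result: CalibrationResult, responses: ResponseMatrix,
             instrument: Instrument | None = None) -> FitReport:
    """Infit/outfit mean-squares.

    outfit_i = mean_n z_ni^2 ;  infit_i = sum_n Var_ni z_ni^2 / sum_n Var_ni
    (and analogously per person).  Extreme persons/items, having been
    excluded from calibration, do not contribute.
    """
    if instrument is None:
        instrument = result.instrument
    p = result.params
    scored = responses.scored(instrument)[p.item_ids]
    calibrated = [
        pid for pid in p.person_ids
        if pid not in set(result.excluded_extreme_persons)
    ]
    scored = scored.loc[calibrated]
    x = scored.to_numpy(dtype=float)
    theta = result.theta.loc[calibrated].to_numpy()
    e, v = result.expected_and_variance(theta)
    obs = ~np.isnan(x)
    z2 = np.where(obs, (x - e) ** 2 / np.maximum(v, 1e-12), 0.0)
    w = np.where(obs, v, 0.0)
    # infit weights are the variances themselves: sum v*z^2 / sum v = sum (x-e)^2 / sum v
    wz2 = np.where(obs, (x - e) ** 2, 0.0)
    item_infit = wz2.sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
    item_outfit = z2.sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    person_infit = wz2.sum(axis=1) / np.maximum(w.sum(axis=1), 1e-12)
    person_outfit = z2.sum(axis=1) / np.maximum(obs.sum(axis=1), 1)

    item_df = pd.DataFrame(
        {"infit": item_infit, "outfit": item_outfit}, index=p.item_ids
    )
    person_df = pd.DataFrame(
        {"infit": person_infit, "outfit": person_outfit}, index=calibrated
    )
    return FitReport(item=item_df, person=person_df)


def purge_items(
    responses: ResponseMatrix,
    instrument: Instrument,
    cutoff: float = MISFIT_CUTOFF,
    model_kind: ModelKind | str = ModelKind.GRSM,
) -> dict:
    """Iteratively remove misfitting items until all retained items fit.

    One item is removed per round: among items with infit or outfit above
    ``cutoff``, the one with the largest outfit (ties: largest infit, then
    lowest position in the instrument) goes first, and the remaining items
    are recalibrated.  Refuses to purge below 3 items.
    """
    active = list(instrument.item_ids)
    removal_log: list[dict] = []
    while True:
        if len(active) < 3:
            raise CtclQolError(
                "purge would leave fewer than 3 items; partial log: "
                f"{removal_log}"
            )
        inst = instrument.subset(active)
        result = fit(responses, inst, model_kind)
        report = item_fit(result, responses, inst)
        tab = report.item
        offenders = tab[(tab.infit > cutoff) | (tab.outfit > cutoff)]
        if offenders.empty:
            return {
                "retained": active,
                "removed": [e["item"] for e in removal_log],
                "log": removal_log,
                "final_result": result,
                "final_fit": report,
            }
        order = {iid: k for k, iid in enumerate(instrument.item_ids)}
        worst = offenders.assign(pos=[order[i] for i in offenders.index]) \
            .sort_values(["outfit", "infit", "pos"],
                         ascending=[False, False, True]) \
            .index[0]
        removal_log.append(
            {
                "round": len(removal_log) + 1,
                "item": worst,
                "infit": float(tab.loc[worst, "infit"]),
                "outfit": float(tab.loc[worst, "outfit"]),
            }
        )
        active = [i for i in active if i != worst]


# ---------------------------------------------------------------------------
# Dimensionality
# ---------------------------------------------------------------------------

def pca_first_contrast(
    residuals: pd.DataFrame,
    observed: pd.DataFrame | None = None,
    expected: pd.DataFrame | None = None,
) -> dict:
    """Unrotated PCA of standardized residuals; first-contrast screening.

    Missing residuals are imputed as 0 (no surprise) with a log note;
    residuals are person-centered before the item-by-item correlation
    matrix is formed, and eigenvalues are reported on the correlation
    scale, so they sum to the number of items.  If the observed scores and
    model expectations are supplied, the percentage of observation variance
    explained by the model's measures is also reported.
    """
    z = residuals.to_numpy(dtype=float)
    n, m = z.shape
    if n < m:
        logger.warning("fewer persons (%d) than items (%d): rank-deficient PCA",
                       n, m)
    n_missing = int(np.isnan(z).sum())
    if n_missing:
        logger.info("imputing %d missing residuals as 0 for PCA", n_missing)
        z = np.nan_to_num(z, nan=0.0)
    z = z - z.mean(axis=1, keepdims=True)  # person-center
    corr = np.corrcoef(z, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]

    out = {
        "eigenvalues": eigvals,
        "first_contrast_eigenvalue": float(eigvals[0]),
        "n_components_ge_2": int((eigvals >= 2.0).sum()),
        "variance_explained_by_measures_pct": None,
    }
    if observed is not None and expected is not None:
        x = observed.to_numpy(dtype=float)
        e = expected.to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(e)
        total = float(((x[ok] - x[ok].mean()) ** 2).sum())
        resid = float(((x[ok] - e[ok]) ** 2).sum())
        out["variance_explained_by_measures_pct"] = (
            100.0 * (total - resid) / total if total > 0 else 0.0
        )
    return out


def dimensionality_report(
    result: CalibrationResult,
    responses: ResponseMatrix,
    instrument: Instrument | None = None,
) -> dict:
    """Convenience wrapper: residual PCA plus variance explained by measures."""
    if instrument is None:
        instrument = result.instrument
    z = standardized_residuals(result, responses, instrument)
    calibrated = [
        pid for pid in result.params.person_ids
        if pid not in set(result.excluded_extreme_persons)
    ]
    z = z.loc[calibrated]
    scored = responses.scored(instrument)[result.params.item_ids].loc[calibrated]
    theta = result.theta.loc[calibrated].to_numpy()
    e, _ = result.expected_and_variance(theta)
    expected = pd.DataFrame(e, index=calibrated, columns=result.params.item_ids)
    return pca_first_contrast(z, observed=scored, expected=expected)


# ---------------------------------------------------------------------------
# Rating-scale performance
# ---------------------------------------------------------------------------

def thresholds_ordered(result: CalibrationResult) -> dict:
    """Per-group strict ordering check of the Andrich thresholds."""
    out = {}
    for g, tau in result.params.tau.items():
        out[g] = {
            "ordered": bool(np.all(np.diff(tau) > 0)),
            "tau": tau.copy(),
        }
    return out


def category_curves(
    result: CalibrationResult,
    group: str,
    grid: np.ndarray | None = None,
) -> dict:
    """Category response curves for one rating-scale group.

    Curves are plotted against theta - delta, so they characterize the
    group's shared thresholds independent of any one item.
    """
    if grid is None:
        grid = np.linspace(-5, 5, 201)
    tau = result.params.tau[group]
    probs = np.array([category_probs(t, 0.0, tau) for t in grid])
    return {"grid": grid, "probs": probs, "tau": tau.copy()}


def test_information(
    result: CalibrationResult, theta_grid: np.ndarray | None = None
) -> dict:
    """Test information I(theta) = sum_i Var_i(theta), and conditional SEM."""
    if theta_grid is None:
        theta_grid = np.linspace(-5, 5, 201)
    p = result.params
    cumtau = _cumtau_per_item(p)
    phi = np.asarray(theta_grid)[:, None] - p.delta[None, :]
    probs = _probs_grid(phi, cumtau)
    e = probs @ _KS
    v = probs @ _KS**2 - e**2
    info = v.sum(axis=1)
    with np.errstate(divide="ignore"):
        sem = 1.0 / np.sqrt(info)
    return {"theta_grid": np.asarray(theta_grid), "information": info,
            "sem": sem}


def person_item_map(result: CalibrationResult) -> dict:
    """Wright map data: person and item locations on the shared logit ruler.

    The targeting summary reports the offset between the two distributions
    and the share of persons lying outside the item range (coverage gaps at
    either end of the trait).
    """
    theta = result.theta.dropna().sort_values()
    delta = result.delta.sort_values()
    frac_below = float((theta < delta.min()).mean())
    frac_above = float((theta > delta.max()).mean())
    summary = {
        "mean_theta": float(theta.mean()),
        "sd_theta": float(theta.std(ddof=1)),
        "mean_delta": float(delta.mean()),
        "sd_delta": float(delta.std(ddof=1)),
        "targeting_offset": float(abs(theta.mean() - delta.mean())),
        "frac_persons_below_items": frac_below,
        "frac_persons_above_items": frac_above,
        "undercoverage_low": frac_below > 0.10,
        "undercoverage_high": frac_above > 0.10,
    }
    return {
        "persons": theta,
        "items": delta,
        "targeting": summary,
    }


def map_to_dict(m: dict) -> dict:
    return {
        "persons": {str(k): float(v) for k, v in m["persons"].items()},
        "items": {str(k): float(v) for k, v in m["items"].items()},
        "targeting": m["targeting"],
    }


def map_from_dict(d: dict) -> dict:
    return {
        "persons": pd.Series(d["persons"], name="theta"),
        "items": pd.Series(d["items"], name="delta"),
        "targeting": d["targeting"],
    }


# ---------------------------------------------------------------------------
# Differential item functioning
# ---------------------------------------------------------------------------

@dataclass
class DIFReport:
    """Anchored DIF contrasts; one row per item and group pair."""

    table: pd.DataFrame  # item, group_a, group_b, delta_a, delta_b,
    #                      contrast, se, t, df, p, flagged
    contrast_threshold: float
    alpha: float

    @property
    def flagged_items(self) -> list[str]:
        return sorted(self.table.loc[self.table.flagged, "item"].unique())


def _anchored_item_delta(x_col, theta, cumtau_row, d0, max_iter=100):
    """1-D Newton re-estimate of one item's difficulty with theta, tau fixed."""
    obs = ~np.isnan(x_col)
    if obs.sum() == 0 or np.nanstd(x_col) == 0:
        return np.nan, np.nan
    xs = x_col[obs]
    th = theta[obs]
    d = d0
    for _ in range(max_iter):
        phi = (th - d)[:, None]
        probs = _probs_grid(phi, cumtau_row[None, :])[:, 0, :]
        e = probs @ _KS
        v = probs @ _KS**2 - e**2
        step = np.clip((e.sum() - xs.sum()) / max(v.sum(), 1e-10), -1.0, 1.0)
        d += step
        if abs(step) < 1e-6:
            break
    phi = (th - d)[:, None]
    probs = _probs_grid(phi, cumtau_row[None, :])[:, 0, :]
    e = probs @ _KS
    v = probs @ _KS**2 - e**2
    se = 1.0 / np.sqrt(max(v.sum(), 1e-12))
    return d, se


def dif(
    responses: ResponseMatrix,
    result: CalibrationResult,
    grouping: pd.Series,
    *,
    contrast_threshold: float = 1.0,
    alpha: float = 0.05,
    min_group_size: int = 20,
) -> DIFReport:
    """Anchored separate-calibration DIF.

    Person measures and thresholds are held at the pooled estimates; each
    item's difficulty is re-estimated within each group.  The contrast
    (difference in logits) is tested with a two-sample t statistic using
    the joint standard error and Welch-type degrees of freedom; an item is
    flagged when |contrast| exceeds ``contrast_threshold`` logits AND the
    contrast is significant at ``alpha``.  For more than two groups, all
    pairwise contrasts are reported.
    """
    p = result.params
    scored_index = [
        pid for pid in p.person_ids
        if pid not in set(result.excluded_extreme_persons)
    ]
    grouping = grouping.loc[scored_index]
    labels = sorted(
        (
            lab for lab in pd.unique(grouping.dropna())
            if (grouping == lab).sum() >= min_group_size
        ),
        key=str,
    )
    if len(labels) < 2:
        raise InsufficientDataError(
            f"need at least 2 groups with >= {min_group_size} persons"
        )
    theta_all = result.theta.loc[scored_index].to_numpy()
    cumtau = _cumtau_per_item(p)

    rows = []
    scored = _score_like_result(responses, result).loc[scored_index]

    for item_pos, iid in enumerate(p.item_ids):
        per_group = {}
        for lab in labels:
            mask = (grouping == lab).to_numpy()
            xg = scored[iid].to_numpy()[mask]
            if np.all(np.isnan(xg)) or np.nanstd(xg) == 0:
                logger.info("item %s skipped for group %s: no variance", iid, lab)
                per_group[lab] = (np.nan, np.nan, int((~np.isnan(xg)).sum()))
                continue
            d, se = _anchored_item_delta(
                xg, theta_all[mask], cumtau[item_pos], float(p.delta[item_pos])
            )
            per_group[lab] = (d, se, int((~np.isnan(xg)).sum()))
        for a, b in combinations(labels, 2):
            da, sea, na = per_group[a]
            db, seb, nb = per_group[b]
            if np.isnan(da) or np.isnan(db):
                continue
            contrast = da - db
            se = np.sqrt(sea**2 + seb**2)
            t = contrast / se
            df = (sea**2 + seb**2) ** 2 / (
                sea**4 / max(na - 1, 1) + seb**4 / max(nb - 1, 1)
            )
            pval = 2 * stats.t.sf(abs(t), df)
            rows.append(
                {
                    "item": iid,
                    "group_a": a,
                    "group_b": b,
                    "delta_a": da,
                    "delta_b": db,
                    "contrast": contrast,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p": pval,
                    "flagged": bool(
                        abs(contrast) > contrast_threshold and pval < alpha
                    ),
                }
            )
    table = pd.DataFrame(rows)
    return DIFReport(
        table=table, contrast_threshold=contrast_threshold, alpha=alpha
    )


def _score_like_result(
    responses: ResponseMatrix, result: CalibrationResult
) -> pd.DataFrame:
    """Scored (0..4, NaN-missing) matrix aligned to the calibration's items."""
    if result.instrument is None:
        raise ParameterError("calibration result carries no instrument")
    return responses.scored(result.instrument)[result.params.item_ids]
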