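"""Polytomous Rasch models and joint maximum likelihood estimation.

Three nested model variants are supported, all with categories 0..K on the
analysis scale:

* RSM  — one shared set of Andrich thresholds for every item;
* G-RSM — thresholds shared within predefined item groups (here the
  frequency-worded vs intensity-worded items) but free between groups;
* PCM  — item-specific thresholds.

The category probability is

    P(X = k | theta, delta, tau) ∝ exp(k (theta - delta) - sum_{j<=k} tau_j)

with ``tau_0 = 0``.  Estimation is joint (unconditional) maximum
likelihood: alternating Newton updates of person measures theta, item
difficulties delta and thresholds tau, under the identification
constraints mean(delta) = 0 and sum(tau) = 0 within each group.  Persons
and items with extreme (all-minimum or all-maximum) observed scores carry
no information about their own location and are excluded from calibration;
they receive finite measures afterwards via an inward nudge of the extreme
raw score (0.3 score points by default, the convention of the Winsteps
software lineage).
"""

from __future__ import annotations

import enum
import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComparisonError, ParameterError
from .instrument import Instrument, ResponseMatrix

logger = logging.getLogger(__name__)

N_CATEGORIES = 5
K_MAX = N_CATEGORIES - 1
_KS = np.arange(N_CATEGORIES, dtype=float)

EXTREME_ADJUST = 0.3  # inward nudge for extreme raw scores, in score points

#: value at which thresholds of never-observed top categories are frozen;
#: makes those categories numerically unreachable without special-casing
TAU_FROZEN = 30.0


class ModelKind(str, enum.Enum):
    RSM = "rsm"
    GRSM = "grsm"
    PCM = "pcm"


# ---------------------------------------------------------------------------
# Category probabilities and moments
# ---------------------------------------------------------------------------

def category_probs(theta, delta, tau) -> np.ndarray:
    """Category probabilities of the (grouped) rating scale model.

    Parameters
    ----------
    theta, delta : float
        Person measure and item difficulty, in logits.
    tau : array-like, length K
        Andrich thresholds for the item's rating-scale group.

    Returns
    -------
    ndarray, length K+1
        Probabilities of categories 0..K; nonnegative, summing to 1.
    """
    theta = float(theta)
    delta = float(delta)
    tau = np.asarray(tau, dtype=float)
    if not (np.isfinite(theta) and np.isfinite(delta) and np.isfinite(tau).all()):
        raise ValueError("category_probs requires finite inputs")
    k = np.arange(tau.size + 1, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(tau)])
    logits = k * (theta - delta) - cum
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def expected_score(theta, delta, tau) -> float:
    """Expected category (0..K scale) for one item at ``theta``."""
    p = category_probs(theta, delta, tau)
    k = np.arange(p.size, dtype=float)
    return float(p @ k)


def item_variance(theta, delta, tau) -> float:
    """Conditional variance of the category score; also the item information."""
    p = category_probs(theta, delta, tau)
    k = np.arange(p.size, dtype=float)
    m = p @ k
    return float(p @ k**2 - m**2)


def _probs_grid(phi: np.ndarray, cumtau_items: np.ndarray) -> np.ndarray:
    """Vectorized probabilities: phi (n, m), cumtau_items (m, K+1) -> (n, m, K+1)."""
    logits = phi[:, :, None] * _KS[None, None, :] - cumtau_items[None, :, :]
    logits -= logits.max(axis=2, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=2, keepdims=True)
    return logits


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class GRSMParams:
    """Estimated parameters of a fitted polytomous Rasch model."""

    model_kind: ModelKind
    person_ids: list
    item_ids: list[str]
    theta: np.ndarray
    theta_se: np.ndarray
    delta: np.ndarray
    delta_se: np.ndarray
    #: thresholds per group name; for PCM the "groups" are the items
    tau: dict[str, np.ndarray]
    tau_se: dict[str, np.ndarray]
    #: group name of each item, aligned with item_ids
    item_group: list[str]

    def tau_of_item(self, item_id: str) -> np.ndarray:
        j = self.item_ids.index(item_id)
        return self.tau[self.item_group[j]]


@dataclass
class CalibrationResult:
    """Everything a calibration produces: estimates, fit record, residuals."""

    params: GRSMParams
    loglik: float
    n_iter: int
    converged: bool
    excluded_extreme_persons: list
    excluded_extreme_items: list[str]
    #: standardized residuals for calibrated persons x items (NaN = missing)
    residual_matrix: pd.DataFrame
    data_fingerprint: str
    tolerance: float
    #: the instrument the calibration was fit with (active items only)
    instrument: "Instrument | None" = None

    @property
    def theta(self) -> pd.Series:
        return pd.Series(
            self.params.theta, index=self.params.person_ids, name="theta"
        )

    @property
    def delta(self) -> pd.Series:
        return pd.Series(
            self.params.delta, index=self.params.item_ids, name="delta"
        )

    def expected_and_variance(
        self, theta: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Model expectations and variances for all (person, item) pairs."""
        p = self.params
        th = p.theta if theta is None else np.asarray(theta, dtype=float)
        cumtau = _cumtau_per_item(p)
        phi = th[:, None] - p.delta[None, :]
        probs = _probs_grid(phi, cumtau)
        e = probs @ _KS
        v = probs @ _KS**2 - e**2
        return e, v

    def to_dict(self) -> dict:
        p = self.params
        return {
            "model_kind": p.model_kind.value,
            "person_ids": [str(x) for x in p.person_ids],
            "item_ids": list(p.item_ids),
            "theta": p.theta.tolist(),
            "theta_se": p.theta_se.tolist(),
            "delta": p.delta.tolist(),
            "delta_se": p.delta_se.tolist(),
            "tau": {g: t.tolist() for g, t in p.tau.items()},
            "tau_se": {g: t.tolist() for g, t in p.tau_se.items()},
            "item_group": list(p.item_group),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "excluded_extreme_persons": [
                str(x) for x in self.excluded_extreme_persons
            ],
            "excluded_extreme_items": list(self.excluded_extreme_items),
            "data_fingerprint": self.data_fingerprint,
            "tolerance": self.tolerance,
        }


def _cumtau_per_item(p: GRSMParams) -> np.ndarray:
    """(m, K+1) cumulative thresholds aligned with p.item_ids."""
    rows = []
    for g in p.item_group:
        tau = p.tau[g]
        rows.append(np.concatenate([[0.0], np.cumsum(tau)]))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fingerprint(x: np.ndarray) -> str:
    arr = np.ascontiguousarray(np.nan_to_num(x, nan=-1.0))
    return hashlib.sha256(arr.tobytes() + str(arr.shape).encode()).hexdigest()


def _drop_extremes(x: np.ndarray, person_ids, item_ids):
    """Iteratively remove persons/items whose observed scores are extreme."""
    keep_p = np.ones(x.shape[0], dtype=bool)
    keep_i = np.ones(x.shape[1], dtype=bool)
    changed = True
    while changed:
        changed = False
        sub = x[np.ix_(keep_p, keep_i)]
        obs = ~np.isnan(sub)
        r = np.nansum(sub, axis=1)
        rmax = K_MAX * obs.sum(axis=1)
        extreme_p = (obs.sum(axis=1) == 0) | (r <= 0) | (r >= rmax)
        if extreme_p.any():
            idx = np.flatnonzero(keep_p)[extreme_p]
            keep_p[idx] = False
            changed = True
            continue
        s = np.nansum(sub, axis=0)
        smax = K_MAX * obs.sum(axis=0)
        extreme_i = (obs.sum(axis=0) == 0) | (s <= 0) | (s >= smax)
        if extreme_i.any():
            idx = np.flatnonzero(keep_i)[extreme_i]
            keep_i[idx] = False
            changed = True
    excluded_p = [person_ids[i] for i in np.flatnonzero(~keep_p)]
    excluded_i = [item_ids[j] for j in np.flatnonzero(~keep_i)]
    return keep_p, keep_i, excluded_p, excluded_i


def _collapse_unobserved(x: np.ndarray, group_of_item: np.ndarray) -> np.ndarray:
    """Collapse never-observed categories onto their lower neighbour, per group.

    Thresholds between categories that never occur in a group's data are
    inestimable; the affected categories are merged downward and a warning
    is logged.  Returns a possibly modified copy of ``x``.
    """
    x = x.copy()
    for g in np.unique(group_of_item):
        cols = group_of_item == g
        sub = x[:, cols]
        obs = sub[~np.isnan(sub)]
        present = np.isin(np.arange(N_CATEGORIES), np.unique(obs))
        if present.all():
            continue
        logger.warning(
            "group %s: categories %s unobserved; collapsing onto adjacent "
            "categories for calibration",
            g,
            np.flatnonzero(~present).tolist(),
        )
        # map each category to its rank among observed categories
        ranks = np.cumsum(present) - 1
        ranks = np.maximum(ranks, 0)
        mapped = sub.copy()
        ok = ~np.isnan(sub)
        mapped[ok] = ranks[sub[ok].astype(int)]
        x[:, cols] = mapped
    return x


def _loglik(x, obs, phi, cumtau_items) -> float:
    probs = _probs_grid(phi, cumtau_items)
    xi = np.where(obs, x, 0).astype(int)
    pk = np.take_along_axis(probs, xi[:, :, None], axis=2)[:, :, 0]
    return float(np.log(pk[obs]).sum())


def _solve_theta_for_score(target, delta, cumtau_items, lo=-12.0, hi=12.0):
    """theta with expected total score equal to ``target`` (bisection)."""

    def tcc(th):
        phi = np.full((1, len(delta)), th) - delta[None, :]
        probs = _probs_grid(phi, cumtau_items)
        return float((probs @ _KS).sum()) - target

    while tcc(lo) > 0:
        lo -= 6
        if lo < -60:
            break
    while tcc(hi) < 0:
        hi += 6
        if hi > 60:
            break
    return float(optimize.brentq(tcc, lo, hi, xtol=1e-10))


def fit(
    responses: ResponseMatrix,
    instrument: Instrument,
    model_kind: ModelKind | str = ModelKind.GRSM,
    *,
    tol: float = 1e-4,
    max_iter: int = 200,
    extreme_adjust: float = EXTREME_ADJUST,
) -> CalibrationResult:
    """Calibrate a polytomous Rasch model by joint maximum likelihood.

    Missing cells and "does not apply" responses are skipped (the
    likelihood runs over observed cells only).  Non-convergence within
    ``max_iter`` cycles is flagged, not raised.
    """
    model_kind = ModelKind(model_kind)
    scored = responses.scored(instrument)
    scored = scored[instrument.item_ids]
    x_full = scored.to_numpy(dtype=float)
    person_ids_full = list(scored.index)
    item_ids_full = list(scored.columns)

    obs_any = ~np.isnan(x_full)
    vals = x_full[obs_any]
    if np.unique(vals).size < 2:
        raise ParameterError("need at least 2 distinct observed categories")

    fingerprint = _fingerprint(x_full)

    keep_p, keep_i, excl_p, excl_i = _drop_extremes(
        x_full, person_ids_full, item_ids_full
    )
    x = x_full[np.ix_(keep_p, keep_i)]
    person_ids = [p for p, k in zip(person_ids_full, keep_p) if k]
    item_ids = [i for i, k in zip(item_ids_full, keep_i) if k]
    n, m = x.shape

    # grouping of items into threshold sets
    if model_kind is ModelKind.RSM:
        group_names = ["all"]
        item_group = ["all"] * m
    elif model_kind is ModelKind.GRSM:
        gmap = {it.id: it.scale_group.value for it in instrument.items}
        item_group = [gmap[i] for i in item_ids]
        group_names = [
            g for g in instrument.group_names if g in set(item_group)
        ]
        if len(group_names) < 1:
            raise ParameterError("grouped model requires defined scale groups")
    else:  # PCM: one threshold set per item
        item_group = list(item_ids)
        group_names = list(item_ids)
    gidx = np.array([group_names.index(g) for g in item_group])

    x = _collapse_unobserved(x, gidx)
    obs = ~np.isnan(x)

    # --- initial values ---------------------------------------------------
    r = np.nansum(x, axis=1)
    rmax = K_MAX * obs.sum(axis=1)
    pr = (r + 0.5) / (rmax + 1.0)
    theta = np.log(pr / (1 - pr))
    s = np.nansum(x, axis=0)
    smax = K_MAX * obs.sum(axis=0)
    ps = (s + 0.5) / (smax + 1.0)
    delta = -np.log(ps / (1 - ps))
    delta -= delta.mean()
    # after collapsing, each group observes categories 0..ka; thresholds
    # above ka are inestimable and frozen high (the categories are dead)
    n_groups_ = len(group_names)
    n_active = np.empty(n_groups_, dtype=int)
    for gi in range(n_groups_):
        n_active[gi] = int(np.nanmax(x[:, gidx == gi]))
    tau = np.zeros((n_groups_, K_MAX))
    for gi in range(n_groups_):
        tau[gi, n_active[gi]:] = TAU_FROZEN

    obs_f = obs.astype(float)
    n_groups = len(group_names)
    onehot = np.zeros((m, n_groups))
    onehot[np.arange(m), gidx] = 1.0
    # per-item observed counts of [x >= j], j = 1..K (constant across cycles)
    ge_sum = np.stack(
        [np.where(obs, (x >= j), False).sum(axis=0) for j in range(1, N_CATEGORIES)],
        axis=1,
    ).astype(float)  # (m, K)
    _jl_max = np.maximum.outer(np.arange(K_MAX), np.arange(K_MAX))

    def _tau_terms(probs):
        """Gradient (G, K) and Hessian-negative (G, K, K) for the thresholds."""
        pge = np.cumsum(probs[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:]
        pw = pge * obs_f[:, :, None]
        S = pw.sum(axis=0)  # (m, K): sum_n P(X>=j) over observed cells
        O = np.einsum("nij,nil->ijl", pw, pge)  # (m, K, K)
        C = S[:, _jl_max] - O  # per-item covariance blocks
        grad = onehot.T @ (S - ge_sum)
        cov = np.einsum("ijl,ig->gjl", C, onehot)
        return grad, cov

    def _probs_at(theta_, delta_, tau_):
        cumtau = np.concatenate(
            [np.zeros((m, 1)), np.cumsum(tau_[gidx], axis=1)], axis=1
        )
        return _probs_grid(theta_[:, None] - delta_[None, :], cumtau)

    converged = False
    n_iter = 0
    inner_tol = max(tol / 10.0, 1e-7)
    for n_iter in range(1, max_iter + 1):
        theta_old, delta_old, tau_old = theta.copy(), delta.copy(), tau.copy()

        # -- persons: Newton to convergence given current item parameters
        for _ in range(30):
            probs = _probs_at(theta, delta, tau)
            e = probs @ _KS
            v = probs @ _KS**2 - e**2
            step = np.clip(
                (r - (e * obs_f).sum(axis=1))
                / np.maximum((v * obs_f).sum(axis=1), 1e-10),
                -1.0,
                1.0,
            )
            theta += step
            if np.abs(step).max() < inner_tol:
                break

        # -- items and thresholds: joint Newton given person measures
        for _ in range(30):
            d_prev, t_prev = delta.copy(), tau.copy()
            probs = _probs_at(theta, delta, tau)
            e = probs @ _KS
            v = probs @ _KS**2 - e**2
            dstep = np.clip(
                ((e * obs_f).sum(axis=0) - s)
                / np.maximum((v * obs_f).sum(axis=0), 1e-10),
                -1.0,
                1.0,
            )
            delta += dstep
            # fresh probabilities for the threshold step (Gauss-Seidel);
            # updating tau from the pre-delta probabilities oscillates
            grad, cov = _tau_terms(_probs_at(theta, delta, tau))
            for gi in range(n_groups):
                ka = n_active[gi]
                if ka == 0:
                    continue
                try:
                    step = np.linalg.solve(
                        cov[gi][:ka, :ka] + 1e-8 * np.eye(ka), grad[gi][:ka]
                    )
                except np.linalg.LinAlgError:
                    step = grad[gi][:ka] / np.maximum(
                        np.diag(cov[gi])[:ka], 1e-8
                    )
                tau[gi, :ka] += np.clip(step, -1.0, 1.0)
            # project out the flat tau-mean vs group-delta direction so the
            # joint delta/tau Newton can actually converge
            for gi in range(n_groups):
                ka = n_active[gi]
                if ka == 0:
                    continue
                c = tau[gi, :ka].mean()
                tau[gi, :ka] -= c
                delta[gidx == gi] += c
            mx = max(
                np.abs(delta - d_prev).max(), np.abs(tau - t_prev).max()
            )
            if mx < inner_tol:
                break

        # -- identification: center delta (compensating theta)
        mdelta = delta.mean()
        delta -= mdelta
        theta -= mdelta

        change = max(
            np.abs(theta - theta_old).max(),
            np.abs(delta - delta_old).max(),
            np.abs(tau - tau_old).max() if tau.size else 0.0,
        )
        if change < tol:
            converged = True
            break

    cumtau_items = np.concatenate(
        [np.zeros((m, 1)), np.cumsum(tau[gidx], axis=1)], axis=1
    )
    phi = theta[:, None] - delta[None, :]
    probs = _probs_grid(phi, cumtau_items)
    e = probs @ _KS
    v = probs @ _KS**2 - e**2
    loglik = _loglik(x, obs, phi, cumtau_items)

    theta_se = 1.0 / np.sqrt(np.maximum((v * obs_f).sum(axis=1), 1e-12))
    delta_se = 1.0 / np.sqrt(np.maximum((v * obs_f).sum(axis=0), 1e-12))

    _, tau_cov = _tau_terms(probs)
    tau_se = {}
    for gi, g in enumerate(group_names):
        ka = n_active[gi]
        se = np.full(K_MAX, np.nan)
        if ka > 0:
            try:
                se[:ka] = np.sqrt(
                    np.diag(
                        np.linalg.inv(tau_cov[gi][:ka, :ka] + 1e-8 * np.eye(ka))
                    )
                )
            except np.linalg.LinAlgError:
                pass
        tau_se[g] = se

    # standardized residuals over calibrated cells
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - e) / np.sqrt(v)
    z[~obs] = np.nan
    degenerate = obs & (v < 1e-12)
    if degenerate.any():
        logger.warning(
            "%d zero-variance cells excluded from residuals", degenerate.sum()
        )
        z[degenerate] = np.nan
    residual_matrix = pd.DataFrame(z, index=person_ids, columns=item_ids)

    # --- measures for extreme persons/items (post-hoc, nudged scores) -----
    all_theta = pd.Series(index=person_ids_full, dtype=float)
    all_theta_se = pd.Series(index=person_ids_full, dtype=float)
    all_theta.loc[person_ids] = theta
    all_theta_se.loc[person_ids] = theta_se
    for pid in excl_p:
        row = x_full[person_ids_full.index(pid), keep_i]
        o = ~np.isnan(row)
        if o.sum() == 0:
            all_theta.loc[pid] = np.nan
            all_theta_se.loc[pid] = np.nan
            continue
        rmax_p = K_MAX * o.sum()
        raw = np.nansum(row)
        adj = (
            extreme_adjust
            if raw <= 0
            else rmax_p - extreme_adjust
            if raw >= rmax_p
            else raw
        )
        cum_p = cumtau_items[o]
        th = _solve_theta_for_score(adj, delta[o], cum_p)
        all_theta.loc[pid] = th
        phi_p = np.full((1, o.sum()), th) - delta[None, o]
        vv = (
            _probs_grid(phi_p, cum_p) @ _KS**2
            - (_probs_grid(phi_p, cum_p) @ _KS) ** 2
        )
        all_theta_se.loc[pid] = 1.0 / np.sqrt(max(vv.sum(), 1e-12))

    params = GRSMParams(
        model_kind=model_kind,
        person_ids=person_ids_full,
        item_ids=item_ids,
        theta=all_theta.to_numpy(),
        theta_se=all_theta_se.to_numpy(),
        delta=delta,
        delta_se=delta_se,
        tau={g: tau[gi].copy() for gi, g in enumerate(group_names)},
        tau_se=tau_se,
        item_group=item_group,
    )
    return CalibrationResult(
        params=params,
        loglik=loglik,
        n_iter=n_iter,
        converged=converged,
        excluded_extreme_persons=excl_p,
        excluded_extreme_items=excl_i,
        residual_matrix=residual_matrix,
        data_fingerprint=fingerprint,
        tolerance=tol,
        instrument=instrument,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def lrt_grsm_vs_rsm(
    grsm: CalibrationResult, rsm: CalibrationResult
) -> dict:
    """Global likelihood-ratio test of grouped vs common rating-scale thresholds.

    With G groups and K+1 categories the grouped model frees
    (G - 1) x (K - 1) thresholds beyond the common model under sum-to-zero
    identification.
    """
    if grsm.data_fingerprint != rsm.data_fingerprint:
        raise ComparisonError("calibrations were not fit to the same data")
    if grsm.params.model_kind is not ModelKind.GRSM:
        raise ComparisonError("first argument must be a grouped-model fit")
    if rsm.params.model_kind is not ModelKind.RSM:
        raise ComparisonError("second argument must be a common-model fit")
    n_groups = len(grsm.params.tau)
    df = (n_groups - 1) * (N_CATEGORIES - 2)
    chi2 = max(0.0, 2.0 * (grsm.loglik - rsm.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": chi2, "df": df, "p": p}


def icc_overlay(
    pcm_result: CalibrationResult,
    instrument: Instrument,
    theta_grid: np.ndarray | None = None,
) -> dict:
    """Expected-score curves per item on a theta grid, grouped by scale group.

    Returns the grid, per-item curves, and within/between-group
    dissimilarity (maximum pairwise sup-distance between curves).  Similar
    within-group curves support sharing thresholds across the group.
    """
    if theta_grid is None:
        theta_grid = np.linspace(-4, 4, 81)
    p = pcm_result.params
    gmap = {it.id: it.scale_group.value for it in instrument.items}
    curves: dict[str, np.ndarray] = {}
    for j, iid in enumerate(p.item_ids):
        tau = p.tau_of_item(iid)
        curves[iid] = np.array(
            [expected_score(t, p.delta[j], tau) for t in theta_grid]
        )
    groups: dict[str, list[str]] = {}
    for iid in p.item_ids:
        groups.setdefault(gmap[iid], []).append(iid)

    def supdist(a, b):
        return float(np.abs(curves[a] - curves[b]).max())

    within = {}
    for g, iids in groups.items():
        d = 0.0
        for a in range(len(iids)):
            for b in range(a + 1, len(iids)):
                d = max(d, supdist(iids[a], iids[b]))
        within[g] = d
    gnames = list(groups)
    between = 0.0
    for a in range(len(gnames)):
        for b in range(a + 1, len(gnames)):
            for ia in groups[gnames[a]]:
                for ib in groups[gnames[b]]:
                    between = max(between, supdist(ia, ib))
    return {
        "theta_grid": theta_grid,
        "curves": curves,
        "groups": groups,
        "within_group_dissimilarity": within,
        "between_group_dissimilarity": between,
    }
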