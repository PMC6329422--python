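"""Synthetic questionnaire responses with the structure the analysis assumes.

The generator draws ordinal responses from the same grouped rating-scale
model the engine fits (one shared category-probability function), so every
downstream stage — calibration, fit statistics, dimensionality checks, DIF,
reliability, scoring — can be exercised end to end without any patient
data.  Optional mechanisms inject the departures the diagnostics are meant
to detect: off-model (uniform-random) items, a group-specific difficulty
shift for DIF, "does not apply" responding on the symptom-conditional
items, a retest administration with a chosen latent correlation, and
comparator variables (a dermatology-QoL-like total and an ordinal disease
stage).

Randomness uses one root seed with independent named substreams per
mechanism, so switching one mechanism on or off does not perturb the
draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .instrument import (
    DNA_CODE,
    Instrument,
    ResponseMatrix,
    published_instrument,
)
from .rasch import K_MAX, N_CATEGORIES, _probs_grid

#: Interference-direction item means of the published bank's descriptive
#: statistics (positively worded items flipped), used to place realistic
#: default difficulties: lower mean endorsement = harder to endorse.
_BANK_MEANS = np.array(
    [2.74, 2.01, 2.67, 2.15, 6 - 2.94, 6 - 3.47, 1.95, 2.20, 1.79, 2.28,
     2.11, 1.73, 2.67, 1.94]
)

#: Default ordered Andrich thresholds per rating-scale group (logits).
DEFAULT_TAU = {
    "frequency": np.array([-1.8, -0.6, 0.6, 1.8]),
    "intensity": np.array([-2.4, -0.8, 0.8, 2.4]),
}


def default_delta(instrument: Instrument) -> np.ndarray:
    """Realistic item difficulties: centered, scaled map of observed item means."""
    bank = published_instrument(active=[f"q{i:02d}" for i in range(1, 15)])
    mean_of = dict(zip(bank.item_ids, _BANK_MEANS))
    m = np.array([mean_of.get(iid, float(_BANK_MEANS.mean()))
                  for iid in instrument.item_ids])
    delta = -1.2 * (m - m.mean())
    return delta - delta.mean()


@dataclass
class SimulationTruth:
    """Generating parameters for a synthetic study.

    theta_sd is the SD of the standard-normal-family latent trait;
    misfit_items respond uniformly at random over the five categories;
    dif_spec, if given, is ``{"item": id, "covariate": name,
    "contrast": logits}`` — the item's difficulty is shifted by
    -contrast/2 in the covariate's first group and +contrast/2 in the
    second.
    """

    delta: np.ndarray
    tau: dict[str, np.ndarray]
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    misfit_items: frozenset[str] = frozenset()
    dif_spec: dict | None = None
    dna_rate: float = 0.0
    retest_rho: float = 0.9
    seed: int = 0

    def __post_init__(self):
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = {g: np.asarray(t, dtype=float) for g, t in self.tau.items()}
        for g, t in self.tau.items():
            if t.size != N_CATEGORIES - 1:
                raise ParameterError(
                    f"tau for group '{g}' must have {N_CATEGORIES - 1} entries"
                )
            if abs(t.sum()) > 1e-8:
                raise ParameterError(f"tau for group '{g}' must sum to 0")
        if not 0.0 <= self.dna_rate < 1.0:
            raise ParameterError("dna_rate must be in [0, 1)")
        if not -1.0 <= self.retest_rho <= 1.0:
            raise ParameterError("retest_rho must be in [-1, 1]")
        self.misfit_items = frozenset(self.misfit_items)

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent substreams of the root seed."""
        names = ["theta", "responses", "misfit", "dna", "retest",
                 "comparators", "covariates"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def make_truth(instrument: Instrument, seed: int = 0, **overrides) -> SimulationTruth:
    """Truth with realistic defaults for ``instrument`` (see docstring of module)."""
    base = dict(
        delta=default_delta(instrument),
        tau={g: DEFAULT_TAU[g].copy() for g in instrument.group_names},
        seed=seed,
    )
    base.update(overrides)
    return SimulationTruth(**base)


def _draw_categories(rng, theta, delta, cumtau_items) -> np.ndarray:
    """Inverse-CDF draws of categories 0..K for all persons x items."""
    phi = theta[:, None] - delta[None, :]
    probs = _probs_grid(phi, cumtau_items)
    cdf = np.cumsum(probs, axis=2)
    u = rng.random(phi.shape)
    return (u[:, :, None] > cdf).sum(axis=2)


def _categories_to_codes(cats: np.ndarray, instrument: Instrument) -> np.ndarray:
    codes = cats.astype(float) + 1.0
    for j, it in enumerate(instrument.items):
        if it.reverse_scored:
            codes[:, j] = 5.0 - cats[:, j]
    return codes


def _cumtau(instrument: Instrument, truth: SimulationTruth) -> np.ndarray:
    rows = []
    for it in instrument.items:
        t = truth.tau[it.scale_group.value]
        rows.append(np.concatenate([[0.0], np.cumsum(t)]))
    return np.asarray(rows)


def _simulate_from_theta(
    instrument: Instrument,
    theta: np.ndarray,
    truth: SimulationTruth,
    streams: dict,
    covariates: pd.DataFrame | None,
    person_ids,
) -> ResponseMatrix:
    n = theta.size
    m = instrument.n_items
    if truth.delta.size != m:
        raise ParameterError(
            f"delta has {truth.delta.size} entries for {m} active items"
        )
    delta = truth.delta.copy()
    cumtau = _cumtau(instrument, truth)

    if truth.dif_spec is None:
        cats = _draw_categories(streams["responses"], theta, delta, cumtau)
    else:
        spec = truth.dif_spec
        j = instrument.item_ids.index(spec["item"])
        if covariates is None or spec["covariate"] not in covariates:
            raise ParameterError(
                f"DIF covariate '{spec['covariate']}' not available"
            )
        labels = covariates[spec["covariate"]].to_numpy()
        uniq = pd.unique(labels)
        if len(uniq) != 2:
            raise ParameterError("DIF covariate must be binary")
        shift = np.where(labels == uniq[0], -0.5, 0.5) * spec["contrast"]
        # draw the DIF item separately with shifted difficulty
        cats = _draw_categories(streams["responses"], theta, delta, cumtau)
        dj = delta[j] + shift
        phi = theta - dj
        probs = _probs_grid(phi[:, None], cumtau[j : j + 1])[:, 0, :]
        u = streams["responses"].random(n)
        cats[:, j] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)

    # off-model items: uniform-random categories
    if truth.misfit_items:
        rng = streams["misfit"]
        for j, iid in enumerate(instrument.item_ids):
            if iid in truth.misfit_items:
                cats[:, j] = rng.integers(0, N_CATEGORIES, size=n)

    codes = _categories_to_codes(cats, instrument)

    # "does not apply" responding on DNA-capable items
    if truth.dna_rate > 0:
        rng = streams["dna"]
        for j, it in enumerate(instrument.items):
            if it.has_dna_option:
                mask = rng.random(n) < truth.dna_rate
                codes[mask, j] = DNA_CODE

    values = pd.DataFrame(codes, index=person_ids, columns=instrument.item_ids)
    return ResponseMatrix(values=values, covariates=covariates)


def _default_covariates(n: int, rng: np.random.Generator, person_ids) -> pd.DataFrame:
    """Demographics mimicking the validation sample's composition."""
    gender = np.where(rng.random(n) < 0.587, "female", "male")
    age = np.clip(np.round(rng.normal(59, 13.5, n)), 22, 86).astype(int)
    race = np.where(rng.random(n) < 0.857, "white", "nonwhite")
    return pd.DataFrame(
        {"gender": gender, "age": age, "race": race}, index=person_ids
    )


def simulate_responses(
    instrument: Instrument,
    n: int,
    truth: SimulationTruth,
    *,
    with_covariates: bool = True,
    theta: np.ndarray | None = None,
) -> tuple[ResponseMatrix, SimulationTruth, np.ndarray]:
    """Draw ``n`` response vectors from the grouped rating-scale model.

    Returns the response matrix, the truth used (echoed), and the latent
    person locations actually drawn.  Pass ``theta`` to condition on given
    latent locations (e.g. multi-factor scenarios) instead of drawing them.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    streams = truth.streams()
    if theta is None:
        theta = truth.theta_mean + truth.theta_sd * streams["theta"].standard_normal(n)
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.size != n:
            raise ParameterError("theta override must have length n")
    person_ids = [f"p{i + 1:05d}" for i in range(n)]
    cov = (
        _default_covariates(n, streams["covariates"], person_ids)
        if with_covariates
        else None
    )
    rm = _simulate_from_theta(instrument, theta, truth, streams, cov, person_ids)
    return rm, truth, theta


def simulate_retest(
    instrument: Instrument,
    n: int,
    truth: SimulationTruth,
    *,
    retest_fraction: float = 1.0,
) -> tuple[ResponseMatrix, ResponseMatrix, np.ndarray, np.ndarray]:
    """Two administrations with latent correlation ``truth.retest_rho``.

    The second administration covers the first ``round(retest_fraction*n)``
    persons (a retest subsample), uses the same item parameters, and draws
    its latent locations from the Gaussian copula
    ``theta2 = rho*theta1 + sqrt(1-rho^2)*eps``.
    """
    streams = truth.streams()
    theta1 = truth.theta_mean + truth.theta_sd * streams["theta"].standard_normal(n)
    rho = truth.retest_rho
    eps = streams["retest"].standard_normal(n)
    theta2 = (
        truth.theta_mean
        + rho * (theta1 - truth.theta_mean)
        + np.sqrt(max(0.0, 1 - rho**2)) * truth.theta_sd * eps
    )
    n2 = int(round(retest_fraction * n))
    person_ids = [f"p{i + 1:05d}" for i in range(n)]
    cov = _default_covariates(n, streams["covariates"], person_ids)
    rm1 = _simulate_from_theta(
        instrument, theta1, truth, streams, cov, person_ids
    )
    streams2 = replace(truth, seed=truth.seed).streams()  # fresh per-purpose
    # second administration draws come from the retest stream to keep them
    # independent of the first administration's response noise
    streams2["responses"] = streams["retest"]
    streams2["dna"] = streams["retest"]
    streams2["misfit"] = streams["retest"]
    rm2 = _simulate_from_theta(
        instrument,
        theta2[:n2],
        truth,
        streams2,
        cov.iloc[:n2],
        person_ids[:n2],
    )
    return rm1, rm2, theta1, theta2[:n2]


def _ordinal_attenuation(cuts: np.ndarray) -> float:
    """corr(discretized L, theta)/corr(L, theta) for standard-normal L.

    With Y = sum of indicators 1[L > c_k], Cov(Y, L) = sum_k phi(c_k) and
    Var(Y) follows from the cell probabilities, so the attenuation factor
    is analytic.
    """
    dens = stats.norm.pdf(cuts).sum()
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    pk = np.diff(stats.norm.cdf(edges))
    levels = np.arange(pk.size, dtype=float)
    mu = (levels * pk).sum()
    var = ((levels - mu) ** 2 * pk).sum()
    return float(dens / np.sqrt(var))


def simulate_comparators(
    truth: SimulationTruth,
    theta: np.ndarray,
    convergent_loading: float = 0.85,
    stage_loading: float = 0.26,
    n_stage_levels: int = 3,
    stage_probs: tuple = (0.52, 0.22, 0.26),
) -> pd.DataFrame:
    """Comparator variables: a convergent continuous QoL total and ordinal stage.

    The continuous comparator is ``loading * z(theta) + noise``.  Stage is
    an ordinal discretization of a latent variable whose correlation with
    theta is inflated analytically so the *discretized* stage correlates
    with theta at approximately ``stage_loading``.
    """
    for ld in (convergent_loading, stage_loading):
        if not -1.0 <= ld <= 1.0:
            raise ParameterError("loadings must lie in [-1, 1]")
    rng = truth.streams()["comparators"]
    n = theta.size
    z = (theta - theta.mean()) / (theta.std() if theta.std() > 0 else 1.0)
    noise_sd = np.sqrt(max(0.0, 1 - convergent_loading**2))
    comparator = convergent_loading * z + noise_sd * rng.standard_normal(n)

    cum = np.cumsum(stage_probs)[: n_stage_levels - 1]
    cuts = stats.norm.ppf(cum)
    atten = _ordinal_attenuation(cuts)
    rho_latent = np.clip(stage_loading / atten, -1.0, 1.0)
    latent = rho_latent * z + np.sqrt(max(0.0, 1 - rho_latent**2)) * (
        rng.standard_normal(n)
    )
    stage = (latent[:, None] > cuts[None, :]).sum(axis=1) + 1
    return pd.DataFrame(
        {"comparator_qol": comparator, "stage": stage},
        index=[f"p{i + 1:05d}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# Study-mimicking preset
# ---------------------------------------------------------------------------

#: Conditions of the validation study this package emulates: 126
#: respondents, a 12-item form, two DNA-capable items, 52.4% retest 5 days
#: later, and demographic splits for DIF.
STUDY_PRESET = {
    "n": 126,
    "retest_fraction": 66 / 126,
    "dna_rate": 0.10,
    "retest_rho": 0.95,
    # standard-normal latent trait: matches the person-map convention
    # (logit ruler, persons mean 0 / SD 1) and yields a true person
    # separation reliability near the published one for this form
    "theta_sd": 1.0,
}


def simulate_study(seed: int = 0, n: int | None = None) -> dict:
    """One-call synthetic replica of the validation study's data layout.

    Returns a dict with the instrument, first and second administrations,
    latent truth, and a covariate table that includes comparator variables.
    """
    instrument = published_instrument()
    truth = make_truth(
        instrument,
        seed=seed,
        dna_rate=STUDY_PRESET["dna_rate"],
        retest_rho=STUDY_PRESET["retest_rho"],
        theta_sd=STUDY_PRESET["theta_sd"],
    )
    n = STUDY_PRESET["n"] if n is None else n
    rm1, rm2, theta1, theta2 = simulate_retest(
        instrument, n, truth, retest_fraction=STUDY_PRESET["retest_fraction"]
    )
    comps = simulate_comparators(truth, theta1)
    cov = rm1.covariates.join(comps)
    rm1 = ResponseMatrix(values=rm1.values, covariates=cov)
    return {
        "instrument": instrument,
        "responses": rm1,
        "retest_responses": rm2,
        "truth": truth,
        "theta": theta1,
        "theta_retest": theta2,
    }
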