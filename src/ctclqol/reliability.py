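"""Separation reliability, test-retest stability, and validity correlations."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedCorrelationError

logger = logging.getLogger(__name__)


def separation_reliability(measures, ses) -> float:
    """Rasch separation reliability.

    R = (observed measure variance - mean squared standard error) /
    observed measure variance, clamped to [0, 1].  Applied to person
    measures it indexes how well the instrument separates respondents;
    applied to item difficulties it indexes how stably the sample locates
    the items.
    """
    m = np.asarray(measures, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(m) & np.isfinite(s)
    m, s = m[ok], s[ok]
    if m.size < 2:
        raise InsufficientDataError("need at least 2 measures")
    var_obs = float(np.var(m, ddof=1))
    if var_obs <= 0:
        logger.warning("zero observed variance; reliability set to 0")
        return 0.0
    mse = float(np.mean(s**2))
    return float(np.clip((var_obs - mse) / var_obs, 0.0, 1.0))


def test_retest(admin1, admin2) -> dict:
    """Pearson stability coefficient between two administrations' scores."""
    a = np.asarray(admin1, dtype=float)
    b = np.asarray(admin2, dtype=float)
    if a.shape != b.shape:
        raise InsufficientDataError("administrations must be paired")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise InsufficientDataError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("constant scores in one administration")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": int(a.size)}


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> dict:
    """Steiger's test for two dependent correlations sharing one variable.

    Tests H0: rho(j,k) = rho(j,h) given the correlation r_kh between the
    two non-shared variables, using Fisher-transformed correlations and
    the pooled estimate of the shared-variable correlation.
    """
    if n < 4:
        raise InsufficientDataError("need n >= 4")
    z1 = np.arctanh(r_jk)
    z2 = np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    # covariance of the two correlations (Steiger 1980, pooled form)
    num = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (
        1 - 2 * rbar**2 - r_kh**2
    )
    s = num / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - s)))
    p = 2 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}


def convergent_discriminant(qol, comparator, stage) -> dict:
    """Convergent vs discriminant validity of the instrument's scores.

    Correlates the instrument total with a convergent comparator (another
    QoL measure) and with a discriminant variable (ordinal disease stage),
    then tests whether the convergent correlation significantly exceeds the
    discriminant one with Steiger's z for dependent correlations sharing
    the instrument's score.
    """
    q = np.asarray(qol, dtype=float)
    c = np.asarray(comparator, dtype=float)
    s = np.asarray(stage, dtype=float)
    ok = np.isfinite(q) & np.isfinite(c) & np.isfinite(s)
    q, c, s = q[ok], c[ok], s[ok]
    if q.size < 4:
        raise InsufficientDataError("need at least 4 complete triples")
    for name, v in (("qol", q), ("comparator", c), ("stage", s)):
        if np.std(v) == 0:
            raise UndefinedCorrelationError(f"'{name}' is constant")
    r_conv, p_conv = stats.pearsonr(q, c)
    r_disc, p_disc = stats.pearsonr(q, s)
    r_cs, _ = stats.pearsonr(c, s)
    test = steiger_z(float(r_conv), float(r_disc), float(r_cs), q.size)
    return {
        "r_convergent": float(r_conv),
        "p_convergent": float(p_conv),
        "r_discriminant": float(r_disc),
        "p_discriminant": float(p_disc),
        "r_comparator_stage": float(r_cs),
        "dependent_correlation_z": test["z"],
        "p": test["p"],
        "n": int(q.size),
    }
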