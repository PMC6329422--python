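"""Raw-to-scaled score conversion and scoring of the published instrument.

Two distinct capabilities live here:

* :func:`build_score_table` reconstructs a conversion table from any
  calibration: for each attainable raw total it finds the latent measure
  whose expected total equals that raw score (test characteristic curve
  inversion), then standardizes measures on the calibration sample to a
  mean of 100 and an SD of 15.
* :func:`published_score` scores respondents on the released 12-item form
  using the *published* conversion and interpretation tables embedded
  verbatim below — those tables, not any recalibration, are authoritative
  for operational scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CtclQolError,
    ImpossibleInputError,
    IncompleteRecordError,
    UnmappedScoreError,
)
from .instrument import Instrument, published_instrument, raw_total
from .rasch import (
    CalibrationResult,
    EXTREME_ADJUST,
    _cumtau_per_item,
    _solve_theta_for_score,
)

# ---------------------------------------------------------------------------
# Published conversion table (raw total -> scaled score).  Raw totals of 10
# or 11 arise only through "does not apply" responses and are interpreted as
# equivalent to 12.
# ---------------------------------------------------------------------------

_TABLE3_ROWS: list[tuple[int, int]] = [
    (12, 62), (13, 74), (14, 80), (15, 84), (16, 87), (17, 89), (18, 91),
    (19, 93), (20, 94), (21, 96), (22, 97), (23, 98), (24, 100), (25, 101),
    (26, 102), (27, 103), (28, 104), (29, 105), (30, 106), (31, 107),
    (32, 108), (33, 109), (34, 110), (35, 111), (36, 112), (37, 113),
    (38, 114), (39, 115), (40, 116), (41, 117), (42, 118), (43, 119),
    (44, 120), (45, 121), (46, 123), (47, 124), (48, 125), (49, 126),
    (50, 128), (51, 129), (52, 131), (53, 133), (54, 135), (55, 137),
    (56, 139), (57, 143), (58, 147), (59, 154), (60, 154),
]

RAW_TO_SCALED: dict[int, int] = {10: 62, 11: 62, **dict(_TABLE3_ROWS)}

#: Qualitative interpretation bands for scaled scores.  The gaps between
#: bands (90, 134, ...) are scaled values no raw total produces.
QUALITATIVE_BANDS: list[tuple[int, int, str]] = [
    (62, 89, "No to low interference"),
    (91, 105, "Mild interference"),
    (106, 117, "Moderate interference"),
    (118, 133, "Substantial interference"),
    (135, 154, "Severe interference"),
]

MEAN_TARGET = 100.0
SD_TARGET = 15.0


def categorize(scaled: int) -> str:
    """Qualitative band label for an attainable scaled score."""
    for lo, hi, label in QUALITATIVE_BANDS:
        if lo <= scaled <= hi:
            return label
    raise UnmappedScoreError(
        f"scaled score {scaled} is not attainable from any raw total"
    )


def published_score(row, instrument: Instrument | None = None) -> dict:
    """Score one respondent on the published 12-item form.

    Requires all 12 items answered ("does not apply" counts as answered,
    and only on the two items that offer it).  Returns the raw total, the
    published scaled score, and the qualitative band.
    """
    if instrument is None:
        instrument = published_instrument()
    raw = raw_total(row, instrument)
    if raw not in RAW_TO_SCALED:
        raise ImpossibleInputError(
            f"raw total {raw} outside the attainable range 10-60"
        )
    scaled = RAW_TO_SCALED[raw]
    return {"raw": raw, "scaled": scaled, "band": categorize(scaled)}


def score_responses(responses_df: pd.DataFrame,
                    instrument: Instrument | None = None,
                    *, lenient: bool = False) -> pd.DataFrame:
    """Score every row of a raw-code response table.

    With ``lenient=True`` incomplete rows get NaN scores instead of
    raising.
    """
    if instrument is None:
        instrument = published_instrument()
    out = []
    for pid, row in responses_df.iterrows():
        try:
            rec = published_score(row, instrument)
        except (IncompleteRecordError, ImpossibleInputError):
            if not lenient:
                raise
            rec = {"raw": np.nan, "scaled": np.nan, "band": ""}
        rec["person_id"] = pid
        out.append(rec)
    return pd.DataFrame(out).set_index("person_id")[["raw", "scaled", "band"]]


# ---------------------------------------------------------------------------
# Score-table construction from a calibration
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ScoreTable:
    """Raw total -> latent measure -> integer scaled score.

    ``transform`` records the standardization: scaled = 100 + 15 * (theta -
    sample mean) / sample SD, computed on the calibration sample's person
    measures.
    """

    rows: pd.DataFrame  # columns: raw_total, measure, scaled_exact, scaled
    transform: dict

    def __post_init__(self):
        raws = self.rows["raw_total"].to_numpy()
        if not np.array_equal(raws, np.arange(raws[0], raws[-1] + 1)):
            raise CtclQolError("raw totals must be contiguous")
        scaled = self.rows["scaled"].to_numpy()
        if np.any(np.diff(scaled) < 0):
            raise CtclQolError("scaled scores must be nondecreasing in raw")

    def lookup(self, raw: int) -> int:
        r = self.rows.set_index("raw_total")
        if raw not in r.index:
            raise ImpossibleInputError(f"raw total {raw} not in table")
        return int(r.loc[raw, "scaled"])

    def scale_measure(self, theta: float) -> float:
        t = self.transform
        return MEAN_TARGET + SD_TARGET * (theta - t["sample_mean"]) / t["sample_sd"]


def build_score_table(
    result: CalibrationResult,
    sample_thetas: np.ndarray | None = None,
    *,
    extreme_adjust: float = EXTREME_ADJUST,
) -> ScoreTable:
    """Construct a raw-to-scaled conversion table from a calibration.

    For each attainable raw total R the measure theta_R solves
    ``expected total(theta) = R`` on the test characteristic curve, with
    the extreme raw totals nudged ``extreme_adjust`` score points inward so
    their measures are finite.  Scaled scores standardize the calibration
    sample's person measures to mean 100, SD 15 and are rounded half-up to
    integers.  Raw totals attainable only through "does not apply"
    responses (below the all-items minimum) map to the minimum row.
    """
    p = result.params
    if sample_thetas is None:
        sample_thetas = result.theta.dropna().to_numpy()
    sample_thetas = np.asarray(sample_thetas, dtype=float)
    mean, sd = float(sample_thetas.mean()), float(sample_thetas.std(ddof=1))
    if sd <= 0:
        raise CtclQolError("calibration sample has no measure variance")

    m = len(p.item_ids)
    cumtau = _cumtau_per_item(p)
    k_max = cumtau.shape[1] - 1
    n_dna = (
        len([it for it in result.instrument.items if it.has_dna_option])
        if result.instrument is not None
        else 0
    )

    raw_min, raw_max = m, (k_max + 1) * m  # codes 1..5 => totals m..5m
    rows = []
    measures = {}
    for raw in range(raw_min, raw_max + 1):
        target = float(raw - m)  # 0..4-scale total
        if target <= 0:
            target = extreme_adjust
        elif target >= k_max * m:
            target = k_max * m - extreme_adjust
        theta_r = _solve_theta_for_score(target, p.delta, cumtau)
        measures[raw] = theta_r
    # monotonicity of the characteristic curve guarantees increasing measures
    vals = [measures[r] for r in range(raw_min, raw_max + 1)]
    if np.any(np.diff(vals) <= 0):
        raise CtclQolError("non-monotone test characteristic curve")

    for raw in range(raw_min - n_dna, raw_max + 1):
        eff = max(raw, raw_min)  # footnote-c rule: sub-minimum raws = minimum
        theta_r = measures[eff]
        exact = MEAN_TARGET + SD_TARGET * (theta_r - mean) / sd
        rows.append(
            {
                "raw_total": raw,
                "measure": theta_r,
                "scaled_exact": exact,
                "scaled": _round_half_up(exact),
            }
        )
    table = pd.DataFrame(rows)
    return ScoreTable(
        rows=table,
        transform={
            "mean_target": MEAN_TARGET,
            "sd_target": SD_TARGET,
            "sample_mean": mean,
            "sample_sd": sd,
            "n_sample": int(sample_thetas.size),
        },
    )
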