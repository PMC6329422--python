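"""Questionnaire structure, response data validation, and raw totals.

The MF/SS-CTCL QoL instrument is a short polytomous questionnaire in which
each item is rated on five ordered categories (coded 1-5).  Items fall into
two rating-scale groups by wording: *frequency* items ("never" ... "always")
and *intensity* items ("not at all" ... "very much").  A subset of items
offers a sixth choice, "Does not apply (I don't have symptoms right now)",
coded 0.  Two items are worded positively (confidence, coping) and are
reverse-scored so that higher totals always mean more interference with
quality of life.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    IncompleteRecordError,
    ResponseValidationError,
    SchemaError,
)

DNA_CODE = 0  # "Does not apply (I don't have symptoms right now)"


class ScaleGroup(str, enum.Enum):
    FREQUENCY = "frequency"
    INTENSITY = "intensity"


@dataclass(frozen=True)
class Item:
    """One questionnaire item.

    Parameters
    ----------
    id : str
        Short unique identifier (e.g. ``"q05"``).
    text : str
        Full item wording.
    scale_group : ScaleGroup
        Which of the two rating scales the item uses.
    has_dna_option : bool
        Whether the item offers the "Does not apply" (code 0) choice.
    reverse_scored : bool
        Whether a high rating indicates *better* functioning, so the item
        is flipped (code ``c`` contributes ``6 - c``) before summation.
    """

    id: str
    text: str
    scale_group: ScaleGroup
    has_dna_option: bool = False
    reverse_scored: bool = False

    def __post_init__(self):
        object.__setattr__(self, "scale_group", ScaleGroup(self.scale_group))


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of items plus rating-scale metadata."""

    items: tuple[Item, ...]
    n_categories: int = 5
    recall_period_days: int = 28

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in instrument")
        if self.n_categories < 2:
            raise ValueError("n_categories must be at least 2")

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def groups(self) -> list[ScaleGroup]:
        return [it.scale_group for it in self.items]

    @property
    def group_names(self) -> list[str]:
        """Distinct scale-group names in first-appearance order."""
        seen: list[str] = []
        for it in self.items:
            g = it.scale_group.value
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def dna_item_ids(self) -> list[str]:
        return [it.id for it in self.items if it.has_dna_option]

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Sequence[str]) -> "Instrument":
        """New instrument restricted to ``item_ids`` (original order kept)."""
        wanted = set(item_ids)
        missing = wanted - set(self.item_ids)
        if missing:
            raise KeyError(f"unknown item ids: {sorted(missing)}")
        return replace(
            self, items=tuple(it for it in self.items if it.id in wanted)
        )

    # --- YAML round-trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_categories": self.n_categories,
            "recall_period_days": self.recall_period_days,
            "items": [
                {
                    "id": it.id,
                    "text": it.text,
                    "scale_group": it.scale_group.value,
                    "has_dna_option": it.has_dna_option,
                    "reverse_scored": it.reverse_scored,
                }
                for it in self.items
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Instrument":
        doc = yaml.safe_load(Path(path).read_text())
        items = tuple(Item(**d) for d in doc["items"])
        return cls(
            items=items,
            n_categories=doc.get("n_categories", 5),
            recall_period_days=doc.get("recall_period_days", 28),
        )


@dataclass
class ResponseMatrix:
    """Persons x items grid of raw response codes.

    ``values`` holds codes as floats: 1-5 for ratings, 0 for "does not
    apply", NaN for missing.  ``covariates`` optionally carries per-person
    demographics, comparator scores and retest totals, indexed like
    ``values``.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = self.values.astype(float)
        self.values.index.name = "person_id"
        if self.covariates is not None and not self.values.index.equals(
            self.covariates.index
        ):
            raise ValueError("covariates index must match response index")

    @property
    def person_ids(self) -> list:
        return list(self.values.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    def validate(self, instrument: Instrument) -> None:
        """Check coding rules against the instrument; raise on violation."""
        if list(self.values.columns) != instrument.item_ids:
            extra = set(self.values.columns) - set(instrument.item_ids)
            if extra:
                raise SchemaError(f"unknown columns: {sorted(extra)}")
            raise SchemaError(
                "response columns do not match instrument item ids"
            )
        arr = self.values.to_numpy()
        for j, it in enumerate(instrument.items):
            col = arr[:, j]
            obs = col[~np.isnan(col)]
            bad_range = (obs != np.round(obs)) | (obs < 0) | (obs > 5)
            if bad_range.any():
                pid = self.values.index[np.flatnonzero(~np.isnan(col))[
                    int(np.flatnonzero(bad_range)[0])
                ]]
                raise ResponseValidationError(
                    f"code {obs[bad_range][0]:g} out of range 0-5 for item "
                    f"'{it.id}' (person '{pid}')",
                    person_id=pid,
                    item_id=it.id,
                )
            if not it.has_dna_option and (obs == DNA_CODE).any():
                rows = np.flatnonzero(col == DNA_CODE)
                pid = self.values.index[rows[0]]
                raise ResponseValidationError(
                    f"code 0 ('does not apply') on item '{it.id}' which has "
                    f"no such option (person '{pid}')",
                    person_id=pid,
                    item_id=it.id,
                )

    def scored(self, instrument: Instrument) -> pd.DataFrame:
        """Responses on the 0-4 analysis scale, oriented toward interference.

        Rating code ``c`` maps to category ``c - 1``; reverse-scored items
        map to ``5 - c``.  The "does not apply" code and blanks both become
        NaN: calibration skips those cells (they re-enter only in raw
        totals).
        """
        out = self.values.copy()
        for it in instrument.items:
            col = out[it.id]
            col = col.mask(col == DNA_CODE)
            out[it.id] = (5.0 - col) if it.reverse_scored else (col - 1.0)
        return out


def load_responses(path: str | Path, instrument: Instrument) -> ResponseMatrix:
    """Read a wide-format response CSV and validate it.

    The file must have a header of item ids (a leading ``person_id`` column
    is optional), codes 1-5, a literal 0 for "does not apply", and empty
    cells for missing.  Extra columns not matching item ids are treated as
    covariates only if the header starts with ``person_id``; otherwise an
    unknown column is a schema error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "person_id" in df.columns:
        df = df.set_index("person_id")
    item_cols = [c for c in df.columns if c in set(instrument.item_ids)]
    unknown = [
        c for c in df.columns if c not in set(instrument.item_ids)
    ]
    if set(item_cols) != set(instrument.item_ids):
        missing = set(instrument.item_ids) - set(item_cols)
        raise SchemaError(f"missing item columns: {sorted(missing)}")
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    vals = df[instrument.item_ids].mask(lambda v: v == "")
    try:
        vals = vals.astype(float)
    except ValueError as exc:
        raise ResponseValidationError(f"non-numeric response code: {exc}")
    rm = ResponseMatrix(values=vals)
    rm.validate(instrument)
    return rm


def write_responses(rm: ResponseMatrix, path: str | Path) -> None:
    """Write a ResponseMatrix back to the CSV dialect ``load_responses`` reads."""
    out = rm.values.copy()
    out.index.name = "person_id"
    # integer-looking codes, blank for missing
    out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


def raw_total(
    row: Mapping[str, float] | pd.Series, instrument: Instrument
) -> int:
    """Raw instrument total for one person.

    "Does not apply" contributes 0; reverse-scored items contribute
    ``6 - code``; every active item must be answered (the "does not apply"
    choice counts as answered).
    """
    total = 0
    for it in instrument.items:
        v = row.get(it.id) if hasattr(row, "get") else row[it.id]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise IncompleteRecordError(
                f"item '{it.id}' missing: each of the {instrument.n_items} "
                "items must be completed"
            )
        v = int(v)
        if v == DNA_CODE:
            if not it.has_dna_option:
                raise ResponseValidationError(
                    f"code 0 on item '{it.id}' without a 'does not apply' option",
                    item_id=it.id,
                )
            continue  # contributes 0
        if not 1 <= v <= 5:
            raise ResponseValidationError(
                f"code {v} out of range for item '{it.id}'", item_id=it.id
            )
        total += (6 - v) if it.reverse_scored else v
    return total


def raw_totals(
    rm: ResponseMatrix, instrument: Instrument, *, lenient: bool = True
) -> pd.Series:
    """Raw totals for every person; NaN for incomplete rows when lenient."""
    out = {}
    for pid, row in rm.values.iterrows():
        try:
            out[pid] = raw_total(row, instrument)
        except IncompleteRecordError:
            if not lenient:
                raise
            out[pid] = np.nan
    return pd.Series(out, name="raw_total")


# ---------------------------------------------------------------------------
# The published item bank
# ---------------------------------------------------------------------------

_STEM = "mycosis fungoides or Sézary syndrome"

_BANK_TEXTS = [
    f"In the past 4 weeks, how much did you worry that your {_STEM} may get worse?",
    f"In the past 4 weeks, how often did you feel hopeless because of having {_STEM}?",
    f"In the past 4 weeks, how frustrated were you by the unpredictability of {_STEM}?",
    f"In the past 4 weeks, how often did you feel depressed or sad because of {_STEM}?",
    f"In the past 4 weeks, how confident did you feel about managing your {_STEM}?",
    "In the past 4 weeks, to what extent were you able to cope with the daily "
    "demands (symptom impact and management, treatment, side effects, "
    f"appointments, etc) of {_STEM}?",
    f"In the past 4 weeks, how severe were your {_STEM} symptoms?",
    f"In the past 4 weeks, how burdensome was your {_STEM} treatment?",
    f"In the past 4 weeks, how much did your {_STEM} limit your daily "
    "activities (work inside and outside of the house, self-care such as "
    "cooking, cleaning, getting dressed, etc)?",
    f"In the past 4 weeks, how much did {_STEM} limit your ability to wear "
    "clothes you wanted to?",
    f"In the past 4 weeks, how often did {_STEM} (the condition or associated "
    "treatment) leave you too tired to work or do daily activities?",
    f"In the past 4 weeks, how much did {_STEM} negatively affect your "
    "relationships with others close to you?",
    f"In the past 4 weeks, how often did you feel that others do not "
    f"understand what you are going through with {_STEM}?",
    f"In the past 4 weeks, to what extent did {_STEM} make you feel "
    "uncomfortable being around people other than close family and friends?",
]

# Group membership follows item wording: "how often" items use the
# frequency scale (never..always); all others use the intensity scale
# (not at all..very much).
_FREQUENCY_ITEMS = {2, 4, 11, 13}

# Which 4 bank items offered "Does not apply (I don't have symptoms right
# now)" is not published; we attach it to the four items most clearly
# conditional on current symptoms, two of which sit in the default active
# set so that raw totals of 10-11 remain attainable.
_DNA_ITEMS = {7, 10, 13, 14}

# Positively worded items (confidence in managing; ability to cope) are
# reverse-scored by default so higher totals always mean more interference.
_REVERSED_ITEMS = {5, 6}

#: Default active selection.  The publication reports a final 12-item form
#: but never identifies the two bank items that were dropped; this default
#: keeps items 1-12 and is an explicit, overridable configuration choice,
#: NOT recovered study content.
DEFAULT_ACTIVE = tuple(f"q{i:02d}" for i in range(1, 13))


def item_bank() -> Instrument:
    """The full 14-item bank."""
    items = []
    for i, text in enumerate(_BANK_TEXTS, start=1):
        items.append(
            Item(
                id=f"q{i:02d}",
                text=text,
                scale_group=(
                    ScaleGroup.FREQUENCY
                    if i in _FREQUENCY_ITEMS
                    else ScaleGroup.INTENSITY
                ),
                has_dna_option=i in _DNA_ITEMS,
                reverse_scored=i in _REVERSED_ITEMS,
            )
        )
    return Instrument(items=tuple(items))


def published_instrument(
    active: Sequence[str] | None = None,
) -> Instrument:
    """The published 12-item instrument.

    Parameters
    ----------
    active : sequence of item ids, optional
        Which 12 of the 14 bank items constitute the final form.  The
        publication does not identify the two dropped items, so the default
        (items 1-12) is a configuration convention — override it if the
        composition is known.
    """
    bank = item_bank()
    if active is None:
        active = DEFAULT_ACTIVE
    return bank.subset(active)
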