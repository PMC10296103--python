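"""Psychosexual questionnaire scoring and the attraction-vector representation.

Two self-report instruments are scored here:

* **EROS** — 16 items on a 1–5 scale, 8 assessing androphilia (attraction to
  males) and 8 assessing gynephilia (attraction to females).  The two scale
  means (each in [1, 5]) are treated as the components of a 2-D attraction
  vector.  Its *magnitude* ``sqrt(a**2 + g**2)`` summarises the overall
  strength of attractions (attainable range [sqrt(2), sqrt(50)] ~ [1.41,
  7.07]); its *phase* ``arccos(a / magnitude)`` in degrees summarises the
  androphilia–gynephilia valence (attainable range ~ [11.31, 78.69]; 45 deg
  means equal scores, larger is more gynephilic).

* **GIDYQ-AA** — 27 items on a 1–5 scale measuring gender identity /
  gender dysphoria; a mean score below 3.00 screens positive for likely
  gender dysphoria.

A scale mean is computed only when at least 75% of its items were answered;
otherwise the participant's score is missing (NaN) and propagates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EROS_N_ITEMS",
    "GIDYQ_N_ITEMS",
    "GD_THRESHOLD",
    "AttractionVector",
    "ParticipantRecord",
    "score_scale",
    "attraction_magnitude",
    "attraction_phase",
    "attraction_components",
    "gd_flag",
    "load_participants",
    "participants_frame",
]

EROS_N_ITEMS = 8
GIDYQ_N_ITEMS = 27

#: GIDYQ-AA screening threshold: a mean strictly below this indicates a
#: likelihood of meeting gender dysphoria criteria.
GD_THRESHOLD = 3.00

GROUPS = ("cis_boy", "gd_afab", "cis_girl")


class ScaleValidationError(ValueError):
    """An item response lies outside the 1–5 scale."""


def _validate_items(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    present = ~np.isnan(arr)
    bad = present & ((arr < 1) | (arr > 5) | (arr != np.round(arr)))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ScaleValidationError(
            f"item {idx} has response {arr[idx]!r}, expected an integer in 1..5"
        )
    return arr


def score_scale(values, n_items: int | None = None, min_fraction: float = 0.75) -> float:
    """Mean of the present item responses, or NaN under the 75% rule.

    Parameters
    ----------
    values
        Item responses on the 1–5 scale; missing items as NaN/None.
    n_items
        Number of slots the scale has.  Defaults to ``len(values)``.
    min_fraction
        Minimum fraction of items that must be answered for the mean to be
        computed (default 0.75).

    Returns
    -------
    float
        Arithmetic mean of the present responses, or NaN if fewer than
        ``min_fraction`` of the slots were answered.
    """
    arr = _validate_items([np.nan if v is None else v for v in values])
    if n_items is None:
        n_items = arr.size
    present = ~np.isnan(arr)
    if present.sum() / n_items < min_fraction:
        return float("nan")
    return float(arr[present].mean())


def _check_mean_range(name: str, value: float) -> None:
    if math.isnan(value):
        raise ValueError(f"{name} is missing (NaN)")
    if not 1.0 <= value <= 5.0:
        raise ValueError(f"{name}={value} outside the attainable scale range [1, 5]")


def attraction_magnitude(a: float, g: float) -> float:
    """Strength of attractions: Euclidean length of the (a, g) vector.

    ``sqrt(a**2 + g**2)`` for androphilia mean ``a`` and gynephilia mean
    ``g``, each in [1, 5]; range [sqrt(2), sqrt(50)] ~ [1.41, 7.07].
    """
    _check_mean_range("androphilia_mean", a)
    _check_mean_range("gynephilia_mean", g)
    return math.hypot(a, g)


def attraction_phase(a: float, g: float) -> float:
    """Androphilia–gynephilia valence in degrees.

    ``arccos(a / sqrt(a**2 + g**2)) * 180 / pi``.  11 deg is exclusive
    androphilia, 79 deg exclusive gynephilia, 45 deg equal scores; the
    attainable range is symmetric, 45 +/- ~34 deg.
    """
    m = attraction_magnitude(a, g)
    return math.degrees(math.acos(a / m))


def attraction_components(magnitude: float, phase_deg: float) -> tuple[float, float]:
    """Invert (magnitude, phase) back to the (androphilia, gynephilia) means."""
    rad = math.radians(phase_deg)
    return magnitude * math.cos(rad), magnitude * math.sin(rad)


def gd_flag(gidyq_mean: float) -> bool | float:
    """True iff the GIDYQ-AA mean falls strictly below the 3.00 threshold.

    A missing mean (NaN) yields a missing flag (NaN), never False.
    """
    if gidyq_mean is None or (isinstance(gidyq_mean, float) and math.isnan(gidyq_mean)):
        return float("nan")
    _check_mean_range("gidyq_mean", gidyq_mean)
    return bool(gidyq_mean < GD_THRESHOLD)


@dataclass(frozen=True)
class AttractionVector:
    magnitude: float
    phase_deg: float

    @classmethod
    def from_means(cls, a: float, g: float) -> "AttractionVector":
        return cls(attraction_magnitude(a, g), attraction_phase(a, g))


@dataclass
class ParticipantRecord:
    """Scored demographic and psychosexual profile of one participant."""

    id: str
    group: str
    age_months: int
    androphilia_mean: float
    gynephilia_mean: float
    gidyq_mean: float
    attraction: AttractionVector = field(init=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.attraction = AttractionVector.from_means(
            self.androphilia_mean, self.gynephilia_mean
        )

    @property
    def gd_flag(self):
        return gd_flag(self.gidyq_mean)


def _age_months_from_dates(birth: str, consent: str) -> int:
    """Birth-to-consent age in months, rounded to the nearest month."""
    b, c = pd.Timestamp(birth), pd.Timestamp(consent)
    months = (c.year - b.year) * 12 + (c.month - b.month)
    # fractional remainder measured in days relative to a 30.44-day month
    rem = (c.day - b.day) / 30.44
    return int(round(months + rem))


def load_participants(path_or_df) -> list[ParticipantRecord]:
    """Score a participant item table into :class:`ParticipantRecord` rows.

    The table needs ``id``, ``group``, either ``age_months`` or the pair
    ``birth_date``/``consent_date`` (ISO dates), 16 EROS item columns
    (``eros_a1..8``, ``eros_g1..8``) and 27 GIDYQ columns (``gidyq1..27``).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    records = []
    a_cols = [f"eros_a{i}" for i in range(1, EROS_N_ITEMS + 1)]
    g_cols = [f"eros_g{i}" for i in range(1, EROS_N_ITEMS + 1)]
    q_cols = [f"gidyq{i}" for i in range(1, GIDYQ_N_ITEMS + 1)]
    for col in a_cols + g_cols + q_cols:
        if col not in df.columns:
            raise ValueError(f"missing item column {col!r}")
    for _, row in df.iterrows():
        if "age_months" in df.columns and not pd.isna(row.get("age_months")):
            age = int(row["age_months"])
        else:
            age = _age_months_from_dates(row["birth_date"], row["consent_date"])
        records.append(
            ParticipantRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                age_months=age,
                androphilia_mean=score_scale(row[a_cols].to_numpy(), EROS_N_ITEMS),
                gynephilia_mean=score_scale(row[g_cols].to_numpy(), EROS_N_ITEMS),
                gidyq_mean=score_scale(row[q_cols].to_numpy(), GIDYQ_N_ITEMS),
            )
        )
    return records


def participants_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten scored records into the analysis table used downstream."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "group": [r.group for r in records],
            "age_months": [r.age_months for r in records],
            "androphilia_mean": [r.androphilia_mean for r in records],
            "gynephilia_mean": [r.gynephilia_mean for r in records],
            "gidyq_mean": [r.gidyq_mean for r in records],
            "gd_flag": [r.gd_flag for r in records],
            "strength": [r.attraction.magnitude for r in records],
            "degree": [r.attraction.phase_deg for r in records],
        }
    )
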