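"""ABC Dementia Scale (ABC-DS) instrument model and AB-design series container.

The ABC-DS is a 13-item caregiver-rated dementia scale.  Each item is scored
from 1 to 9 points; higher scores indicate milder dementia.  The items split
into three subscales:

* ADL (activities of daily living): 6 items, subscale range 6-54
* BPSD (behavioral and psychological symptoms): 3 items, range 3-27
* Cognitive function: 4 items, range 4-36

The grand total ranges 13-117.  The published scale names the subscale item
counts but not an item order, so this package fixes a canonical ordering:
items 1-6 are ADL, items 7-9 are BPSD, items 10-13 are cognitive.  Only the
subscale sums enter any downstream analysis, so the ordering is a schema
convention, not a scientific claim.

:class:`ABSeries` holds one outcome followed over time in an AB design
(phase A = baseline, phase B = intervention), with the designed intervention
onset recorded as the index of the first phase-B observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PhaseLengthError, SeriesFormatError, ValidationError

N_ITEMS = 13
ITEM_MIN = 1
ITEM_MAX = 9

# canonical item -> subscale assignment (0-based slices into the 13 items)
ADL_ITEMS = slice(0, 6)
BPSD_ITEMS = slice(6, 9)
COGNITIVE_ITEMS = slice(9, 13)

SUBSCALE_RANGES = {
    "adl": (6, 54),
    "bpsd": (3, 27),
    "cognitive": (4, 36),
    "total": (13, 117),
}

#: minimum number of observations required in each phase for the
#: change-point model to be applicable
MIN_PER_PHASE = 3


def score_record(item_scores: Sequence[int]) -> tuple[int, int, int, int]:
    """Score a 13-item ABC-DS record.

    Parameters
    ----------
    item_scores
        Exactly 13 integers, each in [1, 9], in the canonical item order
        (items 1-6 ADL, 7-9 BPSD, 10-13 cognitive).

    Returns
    -------
    (adl_total, bpsd_total, cognitive_total, grand_total)

    Raises
    ------
    ValidationError
        If the item count is wrong or an item is out of range; the message
        names the offending item index (1-based).
    """
    items = list(item_scores)
    if len(items) != N_ITEMS:
        raise ValidationError(
            f"expected {N_ITEMS} item scores, got {len(items)}"
        )
    for i, v in enumerate(items):
        if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool)):
            raise ValidationError(f"item {i + 1}: score {v!r} is not an integer")
        if not (ITEM_MIN <= v <= ITEM_MAX):
            raise ValidationError(
                f"item {i + 1}: score {v} outside [{ITEM_MIN}, {ITEM_MAX}]"
            )
    adl = int(sum(items[ADL_ITEMS]))
    bpsd = int(sum(items[BPSD_ITEMS]))
    cog = int(sum(items[COGNITIVE_ITEMS]))
    return adl, bpsd, cog, adl + bpsd + cog


@dataclass(frozen=True)
class AbcdsRecord:
    """One ABC-DS assessment occasion: 13 item scores plus derived totals.

    The optional ``rater`` field records who administered the assessment;
    no reliability adjustment is applied (the design assumes a consistent
    rating context).
    """

    item_scores: tuple[int, ...]
    rater: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_scores", tuple(self.item_scores))
        score_record(self.item_scores)  # validates

    @property
    def adl_total(self) -> int:
        return score_record(self.item_scores)[0]

    @property
    def bpsd_total(self) -> int:
        return score_record(self.item_scores)[1]

    @property
    def cognitive_total(self) -> int:
        return score_record(self.item_scores)[2]

    @property
    def total(self) -> int:
        return score_record(self.item_scores)[3]


@dataclass(frozen=True)
class ABSeries:
    """An ordered outcome series from an AB design.

    Attributes
    ----------
    timepoints
        Strictly increasing integer week indices (0-based).
    values
        Outcome scores, one per timepoint (one of: total, ADL, BPSD,
        cognitive, or a single item score).
    intervention_onset
        Position index of the FIRST intervention-phase observation: the
        series splits half-open as ``values[:onset]`` (phase A) vs
        ``values[onset:]`` (phase B).
    label
        Outcome name, e.g. ``"total"``.
    """

    timepoints: np.ndarray
    values: np.ndarray
    intervention_onset: int
    label: str = "score"
    min_per_phase: int = field(default=MIN_PER_PHASE)

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=int)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "values", vals)
        if tp.ndim != 1 or vals.ndim != 1 or len(tp) != len(vals):
            raise ValidationError("timepoints and values must be 1-D and equal length")
        if len(tp) == 0:
            raise ValidationError("empty series")
        if np.any(np.diff(tp) <= 0):
            raise SeriesFormatError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise SeriesFormatError("non-finite outcome value in series")
        onset = int(self.intervention_onset)
        n_a = onset
        n_b = len(vals) - onset
        if n_a < self.min_per_phase or n_b < self.min_per_phase:
            raise PhaseLengthError(
                f"insufficient phase length: {n_a} phase-A and {n_b} phase-B "
                f"observations (need at least {self.min_per_phase} in each phase)"
            )

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def phase_a(self) -> np.ndarray:
        return self.values[: self.intervention_onset]

    @property
    def phase_b(self) -> np.ndarray:
        return self.values[self.intervention_onset:]

    def __eq__(self, other: object) -> bool:  # array fields need custom eq
        if not isinstance(other, ABSeries):
            return NotImplemented
        return (
            np.array_equal(self.timepoints, other.timepoints)
            and np.array_equal(self.values, other.values)
            and self.intervention_onset == other.intervention_onset
            and self.label == other.label
        )


def series_from_records(
    records: Sequence[AbcdsRecord],
    intervention_onset: int,
    outcome: str = "total",
) -> ABSeries:
    """Build an :class:`ABSeries` of one derived score from weekly records."""
    attr = {"total": "total", "adl": "adl_total", "bpsd": "bpsd_total",
            "cognitive": "cognitive_total"}.get(outcome)
    if attr is None:
        raise ValidationError(f"unknown outcome {outcome!r}")
    vals = [getattr(r, attr) for r in records]
    return ABSeries(
        timepoints=np.arange(len(vals)),
        values=np.asarray(vals, dtype=float),
        intervention_onset=intervention_onset,
        label=outcome,
    )


# ---------------------------------------------------------------------------
# CSV IO
#
# Minimal dialect:   week,score
# Extended dialect:  week,adl,bpsd,cog,total   (total must equal adl+bpsd+cog)
# ---------------------------------------------------------------------------

_EXTENDED_COLS = ("adl", "bpsd", "cog", "total")


def read_series_csv(
    path: str | Path,
    onset_index: int,
    outcome_label: str = "score",
    allow_gaps: bool = False,
) -> ABSeries:
    """Read an AB series from CSV.

    The file must have a header with a ``week`` column and either a single
    ``score`` column (minimal dialect) or the extended columns
    ``adl,bpsd,cog,total``; for the extended dialect ``outcome_label``
    selects which column becomes the series and the consistency
    ``total == adl + bpsd + cog`` is enforced.

    Missing weeks are rejected unless ``allow_gaps`` is true (gaps are then
    reported through the strictly-increasing timepoints; they are never
    silently imputed).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many parser types
        raise SeriesFormatError(f"cannot parse {path}: {exc}") from exc
    if "week" not in df.columns:
        raise SeriesFormatError(f"{path}: missing required 'week' column")
    cols = [c for c in df.columns if c != "week"]
    if set(_EXTENDED_COLS).issubset(df.columns):
        if outcome_label == "score":
            outcome_label = "total"
        if outcome_label not in _EXTENDED_COLS:
            raise SeriesFormatError(
                f"{path}: outcome {outcome_label!r} not in extended dialect columns"
            )
        bad = df.index[df["total"] != df["adl"] + df["bpsd"] + df["cog"]]
        if len(bad):
            raise SeriesFormatError(
                f"{path}: row {bad[0]}: total != adl + bpsd + cog"
            )
        value_col = outcome_label
    elif outcome_label in df.columns:
        value_col = outcome_label
    elif len(cols) == 1:
        value_col = cols[0]
    else:
        raise SeriesFormatError(
            f"{path}: cannot identify outcome column among {cols}"
        )
    for col in ("week", value_col):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise SeriesFormatError(f"{path}: unparseable or missing cell at row {row}, column {col!r}")
    weeks = df["week"].to_numpy()
    if not np.issubdtype(weeks.dtype, np.number) or np.any(weeks != weeks.astype(int)):
        raise SeriesFormatError(f"{path}: 'week' column must contain integers")
    weeks = weeks.astype(int)
    if not allow_gaps and len(weeks) and np.any(np.diff(weeks) != 1):
        missing = sorted(set(range(weeks[0], weeks[-1] + 1)) - set(weeks.tolist()))
        raise SeriesFormatError(
            f"{path}: missing weeks {missing} (pass allow_gaps=True to accept)"
        )
    return ABSeries(
        timepoints=weeks,
        values=df[value_col].to_numpy(dtype=float),
        intervention_onset=onset_index,
        label=outcome_label if outcome_label != "score" else value_col,
    )


def write_series_csv(series: ABSeries, path: str | Path) -> None:
    """Write a series in the minimal ``week,score`` CSV dialect.

    The written file round-trips losslessly through :func:`read_series_csv`
    (given the same onset index).
    """
    df = pd.DataFrame({"week": series.timepoints, series.label: series.values})
    df.to_csv(path, index=False)
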