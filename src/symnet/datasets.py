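"""Case-level symptom data: container, scoring and grouping rules, CSV loading.

The instruments modelled here are the 17 DSM-IV PTSD symptom items of the
Davidson Trauma Scale (DTS), each self-rated for severity on a 0-4 Likert
scale, and the Combat Exposure Scale (CES), a 0-41 total score banded into
five named exposure categories.  Diagnostic grouping follows the DSM-IV
criterion structure: *full* PTSD requires criteria A-F, *subthreshold* PTSD
requires A, E, F plus exactly two of the symptom-cluster criteria B, C, D.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 17 DSM-IV symptom items in canonical (table) order.  D2-D4 are absent
#: because they were introduced with DSM-5 and are not part of the DTS item set.
PTSD17_ITEMS: tuple[str, ...] = (
    "B1", "B2", "B3", "B4", "B5",
    "C1", "C2",
    "D1", "D5", "D6", "D7",
    "E1", "E2", "E3", "E4", "E5", "E6",
)

MIN_SCORE, MAX_SCORE = 0, 4


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(ValueError):
    """A requested column, item, or option does not exist."""


@dataclass(frozen=True)
class CESCategory:
    """A named Combat Exposure Scale band with inclusive score bounds."""

    name: str
    lo: int
    hi: int

    def __contains__(self, score: int) -> bool:
        return self.lo <= score <= self.hi


#: The five CES bands; they partition the score range 0..41.
CES_CATEGORIES: tuple[CESCategory, ...] = (
    CESCategory("Light", 0, 8),
    CESCategory("Light-moderate", 9, 16),
    CESCategory("Moderate", 17, 24),
    CESCategory("Moderate-heavy", 25, 32),
    CESCategory("Heavy", 33, 41),
)

CES_MIN, CES_MAX = 0, 41
#: Default CES cut splitting low from high combat exposure.  Scores >= cut are
#: "high": 25 opens the Moderate-heavy band, so band and group edges align.
CES_CUT = 25


@dataclass
class SymptomDataset:
    """A case-by-item matrix of ordinal symptom severities.

    Parameters
    ----------
    items
        Ordered, unique item labels (columns of ``scores``).
    scores
        ``(n_cases, n_items)`` integer matrix with every entry in 0..4.
    group
        Optional per-case categorical label (e.g. ``"full"`` / ``"subthreshold"``).
    covariates
        Optional per-case numeric covariates (age, CES total, ...), one row
        per case, aligned with ``scores``.
    """

    items: tuple[str, ...]
    scores: np.ndarray
    group: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = tuple(str(i) for i in self.items)
        if len(set(self.items)) != len(self.items):
            raise ValidationError("item labels must be unique")
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.items):
            raise ValidationError(
                f"scores must be (n_cases, {len(self.items)}); got {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValidationError("dataset must contain at least one case")
        if not np.issubdtype(self.scores.dtype, np.integer):
            rounded = np.rint(self.scores)
            if not np.allclose(self.scores, rounded, atol=0, rtol=0, equal_nan=False):
                raise ValidationError("scores must be integers")
            self.scores = rounded.astype(np.int64)
        bad = (self.scores < MIN_SCORE) | (self.scores > MAX_SCORE)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"score out of range 0..4 at case {r}, item {self.items[c]!r}: "
                f"{self.scores[r, c]}"
            )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if self.group.shape[0] != self.scores.shape[0]:
                raise ValidationError("group labels must align with cases")
        if self.covariates is not None:
            if len(self.covariates) != self.scores.shape[0]:
                raise ValidationError("covariates must align with cases")
            self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n_cases(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return len(self.items)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SymptomDataset":
        """Dataset restricted to the given case indices (order preserved)."""
        rows = np.asarray(rows)
        return SymptomDataset(
            items=self.items,
            scores=self.scores[rows],
            group=None if self.group is None else self.group[rows],
            covariates=None
            if self.covariates is None
            else self.covariates.iloc[rows].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.items))
        if self.group is not None:
            df["group"] = self.group
        if self.covariates is not None:
            df = pd.concat([df, self.covariates], axis=1)
        return df


def load_dataset(
    path: str | Path,
    item_columns: Sequence[str] = PTSD17_ITEMS,
    group_column: str | None = None,
    covariate_columns: Sequence[str] | None = None,
) -> SymptomDataset:
    """Read a case-by-item CSV into a :class:`SymptomDataset`.

    One row per case; ``item_columns`` must all be present.  Cases with any
    missing item score are dropped (complete-case analysis) and the count of
    dropped cases is logged and recorded in ``meta["n_dropped"]``.

    Raises
    ------
    ConfigurationError
        If a named column is absent from the file.
    ValidationError
        If a score is outside 0..4 (the offending row and column are named).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in item_columns if c not in df.columns]
    if missing:
        raise ConfigurationError(f"columns not found in {path.name}: {missing}")
    if group_column is not None and group_column not in df.columns:
        raise ConfigurationError(f"group column {group_column!r} not found")
    for c in covariate_columns or ():
        if c not in df.columns:
            raise ConfigurationError(f"covariate column {c!r} not found")

    item_df = df[list(item_columns)]
    complete = item_df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d case(s) with missing item scores", n_dropped)
    kept = df.loc[complete].reset_index(drop=True)
    scores = kept[list(item_columns)].to_numpy()
    if not np.allclose(scores, np.rint(scores)):
        raise ValidationError("non-integer score encountered")
    scores = np.rint(scores).astype(np.int64)
    bad = (scores < MIN_SCORE) | (scores > MAX_SCORE)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"score out of range 0..4 at row {r}, column "
            f"{item_columns[c]!r}: {scores[r, c]}"
        )
    return SymptomDataset(
        items=tuple(item_columns),
        scores=scores,
        group=kept[group_column].to_numpy() if group_column else None,
        covariates=kept[list(covariate_columns)] if covariate_columns else None,
        meta={"n_dropped": n_dropped, "source": str(path)},
    )


def dts_total(case_scores: Sequence[int]) -> int:
    """DTS severity total: sum of the 17 item severities (range 0..68)."""
    arr = np.asarray(case_scores)
    if arr.shape != (len(PTSD17_ITEMS),):
        raise ValidationError(
            f"expected {len(PTSD17_ITEMS)} item scores, got shape {arr.shape}"
        )
    if ((arr < MIN_SCORE) | (arr > MAX_SCORE)).any():
        raise ValidationError("item scores must lie in 0..4")
    return int(arr.sum())


def ces_category(score: int) -> CESCategory:
    """Map a CES total (0..41) to its named exposure band."""
    if not (CES_MIN <= score <= CES_MAX):
        raise ValidationError(f"CES score must lie in 0..41, got {score}")
    for cat in CES_CATEGORIES:
        if score in cat:
            return cat
    raise AssertionError("unreachable: CES bands partition 0..41")


def combat_group(score: int, cut: int = CES_CUT) -> str:
    """Dichotomize a CES score into ``"low"`` / ``"high"`` exposure.

    Scores at or above the cut are "high"; with the default cut of 25 this
    places the boundary score in the high group, aligned with the opening of
    the Moderate-heavy band.
    """
    if not (CES_MIN <= score <= CES_MAX):
        raise ValidationError(f"CES score must lie in 0..41, got {score}")
    return "high" if score >= cut else "low"


def subthreshold_status(
    a: bool, b: bool, c: bool, d: bool, e: bool, f: bool
) -> str:
    """Classify DSM-IV criterion flags into full / subthreshold / neither.

    ``full``: all of A-F met.  ``subthreshold``: A, E, F met plus exactly two
    of the symptom-cluster criteria B, C, D.  Anything else: ``neither``.
    """
    flags = [bool(x) for x in (a, b, c, d, e, f)]
    a, b, c, d, e, f = flags
    if all(flags):
        return "full"
    if a and e and f and (b + c + d) == 2:
        return "subthreshold"
    return "neither"
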