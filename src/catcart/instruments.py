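"""Questionnaire instruments: scoring, class bands, and completeness filtering.

The cardiac-rehabilitation needs assessment uses seven patient-reported
outcome questionnaires (QLMI physical and social subscales, HADS anxiety
and depression subscales, PHQ-9, GAD-7, MPSSS).  Each instrument carries a
fixed item count and response scale, a scoring mode (integer sum or mean of
item codes), and ordered score bands that assign respondents to a low /
moderate / high class.  This module encodes those definitions, computes and
classifies scores, and applies the completeness rules used to include or
exclude respondents (a questionnaire with one or more missing item
responses cannot be scored and is excluded).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Band",
    "Instrument",
    "ResponseMatrix",
    "CompletionReport",
    "load_instruments",
    "default_instruments",
    "total_score",
    "classify_score",
    "filter_complete",
]


class CompletenessError(ValueError):
    """Raised when an operation requires a fully answered questionnaire."""


@dataclass(frozen=True)
class Band:
    """One class band on the raw-score scale.

    The interval is ``[lower, upper)`` unless ``upper_closed`` is set; the
    last band of an instrument is always closed at the theoretical maximum.
    ``risk`` carries the clinical wording attached to the band (high scores
    mean symptoms on HADS/PHQ/GAD but protective resource on MPSSS/QLMI).
    """

    label: str
    lower: float
    upper: float
    upper_closed: bool = False
    risk: str = ""


@dataclass(frozen=True)
class Instrument:
    id: str
    n_items: int
    min_code: int
    max_code: int
    scoring_mode: str  # "sum" | "mean"
    bands: tuple[Band, ...]
    construct: str = ""
    risk_direction: str = "symptom"  # "symptom" | "resource"

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError(f"{self.id}: n_items must be >= 1")
        if self.max_code <= self.min_code:
            raise ValueError(f"{self.id}: max_code must exceed min_code")
        if self.scoring_mode not in ("sum", "mean"):
            raise ValueError(f"{self.id}: unknown scoring_mode {self.scoring_mode!r}")
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.id}: band labels must be unique")
        lo, hi = self.score_range
        if not np.isclose(self.bands[0].lower, lo):
            raise ValueError(f"{self.id}: first band must start at {lo}")
        if not np.isclose(self.bands[-1].upper, hi):
            raise ValueError(f"{self.id}: last band must end at {hi}")
        for prev, nxt in zip(self.bands, self.bands[1:]):
            if prev.upper != nxt.lower:
                raise ValueError(f"{self.id}: bands must be contiguous")

    @property
    def n_categories(self) -> int:
        return self.max_code - self.min_code + 1

    @property
    def score_range(self) -> tuple[float, float]:
        """Theoretical (min, max) of the instrument score."""
        if self.scoring_mode == "sum":
            return (self.n_items * self.min_code, self.n_items * self.max_code)
        return (float(self.min_code), float(self.max_code))

    @property
    def item_ids(self) -> list[str]:
        width = len(str(self.n_items))
        return [f"item_{i + 1:0{width}d}" for i in range(self.n_items)]

    @property
    def class_labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def risk_wording(self, label: str) -> str:
        for b in self.bands:
            if b.label == label:
                return b.risk
        raise KeyError(label)

    def band_boundaries_sum_scale(self) -> list[float]:
        """Raw-score boundaries between adjacent bands, on the *sum* scale.

        For integer sum-scored instruments the boundary is the midpoint
        between the highest attainable score of one band and the lowest of
        the next (e.g. 4.5 between a 0-4 band and a 5-7 band).  For
        mean-scored instruments the continuous band edge itself is the
        boundary, rescaled by the item count so it lives on the expected
        total-score scale.
        """
        out = []
        for nxt in self.bands[1:]:
            if self.scoring_mode == "sum":
                out.append(nxt.lower - 0.5)
            else:
                out.append(nxt.lower * self.n_items)
        return out


def _parse_instrument(rec: dict) -> Instrument:
    bands = tuple(
        Band(
            label=str(b["label"]),
            lower=float(b["lower"]),
            upper=float(b["upper"]),
            upper_closed=bool(b.get("upper_closed", False)),
            risk=str(b.get("risk", "")),
        )
        for b in rec["bands"]
    )
    return Instrument(
        id=str(rec["id"]),
        n_items=int(rec["n_items"]),
        min_code=int(rec["min_code"]),
        max_code=int(rec["max_code"]),
        scoring_mode=str(rec["scoring_mode"]),
        bands=bands,
        construct=str(rec.get("construct", "")),
        risk_direction=str(rec.get("risk_direction", "symptom")),
    )


def load_instruments(path: str | Path | None = None) -> dict[str, Instrument]:
    """Load instrument definitions from YAML (packaged defaults if no path)."""
    if path is None:
        src = importlib.resources.files("catcart.data").joinpath("instruments.yaml")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    records = yaml.safe_load(text)
    instruments = {}
    for rec in records:
        inst = _parse_instrument(rec)
        if inst.id in instruments:
            raise ValueError(f"duplicate instrument id {inst.id!r}")
        instruments[inst.id] = inst
    return instruments


_DEFAULTS: dict[str, Instrument] | None = None


def default_instruments() -> dict[str, Instrument]:
    """The seven needs-assessment questionnaires (cached)."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = load_instruments()
    return dict(_DEFAULTS)


@dataclass
class ResponseMatrix:
    """Respondent-by-item integer responses for one instrument.

    ``data`` holds one row per respondent and one column per item; missing
    responses are NaN.  Values are validated against the instrument's code
    range on construction.
    """

    instrument_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    @property
    def respondent_ids(self) -> list:
        return list(self.data.index)

    def validate(self, instrument: Instrument) -> None:
        if list(self.data.columns) != instrument.item_ids:
            raise ValueError(
                f"{self.instrument_id}: columns do not match instrument items"
            )
        vals = self.data.to_numpy()
        observed = vals[~np.isnan(vals)]
        if observed.size and (
            (observed < instrument.min_code).any()
            or (observed > instrument.max_code).any()
            or (observed != np.round(observed)).any()
        ):
            raise ValueError(
                f"{self.instrument_id}: responses outside "
                f"[{instrument.min_code}, {instrument.max_code}]"
            )

    def to_csv(self, path: str | Path, missing_marker: str = "NA") -> None:
        df = self.data.copy()
        df.index.name = "respondent"
        df.to_csv(path, na_rep=missing_marker, float_format="%.0f")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        instrument_id: str,
        missing_marker: str = "NA",
    ) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0, na_values=[missing_marker])
        return cls(instrument_id=instrument_id, data=df)


@dataclass(frozen=True)
class CompletionReport:
    """Counts of fully / not at all / partially answered questionnaires."""

    instrument_id: str
    n_total: int
    n_fully: int
    n_missing: int
    n_insufficient: int

    def __post_init__(self) -> None:
        if self.n_fully + self.n_missing + self.n_insufficient != self.n_total:
            raise ValueError("completion counts must sum to the total")

    @staticmethod
    def _pct(count: int, total: int) -> float:
        if total == 0:
            return 0.0
        raw = Decimal(100 * count) / Decimal(total)
        return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def pct_fully(self) -> float:
        return self._pct(self.n_fully, self.n_total)

    @property
    def pct_missing(self) -> float:
        return self._pct(self.n_missing, self.n_total)

    @property
    def pct_insufficient(self) -> float:
        return self._pct(self.n_insufficient, self.n_total)


def total_score(responses: Sequence[float], instrument: Instrument) -> float:
    """Score one fully answered questionnaire (sum or mean of item codes)."""
    arr = np.asarray(responses, dtype=float)
    if arr.shape != (instrument.n_items,):
        raise ValueError(
            f"expected {instrument.n_items} responses, got {arr.shape}"
        )
    if np.isnan(arr).any():
        raise CompletenessError("cannot score a questionnaire with missing items")
    if (arr < instrument.min_code).any() or (arr > instrument.max_code).any():
        raise ValueError("response code outside the instrument's scale")
    if instrument.scoring_mode == "sum":
        return float(arr.sum())
    return float(arr.mean())


def classify_score(score: float, instrument: Instrument) -> str:
    """Assign a score to its class band (low / moderate / high)."""
    lo, hi = instrument.score_range
    if score < lo - 1e-9 or score > hi + 1e-9:
        raise ValueError(
            f"score {score} outside theoretical range [{lo}, {hi}] of {instrument.id}"
        )
    for band in instrument.bands[:-1]:
        if score < band.upper or (band.upper_closed and score <= band.upper):
            return band.label
    return instrument.bands[-1].label


def filter_complete(
    matrix: ResponseMatrix, instrument: Instrument
) -> tuple[ResponseMatrix, CompletionReport]:
    """Keep fully answered rows; count missing and insufficient ones.

    A respondent with every item absent counts as *missing* (the
    questionnaire was never filled out); one with some but not all items
    absent counts as *insufficiently filled out*.  Only complete rows can
    be scored and are returned.
    """
    matrix.validate(instrument)
    isna = matrix.data.isna()
    n_na = isna.sum(axis=1)
    fully = n_na == 0
    missing = n_na == instrument.n_items
    insufficient = ~fully & ~missing
    report = CompletionReport(
        instrument_id=instrument.id,
        n_total=matrix.n_respondents,
        n_fully=int(fully.sum()),
        n_missing=int(missing.sum()),
        n_insufficient=int(insufficient.sum()),
    )
    complete = ResponseMatrix(
        instrument_id=matrix.instrument_id, data=matrix.data.loc[fully].copy()
    )
    return complete, report
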