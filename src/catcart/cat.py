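"""Simulated computerized adaptive testing with a classification stopping rule.

An administration replays a respondent's recorded answers: everyone gets
the same first item (the one most informative at the population mean,
theta = 0), each later item is the unadministered one with maximal Fisher
information at the current trait estimate, and the trait is re-estimated by
maximum likelihood after every answer.  Testing stops as soon as the 95%
confidence interval theta_hat +/- z * SE falls strictly inside one class's
latent interval — the respondent can then be classified with 95%
confidence — or when the item pool is exhausted, in which case the class
is taken from the full raw score (so a CAT that never stops early agrees
exactly with conventional scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grm import (
    ItemBank,
    ThetaCutoffs,
    TraitEstimate,
    estimate_theta,
    item_information,
)
from .instruments import CompletenessError, Instrument, classify_score, total_score

__all__ = [
    "CATConfig",
    "CATTranscript",
    "select_first_item",
    "select_next_item",
    "check_stopping",
    "administer_cat",
    "cat_length_stats",
]

CONTINUE = "continue"


@dataclass(frozen=True)
class CATConfig:
    confidence: float = 0.95
    max_items: int | None = None  # None: the full instrument length
    stopping_enabled: bool = True
    theta_bounds: tuple[float, float] = (-4.0, 4.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")

    @property
    def z(self) -> float:
        return float(norm.ppf(0.5 + self.confidence / 2.0))


@dataclass
class CATTranscript:
    """One adaptive administration: what was asked, estimated, and decided."""

    instrument_id: str
    respondent_id: object
    items: list[int]  # item indices in administration order
    responses: list[float]
    thetas: list[float]
    ses: list[float]
    stop_reason: str  # "classified" | "exhausted"
    final_class: str

    @property
    def n_administered(self) -> int:
        return len(self.items)

    def __post_init__(self) -> None:
        k = len(self.items)
        if not (len(self.responses) == len(self.thetas) == len(self.ses) == k):
            raise ValueError("transcript trajectories must have equal lengths")
        if len(set(self.items)) != k:
            raise ValueError("an item may not be administered twice")
        if k < 1:
            raise ValueError("at least one item must be administered")


def select_first_item(bank: ItemBank) -> int:
    """The common first item: maximal information at theta = 0."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    infos = [float(item_information(0.0, item)) for item in bank]
    return int(np.argmax(infos))  # argmax takes the lowest index on ties


def select_next_item(theta: float, administered: set[int], bank: ItemBank) -> int:
    """Unadministered item with maximal information at theta (ties: lowest index)."""
    best, best_info = None, -np.inf
    for j, item in enumerate(bank):
        if j in administered:
            continue
        info = float(item_information(theta, item))
        if info > best_info:
            best, best_info = j, info
    if best is None:
        raise ValueError("all items have been administered")
    return best


def check_stopping(
    estimate: TraitEstimate, cutoffs: ThetaCutoffs, config: CATConfig
) -> str:
    """Return a class label if the CI sits strictly inside one latent
    interval, else ``"continue"``.

    A CI endpoint touching a cutoff does not classify: "can be classified
    with 95% confidence" is read conservatively.
    """
    if not np.isfinite(estimate.se):
        return CONTINUE
    lo = estimate.theta - config.z * estimate.se
    hi = estimate.theta + config.z * estimate.se
    edges = [-np.inf, *cutoffs.cutoffs, np.inf]
    for k, label in enumerate(cutoffs.labels):
        if edges[k] < lo and hi < edges[k + 1]:
            return label
    return CONTINUE


def administer_cat(
    responses: np.ndarray,
    bank: ItemBank,
    instrument: Instrument,
    cutoffs: ThetaCutoffs,
    config: CATConfig | None = None,
    respondent_id: object = None,
) -> CATTranscript:
    """Replay one respondent's recorded answers through the adaptive loop."""
    config = config or CATConfig()
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (len(bank),) or np.isnan(responses).any():
        raise CompletenessError(
            "adaptive administration replays a complete response vector"
        )
    max_items = config.max_items or len(bank)
    max_items = min(max_items, len(bank))

    mask = np.zeros(len(bank), dtype=bool)
    order: list[int] = []
    thetas: list[float] = []
    ses: list[float] = []
    final_class: str | None = None
    stop_reason = "exhausted"

    while len(order) < max_items:
        if not order:
            j = select_first_item(bank)
        else:
            j = select_next_item(thetas[-1], set(order), bank)
        order.append(j)
        mask[j] = True
        est = estimate_theta(responses, bank, mask, bounds=config.theta_bounds)
        thetas.append(est.theta)
        ses.append(est.se)
        if config.stopping_enabled:
            decision = check_stopping(est, cutoffs, config)
            if decision != CONTINUE:
                final_class = decision
                stop_reason = "classified"
                break

    if final_class is None:
        # pool exhausted: fall back to conventional full-score classification
        final_class = classify_score(total_score(responses, instrument), instrument)
        stop_reason = "exhausted"

    return CATTranscript(
        instrument_id=instrument.id,
        respondent_id=respondent_id,
        items=order,
        responses=[float(responses[j]) for j in order],
        thetas=thetas,
        ses=ses,
        stop_reason=stop_reason,
        final_class=final_class,
    )


def cat_length_stats(
    transcripts: list[CATTranscript], n_items: int
) -> dict[str, float]:
    """Min/mean/max administered items and the percentage length reduction."""
    if not transcripts:
        raise ValueError("no transcripts")
    ids = {t.instrument_id for t in transcripts}
    if len(ids) != 1:
        raise ValueError(f"transcripts mix instruments: {sorted(ids)}")
    lengths = np.array([t.n_administered for t in transcripts], dtype=float)
    mean = float(lengths.mean())
    return {
        "min_items": float(lengths.min()),
        "mean_items": mean,
        "max_items": float(lengths.max()),
        "pct_decrease": 100.0 * (1.0 - mean / n_items),
    }


def transcripts_to_frame(transcripts: list[CATTranscript]) -> pd.DataFrame:
    """Long-format export: one row per administration step."""
    rows = []
    for t in transcripts:
        for step, (j, r, th, se) in enumerate(
            zip(t.items, t.responses, t.thetas, t.ses), start=1
        ):
            rows.append(
                {
                    "instrument": t.instrument_id,
                    "respondent": t.respondent_id,
                    "step": step,
                    "item_index": j,
                    "response": r,
                    "theta": th,
                    "se": se,
                    "stopped": step == t.n_administered,
                    "stop_reason": t.stop_reason if step == t.n_administered else "",
                    "final_class": t.final_class if step == t.n_administered else "",
                }
            )
    return pd.DataFrame(rows)
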