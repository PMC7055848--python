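"""Samejima's graded response model: probabilities, information, scoring,
and marginal-maximum-likelihood calibration.

The graded response model (GRM) describes ordered polytomous items.  For an
item with K ordered categories, discrimination a and thresholds
b_1 < ... < b_{K-1}, the cumulative probability of responding in category k
or above is a two-parameter logistic

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k))),   P*_0 = 1, P*_K = 0,

and the category probability is the difference of adjacent cumulatives.
Fisher information follows Samejima's form; the trait is estimated by
bounded maximum likelihood and its standard error is 1/sqrt(test
information).  Calibration is marginal maximum likelihood via EM with a
standard-normal population distribution and fixed Gaussian quadrature,
which also fixes the latent metric (mean 0, SD 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .instruments import Instrument

__all__ = [
    "GradedResponseItem",
    "ItemBank",
    "TraitEstimate",
    "ThetaCutoffs",
    "category_probabilities",
    "log_likelihood",
    "item_information",
    "test_information",
    "estimate_theta",
    "calibrate_grm",
    "expected_score",
    "score_cutoffs_to_theta",
]

_PROB_FLOOR = 1e-300
_THETA_BOUNDS = (-4.0, 4.0)


@dataclass(frozen=True)
class GradedResponseItem:
    """One polytomous item: slope ``a`` and ordered thresholds ``b``.

    ``codes`` are the raw response codes aligned to the K categories (e.g.
    0..3); ``recode`` optionally maps raw codes onto category indices when
    calibration had to collapse a never-observed category into a neighbour.
    """

    item_id: str
    a: float
    b: tuple[float, ...]
    codes: tuple[int, ...]
    recode: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"{self.item_id}: discrimination must be positive")
        if len(self.b) != self.n_categories - 1:
            raise ValueError(f"{self.item_id}: need K-1 thresholds")
        if self.n_categories < 2:
            raise ValueError(f"{self.item_id}: need at least 2 categories")
        if any(x >= y for x, y in zip(self.b, self.b[1:])):
            raise ValueError(f"{self.item_id}: thresholds must strictly increase")

    @property
    def n_categories(self) -> int:
        return len(self.codes)

    def category_index(self, code: float) -> int:
        code = int(code)
        if self.recode is not None:
            return self.recode[code]
        return self.codes.index(code)


@dataclass(frozen=True)
class ItemBank:
    instrument_id: str
    items: tuple[GradedResponseItem, ...]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("empty item bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> GradedResponseItem:
        return self.items[i]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "instrument_id": self.instrument_id,
            "items": [
                {
                    "item_id": it.item_id,
                    "a": it.a,
                    "b": list(it.b),
                    "codes": list(it.codes),
                    **(
                        {"recode": {str(k): v for k, v in it.recode.items()}}
                        if it.recode is not None
                        else {}
                    ),
                }
                for it in self.items
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ItemBank":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        items = tuple(
            GradedResponseItem(
                item_id=rec["item_id"],
                a=float(rec["a"]),
                b=tuple(float(x) for x in rec["b"]),
                codes=tuple(int(c) for c in rec["codes"]),
                recode=(
                    {int(k): int(v) for k, v in rec["recode"].items()}
                    if "recode" in rec
                    else None
                ),
            )
            for rec in payload["items"]
        )
        return cls(instrument_id=payload["instrument_id"], items=items)


@dataclass(frozen=True)
class TraitEstimate:
    theta: float
    se: float
    at_boundary: bool = False


@dataclass(frozen=True)
class ThetaCutoffs:
    """Trait values partitioning the latent scale into the class intervals.

    ``cutoffs`` are strictly increasing; ``labels`` has one more entry and
    names the class of each latent interval, lowest trait first.
    """

    instrument_id: str
    cutoffs: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cutoffs) + 1:
            raise ValueError("need one label per latent interval")
        if any(x >= y for x, y in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must strictly increase")

    def classify_theta(self, theta: float) -> str:
        idx = int(np.searchsorted(np.asarray(self.cutoffs), theta, side="right"))
        return self.labels[idx]


def _cumulative(theta: float | np.ndarray, item: GradedResponseItem) -> np.ndarray:
    """P*_k for k = 0..K as an array with leading axis over thresholds."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.b)
    inner = 1.0 / (1.0 + np.exp(-item.a * (theta[..., None] - b)))
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    return np.concatenate([ones, inner, zeros], axis=-1)


def category_probabilities(
    theta: float | np.ndarray, item: GradedResponseItem
) -> np.ndarray:
    """Probability of each of the K categories at trait level theta."""
    cum = _cumulative(theta, item)
    return cum[..., :-1] - cum[..., 1:]


def log_likelihood(
    theta: float,
    responses: Sequence[float],
    bank: ItemBank,
    mask: Sequence[bool] | None = None,
) -> float:
    """Log-likelihood of the administered responses at theta.

    ``mask`` marks administered items (default: all).  Probabilities are
    floored at 1e-300 so extreme patterns stay finite.
    """
    responses = np.asarray(responses, dtype=float)
    if mask is None:
        mask = ~np.isnan(responses)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("log-likelihood requires at least one administered item")
    total = 0.0
    for admin, resp, item in zip(mask, responses, bank):
        if not admin:
            continue
        k = item.category_index(resp)
        p = category_probabilities(theta, item)[k]
        total += float(np.log(max(p, _PROB_FLOOR)))
    return total


def item_information(theta: float | np.ndarray, item: GradedResponseItem) -> np.ndarray:
    """Samejima item information: a^2 sum_k (w_{k-1} - w_k)^2 / P_k,
    with w_k = P*_k (1 - P*_k)."""
    cum = _cumulative(theta, item)
    w = cum * (1.0 - cum)
    probs = cum[..., :-1] - cum[..., 1:]
    num = (w[..., :-1] - w[..., 1:]) ** 2
    safe = np.where(probs > _PROB_FLOOR, probs, np.inf)
    info = item.a**2 * (num / safe).sum(axis=-1)
    return info if info.ndim else float(info)


def test_information(
    theta: float | np.ndarray,
    bank: ItemBank,
    mask: Sequence[bool] | None = None,
) -> np.ndarray:
    if mask is None:
        mask = np.ones(len(bank), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    total = sum(item_information(theta, item) for item, m in zip(bank, mask) if m)
    return total


def estimate_theta(
    responses: Sequence[float],
    bank: ItemBank,
    mask: Sequence[bool] | None = None,
    bounds: tuple[float, float] = _THETA_BOUNDS,
) -> TraitEstimate:
    """Bounded maximum-likelihood trait estimate with SE from test information.

    All-lowest and all-highest response patterns have monotone likelihoods
    whose ML estimate diverges; the estimate is then clamped to the bound
    and flagged.
    """
    responses = np.asarray(responses, dtype=float)
    if mask is None:
        mask = ~np.isnan(responses)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot estimate theta from zero administered items")

    lo, hi = bounds
    cats = [
        item.category_index(r)
        for item, r, m in zip(bank, responses, mask)
        if m
    ]
    items = [item for item, m in zip(bank, mask) if m]
    all_min = all(k == 0 for k in cats)
    all_max = all(k == it.n_categories - 1 for k, it in zip(cats, items))
    if all_min or all_max:
        theta_hat = lo if all_min else hi
        info = float(test_information(theta_hat, bank, mask))
        se = 1.0 / np.sqrt(info) if info > 0 else np.inf
        return TraitEstimate(theta=theta_hat, se=se, at_boundary=True)

    def neg_ll(t: float) -> float:
        return -log_likelihood(t, responses, bank, mask)

    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    theta_hat = float(res.x)
    boundary = theta_hat <= lo + 1e-4 or theta_hat >= hi - 1e-4
    info = float(test_information(theta_hat, bank, mask))
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return TraitEstimate(theta=theta_hat, se=se, at_boundary=boundary)


# ---------------------------------------------------------------------------
# Marginal maximum likelihood calibration (EM over a fixed quadrature grid)
# ---------------------------------------------------------------------------


def _quadrature(n_nodes: int = 61, span: float = 6.0) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.linspace(-span, span, n_nodes)
    weights = norm.pdf(nodes)
    return nodes, weights / weights.sum()


def _item_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Q x K category probabilities at the quadrature nodes."""
    cum = 1.0 / (1.0 + np.exp(-a * (nodes[:, None] - b[None, :])))
    cum = np.hstack([np.ones((len(nodes), 1)), cum, np.zeros((len(nodes), 1))])
    return cum[:, :-1] - cum[:, 1:]


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    # log(a), b_1, log of successive threshold gaps: enforces a>0 and ordering
    gaps = np.diff(b)
    return np.concatenate([[np.log(a)], [b[0]], np.log(gaps)]) if len(b) > 1 else np.array(
        [np.log(a), b[0]]
    )


def _unpack(params: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(params[0]))
    b0 = params[1]
    if len(params) > 2:
        b = b0 + np.concatenate([[0.0], np.cumsum(np.exp(params[2:]))])
    else:
        b = np.array([b0])
    return a, b


@dataclass
class CalibrationResult:
    bank: ItemBank
    log_likelihoods: list[float] = field(default_factory=list)
    n_cycles: int = 0
    converged: bool = False
    collapsed_categories: dict[str, list[int]] = field(default_factory=dict)


def _marginal_loglik(
    resp_cat: np.ndarray, prob_tables: list[np.ndarray], weights: np.ndarray
) -> float:
    n, _ = resp_cat.shape
    q = len(weights)
    log_l = np.zeros((n, q))
    for j, table in enumerate(prob_tables):
        log_l += np.log(np.maximum(table[:, resp_cat[:, j]].T, _PROB_FLOOR))
    m = log_l.max(axis=1, keepdims=True)
    return float((m.ravel() + np.log(np.exp(log_l - m) @ weights)).sum())


def calibrate_grm(
    matrix_values: np.ndarray,
    instrument: Instrument,
    n_nodes: int = 61,
    span: float = 6.0,
    max_cycles: int = 500,
    tol: float = 1e-4,
    min_respondents: int = 200,
) -> CalibrationResult:
    """Fit a GRM to a complete response matrix by EM.

    The population distribution of the trait is fixed at standard normal
    (fixing the latent metric) and approximated by ``n_nodes`` equally
    spaced quadrature nodes on [-span, span] with renormalised normal
    weights.  The E-step computes each respondent's posterior over the
    nodes; the M-step improves each item's parameters by bounded
    quasi-Newton steps on an order-preserving reparameterisation (log
    slope, first threshold, log threshold gaps), warm-started from the
    previous cycle, so the marginal likelihood never decreases.  Cycles
    stop when no parameter moves more than ``tol`` or ``max_cycles`` is
    reached.  A response category never observed in the data is collapsed
    into its lower neighbour (upper for the lowest category) and the
    recoding is recorded on the fitted item.
    """
    values = np.asarray(matrix_values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("calibration requires a complete response matrix")
    n, n_items = values.shape
    if n_items != instrument.n_items:
        raise ValueError("matrix width does not match the instrument")
    if n < min_respondents:
        raise ValueError(
            f"calibration needs at least {min_respondents} respondents, got {n}"
        )

    codes_full = list(range(instrument.min_code, instrument.max_code + 1))
    nodes, weights = _quadrature(n_nodes, span)

    # Map raw codes to per-item category indices, collapsing unobserved ones.
    resp_cat = np.zeros((n, n_items), dtype=int)
    item_codes: list[list[int]] = []
    recodes: list[dict[int, int] | None] = []
    collapsed: dict[str, list[int]] = {}
    item_ids = instrument.item_ids
    for j in range(n_items):
        observed = set(int(v) for v in values[:, j])
        kept = [c for c in codes_full if c in observed]
        if len(kept) < 2:
            raise ValueError(f"item {item_ids[j]} has fewer than 2 observed categories")
        recode: dict[int, int] = {}
        for c in codes_full:
            # collapse an unobserved code into the nearest kept code below,
            # or the lowest kept code if none is below
            below = [k for k in kept if k <= c]
            target = below[-1] if below else kept[0]
            recode[c] = kept.index(target)
        if len(kept) < len(codes_full):
            collapsed[item_ids[j]] = [c for c in codes_full if c not in observed]
            recodes.append(recode)
        else:
            recodes.append(None)
        item_codes.append(kept)
        resp_cat[:, j] = [recode[int(v)] for v in values[:, j]]

    # Starting values: slope 1, thresholds at normal quantiles of the
    # observed cumulative category frequencies.
    params: list[np.ndarray] = []
    for j in range(n_items):
        k = len(item_codes[j])
        counts = np.bincount(resp_cat[:, j], minlength=k).astype(float)
        cum_above = 1.0 - np.cumsum(counts)[:-1] / counts.sum()
        cum_above = np.clip(cum_above, 0.02, 0.98)
        b0 = norm.ppf(1.0 - cum_above)
        b0 = np.maximum.accumulate(b0)
        for i in range(1, len(b0)):  # break exact ties
            if b0[i] <= b0[i - 1]:
                b0[i] = b0[i - 1] + 0.05
        params.append(_pack(1.0, b0))

    prob_tables = [
        _item_prob_table(*_unpack(p), nodes) for p in params
    ]

    lls: list[float] = [_marginal_loglik(resp_cat, prob_tables, weights)]
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        # E-step: posterior over nodes per respondent
        log_l = np.zeros((n, len(nodes)))
        for j, table in enumerate(prob_tables):
            log_l += np.log(np.maximum(table[:, resp_cat[:, j]].T, _PROB_FLOOR))
        log_post = log_l + np.log(weights)
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)

        # Expected counts r[q, k] per item
        max_change = 0.0
        for j in range(n_items):
            k = len(item_codes[j])
            r = np.zeros((len(nodes), k))
            for c in range(k):
                sel = resp_cat[:, j] == c
                if sel.any():
                    r[:, c] = post[sel].sum(axis=0)

            def neg_q(p: np.ndarray, r=r) -> float:
                a, b = _unpack(p)
                table = _item_prob_table(a, b, nodes)
                return -float((r * np.log(np.maximum(table, _PROB_FLOOR))).sum())

            res = minimize(
                neg_q,
                params[j],
                method="L-BFGS-B",
                options={"maxiter": 15, "ftol": 1e-10},
            )
            # generalized EM: accept only improvements of the item objective
            if res.fun <= neg_q(params[j]):
                max_change = max(max_change, float(np.abs(res.x - params[j]).max()))
                params[j] = res.x
                prob_tables[j] = _item_prob_table(*_unpack(res.x), nodes)

        lls.append(_marginal_loglik(resp_cat, prob_tables, weights))
        if max_change < tol:
            converged = True
            break

    items = []
    for j in range(n_items):
        a, b = _unpack(params[j])
        items.append(
            GradedResponseItem(
                item_id=item_ids[j],
                a=a,
                b=tuple(b),
                codes=tuple(item_codes[j]),
                recode=(
                    {c: recodes[j][c] for c in codes_full}
                    if recodes[j] is not None
                    else None
                ),
            )
        )
    bank = ItemBank(instrument_id=instrument.id, items=tuple(items))
    return CalibrationResult(
        bank=bank,
        log_likelihoods=lls,
        n_cycles=cycle,
        converged=converged,
        collapsed_categories=collapsed,
    )


# ---------------------------------------------------------------------------
# Test characteristic curve and raw-score cutoff mapping
# ---------------------------------------------------------------------------


def expected_score(theta: float | np.ndarray, bank: ItemBank) -> np.ndarray:
    """Test characteristic curve: expected raw sum score at theta."""
    theta = np.asarray(theta, dtype=float)
    total = np.zeros(theta.shape)
    for item in bank:
        probs = category_probabilities(theta, item)
        total += probs @ np.asarray(item.codes, dtype=float)
    return total if total.ndim else float(total)


def score_cutoffs_to_theta(
    bank: ItemBank,
    instrument: Instrument,
    span: float = 12.0,
    tol: float = 1e-8,
) -> ThetaCutoffs:
    """Invert the test characteristic curve at the raw-score band boundaries.

    The curve T(theta) is strictly increasing, so each boundary raw score
    (midpoint between adjacent integer bands, or the continuous band edge
    rescaled to the sum scale) maps to a unique trait cutoff found by
    bisection to residual < ``tol``.
    """
    boundaries = instrument.band_boundaries_sum_scale()
    min_sum = sum(min(it.codes) for it in bank)
    max_sum = sum(max(it.codes) for it in bank)
    cutoffs = []
    for r in boundaries:
        if not (min_sum < r < max_sum):
            raise ValueError(
                f"boundary raw score {r} outside attainable range "
                f"({min_sum}, {max_sum}) for {instrument.id}"
            )
        lo, hi = -span, span
        if expected_score(lo, bank) > r or expected_score(hi, bank) < r:
            raise ValueError(f"boundary {r} not bracketed on [-{span}, {span}]")
        while hi - lo > 1e-13:
            mid = 0.5 * (lo + hi)
            if expected_score(mid, bank) < r:
                lo = mid
            else:
                hi = mid
            if abs(expected_score(0.5 * (lo + hi), bank) - r) < tol:
                break
        cutoffs.append(0.5 * (lo + hi))
    return ThetaCutoffs(
        instrument_id=instrument.id,
        cutoffs=tuple(cutoffs),
        labels=tuple(instrument.class_labels),
    )
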