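"""Synthetic cardiac-rehabilitation cohorts for end-to-end testing.

The study population this emulates is a multi-clinic cardiac-rehabilitation
intake cohort: each patient carries latent trait levels on the constructs
the questionnaires measure (anxiety, depression, physical and social
quality of life, social support), answers each instrument's items according
to a graded response model, and may skip a whole questionnaire or single
items.  Demographics (age, gender, five-level cardiac diagnosis category)
are generated with the marginals of such a cohort and, by default,
independently of the traits — which makes "demographic predictors never
enter the trees" a testable property downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GradedResponseItem, ItemBank, category_probabilities
from .instruments import Instrument, ResponseMatrix, default_instruments

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "generate_item_bank",
    "simulate_responses",
    "inject_missingness",
    "generate_demographics",
    "generate_cohort",
]

# Cohort demographic marginals: ~70% male, age ~ N(66.6, 11.1) truncated to
# adults, and a five-level diagnosis/intervention mix (acute coronary
# syndrome with intervention, chronic diagnosis, elective PCI, elective
# CABG, ACS without intervention).
P_MALE = 0.70
AGE_MEAN, AGE_SD = 66.6, 11.1
AGE_RANGE = (18.0, 100.0)
DIAGNOSIS_LEVELS = (
    "ACS_with_intervention",
    "chronic_diagnosis",
    "elective_PCI",
    "elective_CABG",
    "ACS_without_intervention",
)
DIAGNOSIS_PROPS = (0.2929, 0.2284, 0.2129, 0.1424, 0.1233)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator.

    ``discrimination_range`` bounds the uniform draw of item slopes;
    ``threshold_dispersion`` is the SD of the normal draw of item
    thresholds.  ``p_missing_questionnaire`` drops whole questionnaires,
    ``p_missing_item`` single items.  The seed is recorded in every
    generated artifact.
    """

    n_respondents: int = 2000
    discrimination_range: tuple[float, float] = (1.0, 2.5)
    threshold_dispersion: float = 1.2
    p_missing_questionnaire: float = 0.0
    p_missing_item: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.discrimination_range
        if lo <= 0 or hi < lo:
            raise ValueError("discrimination range must be positive and ordered")
        for p in (self.p_missing_questionnaire, self.p_missing_item):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missingness probabilities must lie in [0, 1]")
        if self.threshold_dispersion <= 0:
            raise ValueError("threshold dispersion must be positive")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")


@dataclass
class SimulatedCohort:
    """A generated cohort: true traits, responses per instrument, demographics."""

    config: SimulationConfig
    traits: pd.DataFrame  # respondents x constructs
    responses: dict[str, ResponseMatrix]
    banks: dict[str, ItemBank]
    demographics: pd.DataFrame

    def write(self, out_dir: str | Path, missing_marker: str = "NA") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for inst_id, matrix in self.responses.items():
            matrix.to_csv(out / f"responses_{inst_id}.csv", missing_marker)
        self.demographics.to_csv(out / "demographics.csv")
        for inst_id, bank in self.banks.items():
            bank.to_json(out / f"bank_{inst_id}.json")
        sidecar = {
            "config": asdict(self.config),
            "true_traits": {
                c: self.traits[c].round(6).tolist() for c in self.traits.columns
            },
        }
        (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))


def _spawn(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def generate_item_bank(
    instrument: Instrument,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> ItemBank:
    """Draw a GRM item bank matching the instrument's scale.

    Slopes are uniform on the configured range; the K-1 thresholds per item
    are sorted normal draws (SD = threshold dispersion) separated by at
    least 0.05 so the ordering is strict and items stay informative across
    the trait range.
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    if instrument.n_categories < 2:
        raise ValueError("instrument must have at least two response categories")
    rng = np.random.default_rng(seed)
    lo, hi = config.discrimination_range
    items = []
    codes = tuple(range(instrument.min_code, instrument.max_code + 1))
    for item_id in instrument.item_ids:
        a = float(rng.uniform(lo, hi))
        b = np.sort(rng.normal(0.0, config.threshold_dispersion, instrument.n_categories - 1))
        for i in range(1, len(b)):
            if b[i] - b[i - 1] < 0.05:
                b[i] = b[i - 1] + 0.05
        items.append(GradedResponseItem(item_id=item_id, a=a, b=tuple(b), codes=codes))
    return ItemBank(instrument_id=instrument.id, items=tuple(items))


def simulate_responses(
    bank: ItemBank,
    thetas: np.ndarray,
    seed: int,
    respondent_ids: list | None = None,
) -> ResponseMatrix:
    """Sample one response per respondent per item from the GRM."""
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0 or len(bank) == 0:
        raise ValueError("need at least one respondent and one item")
    rng = np.random.default_rng(seed)
    n = len(thetas)
    data = np.empty((n, len(bank)), dtype=float)
    u = rng.random((n, len(bank)))
    for j, item in enumerate(bank):
        probs = category_probabilities(thetas, item)  # n x K
        cum = np.cumsum(probs, axis=1)
        idx = (u[:, j : j + 1] > cum).sum(axis=1)
        idx = np.clip(idx, 0, item.n_categories - 1)
        data[:, j] = np.asarray(item.codes)[idx]
    if respondent_ids is None:
        respondent_ids = list(range(n))
    df = pd.DataFrame(data, index=respondent_ids, columns=[it.item_id for it in bank])
    return ResponseMatrix(instrument_id=bank.instrument_id, data=df)


def inject_missingness(
    matrix: ResponseMatrix,
    p_questionnaire: float,
    p_item: float,
    seed: int,
) -> ResponseMatrix:
    """Blank out whole questionnaires and single items at the given rates.

    A row becomes entirely missing with probability ``p_questionnaire``
    (the patient never filled out the questionnaire); otherwise each cell
    is independently blanked with probability ``p_item``.
    """
    for p in (p_questionnaire, p_item):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    n, m = data.shape
    whole = rng.random(n) < p_questionnaire
    cells = rng.random((n, m)) < p_item
    cells[whole, :] = True
    values = data.to_numpy()
    values[cells] = np.nan
    return ResponseMatrix(
        instrument_id=matrix.instrument_id,
        data=pd.DataFrame(values, index=data.index, columns=data.columns),
    )


def generate_demographics(
    n: int,
    seed: int,
    p_male: float = P_MALE,
    diagnosis_props: tuple[float, ...] = DIAGNOSIS_PROPS,
) -> pd.DataFrame:
    """Age, gender, and diagnosis category, independent of the traits."""
    rng = np.random.default_rng(seed)
    props = np.asarray(diagnosis_props, dtype=float)
    props = props / props.sum()
    gender = np.where(rng.random(n) < p_male, "male", "female")
    lo, hi = AGE_RANGE
    age = rng.normal(AGE_MEAN, AGE_SD, size=n)
    while True:  # truncate by redrawing out-of-range ages
        bad = (age < lo) | (age > hi)
        if not bad.any():
            break
        age[bad] = rng.normal(AGE_MEAN, AGE_SD, size=int(bad.sum()))
    diagnosis = rng.choice(np.array(DIAGNOSIS_LEVELS), size=n, p=props)
    return pd.DataFrame(
        {"age": np.round(age, 1), "gender": gender, "diagnosis": diagnosis},
        index=list(range(n)),
    )


def generate_cohort(
    config: SimulationConfig | None = None,
    instruments: dict[str, Instrument] | None = None,
) -> SimulatedCohort:
    """Generate a full cohort: traits, banks, responses, demographics.

    Constructs get independent standard-normal traits; instruments sharing
    a construct (e.g. the two anxiety questionnaires) share the trait.
    All randomness descends from ``config.seed`` via named spawn keys, so
    regeneration is bit-identical.
    """
    config = config or SimulationConfig()
    instruments = instruments or default_instruments()
    n = config.n_respondents

    constructs = sorted({inst.construct or inst.id for inst in instruments.values()})
    trait_rng = _spawn(config.seed, 0)
    traits = pd.DataFrame(
        {c: trait_rng.normal(0.0, 1.0, n) for c in constructs},
        index=list(range(n)),
    )

    responses: dict[str, ResponseMatrix] = {}
    banks: dict[str, ItemBank] = {}
    for k, (inst_id, inst) in enumerate(sorted(instruments.items())):
        bank_seed = int(_spawn(config.seed, 1 + 3 * k).integers(2**31))
        resp_seed = int(_spawn(config.seed, 2 + 3 * k).integers(2**31))
        miss_seed = int(_spawn(config.seed, 3 + 3 * k).integers(2**31))
        bank = generate_item_bank(inst, config, seed=bank_seed)
        theta = traits[inst.construct or inst_id].to_numpy()
        matrix = simulate_responses(bank, theta, seed=resp_seed,
                                    respondent_ids=list(range(n)))
        if config.p_missing_questionnaire > 0 or config.p_missing_item > 0:
            matrix = inject_missingness(
                matrix,
                config.p_missing_questionnaire,
                config.p_missing_item,
                seed=miss_seed,
            )
        banks[inst_id] = bank
        responses[inst_id] = matrix

    demo_seed = int(_spawn(config.seed, 1000).integers(2**31))
    demographics = generate_demographics(n, seed=demo_seed)
    return SimulatedCohort(
        config=config,
        traits=traits,
        responses=responses,
        banks=banks,
        demographics=demographics,
    )
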