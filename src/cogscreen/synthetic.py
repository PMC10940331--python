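"""Synthetic cohort generator.

Emulates the statistical structure of the 86-patient screening cohort
so every pipeline stage is testable without any clinical data:

* impairment prevalence 22% (label drawn first, Bernoulli);
* general ability deficit in the impaired group (default 1 SD), with
  the marginal ability mean kept at 0;
* item responses from the higher-order 2PL generative model over the
  five instruments' item counts (30/12/50/30/144);
* ages 67-93 drawn from the empirical age distribution of the
  reference cohort through a Gaussian copula, with a configurable
  age-impairment association (default correlation 0.27);
* total response times lognormal, moment-matched to the reference
  response-time table (ARW 47.421/11.619 s, DCCS 36.049/14.909 s,
  PSM 73/34 s);
* monotone missingness for MFS and NSM: per-item missing probability
  non-decreasing in item position (fatigue / stopping rules; NSM's
  90-second limit leaves most late items unattempted);
* demographics drawn from the reference frequency table (including the
  special codes "D" and "777").

The label-first scheme (draw impairment, then shift ability) keeps
prevalence and effect size independently controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composites import apply_composite, assemble_scores, load_composite_fixtures
from .hoirt import (
    HigherOrderIRT,
    HOIRTConfig,
    HigherOrderStructure,
    ItemParameters,
    irf_2pl,
)
from .instruments import INSTRUMENTS, PatientRecord

__all__ = [
    "CohortSimConfig",
    "generate_default_item_bank",
    "generate_cohort",
    "make_benchmark_fixture",
    "encode_demographics",
    "TABLE_RT_MOMENTS",
]

#: Reference response-time moments (mean, SD) in seconds.
TABLE_RT_MOMENTS: dict[str, tuple[float, float]] = {
    "ARW": (47.421, 11.619),
    "DCCS": (36.049, 14.909),
    "PSM": (73.0, 34.0),
}

#: Reference demographic frequencies (category -> count out of 86).
_GENDER_FREQ = {"F": 60, "M": 26}
_RACE_FREQ = {"A": 4, "B": 11, "U": 1, "W": 70}
_INCOME_FREQ = {"2": 2, "3": 3, "4": 3, "5": 8, "6": 10, "7": 12, "8": 21, "9": 26, "D": 1}
_EDUCATION_FREQ = {"4": 5, "6": 10, "7": 3, "8": 23, "9": 32, "10": 5, "11": 6, "777": 2}

#: Empirical age counts of the reference cohort (67-93 years).
_AGE_FREQ = {
    67: 4, 68: 6, 69: 4, 70: 8, 71: 5, 72: 5, 73: 2, 74: 6, 75: 9, 76: 4,
    77: 5, 78: 8, 79: 4, 80: 4, 81: 4, 83: 5, 84: 3, 85: 1, 86: 2, 87: 1,
    88: 1, 90: 2, 93: 1,
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the generator.

    ``ability_gap`` is the mean deficit of general ability in the
    impaired group, in SD units.  ``age_impairment_corr`` is the
    Gaussian-copula correlation between the age quantile and the
    impairment propensity.  ``missing_ramp_max`` gives the missing
    probability at the last item of each missing-allowed instrument
    (the ramp rises linearly from 0 at the first item).
    """

    n: int = 86
    prevalence: float = 0.22
    ability_gap: float = 1.0
    age_impairment_corr: float = 0.27
    rt_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE_RT_MOMENTS)
    )
    missing_ramp_max: dict[str, float] = field(
        default_factory=lambda: {"MFS": 0.5, "NSM": 0.9}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.ability_gap < 0:
            raise ValueError("ability_gap must be >= 0")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match (mu, sigma) of a lognormal to a target mean/SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_default_item_bank(
    seed: int = 0, instruments: tuple[str, ...] | None = None
) -> tuple[list[ItemParameters], HigherOrderStructure]:
    """Random item bank over the battery plus a higher-order structure.

    a ~ LogNormal(0, 0.5), b ~ Normal(0, 1), loadings uniform in
    [0.5, 0.9].  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    instruments = tuple(INSTRUMENTS) if instruments is None else instruments
    items: list[ItemParameters] = []
    for d, name in enumerate(instruments):
        spec = INSTRUMENTS[name]
        a = rng.lognormal(mean=0.0, sigma=0.5, size=spec.n_items)
        b = rng.normal(0.0, 1.0, size=spec.n_items)
        items.extend(ItemParameters(float(ai), float(bi), d) for ai, bi in zip(a, b))
    lambdas = tuple(float(x) for x in rng.uniform(0.5, 0.9, size=len(instruments)))
    return items, HigherOrderStructure(lambdas)


def _sample_categorical(rng: np.random.Generator, freq: dict, size: int) -> np.ndarray:
    cats = np.array(list(freq.keys()), dtype=object)
    p = np.array(list(freq.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=size, p=p)


def _age_quantile(u: np.ndarray) -> np.ndarray:
    """Map uniform quantiles onto the empirical age distribution."""
    ages = np.array(sorted(_AGE_FREQ))
    cum = np.cumsum([_AGE_FREQ[a] for a in ages], dtype=float)
    cum /= cum[-1]
    return ages[np.searchsorted(cum, u, side="left").clip(0, len(ages) - 1)]


def generate_cohort(
    config: CohortSimConfig,
    bank: list[ItemParameters] | None = None,
    structure: HigherOrderStructure | None = None,
    instruments: tuple[str, ...] | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort plus its true latent abilities.

    Returns ``(records, truth)`` where ``truth`` holds the impairment
    label, the general and per-domain abilities, and age per patient.
    """
    instruments = tuple(INSTRUMENTS) if instruments is None else instruments
    if bank is None or structure is None:
        bank, structure = generate_default_item_bank(config.seed, instruments)
    rng = np.random.default_rng(config.seed)
    n = config.n

    # Gaussian copula between age quantile and impairment propensity
    rho = config.age_impairment_corr
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    impaired = (stats.norm.cdf(z[:, 0]) > 1.0 - config.prevalence).astype(int)
    ages = _age_quantile(stats.norm.cdf(z[:, 1]))

    # label-first ability shift; offset keeps the marginal mean at 0
    offset = config.ability_gap * config.prevalence
    mean_g = offset - config.ability_gap * impaired
    theta_g = mean_g + rng.standard_normal(n)
    lam = np.asarray(structure.lambdas)
    theta_d = (
        lam[None, :] * theta_g[:, None]
        + structure.residual_sd[None, :] * rng.standard_normal((n, lam.shape[0]))
    )

    a = np.array([it.a for it in bank])
    b = np.array([it.b for it in bank])
    dom = np.array([it.domain for it in bank])
    p = irf_2pl(a[None, :], b[None, :], theta_d[:, dom])
    R = (rng.random((n, len(bank))) < p).astype(float)

    # monotone missingness ramps for the missing-allowed instruments
    for d, name in enumerate(instruments):
        ramp_max = config.missing_ramp_max.get(name)
        if not ramp_max:
            continue
        cols = np.flatnonzero(dom == d)
        k = cols.size
        ramp = ramp_max * np.arange(k) / max(k - 1, 1)
        miss = rng.random((n, k)) < ramp[None, :]
        # keep at least the first item observed for every patient
        miss[:, 0] = False
        block = R[:, cols]
        block[miss] = np.nan
        R[:, cols] = block

    gender = _sample_categorical(rng, _GENDER_FREQ, n)
    race = _sample_categorical(rng, _RACE_FREQ, n)
    income = _sample_categorical(rng, _INCOME_FREQ, n)
    education = _sample_categorical(rng, _EDUCATION_FREQ, n)

    rts = {}
    for name, (mean, sd) in config.rt_lognormal.items():
        mu, sigma = _lognormal_params(mean, sd)
        rts[name] = rng.lognormal(mu, sigma, size=n)

    records = []
    for i in range(n):
        responses = {}
        for d, name in enumerate(instruments):
            responses[name] = R[i, dom == d]
        rec = PatientRecord(
            patient_id=f"sim{i:04d}",
            impaired=int(impaired[i]),
            age=int(ages[i]),
            gender=str(gender[i]),
            race=str(race[i]),
            income=str(income[i]),
            education=str(education[i]),
            responses=responses,
            rt_total={name: float(rts[name][i]) for name in rts},
        ).validate()
        records.append(rec)
    truth = pd.DataFrame(
        {
            "impaired": impaired,
            "age": ages.astype(int),
            "theta_g": theta_g,
            **{f"theta_{name.lower()}": theta_d[:, d] for d, name in enumerate(instruments)},
        }
    )
    return records, truth


#: Integer codes for categorical demographics (reference scaling).
_GENDER_CODE = {"F": 0, "M": 1}
_RACE_CODE = {"A": 0, "B": 1, "U": 2, "W": 3}
_INCOME_CODE = {"2": 0, "3": 1, "4": 2, "5": 3, "6": 4, "7": 5, "8": 6, "9": 7, "D": 8}


def encode_demographics(records: list[PatientRecord]) -> pd.DataFrame:
    """Integer-code demographics following the reference scaling.

    Education's printed codes are already numeric-like; the special
    code 777 is kept as the literal value 777 (an opaque category, not
    a quantity) so it remains a distinct value for tree-based models.
    """
    return pd.DataFrame(
        {
            "gender": [_GENDER_CODE[r.gender] for r in records],
            "race": [_RACE_CODE[r.race] for r in records],
            "income": [_INCOME_CODE[r.income] for r in records],
            "education": [int(r.education) for r in records],
        }
    )


def make_benchmark_fixture(
    config: CohortSimConfig,
    instruments_2d: tuple[str, ...] = ("DCCS", "PSM"),
    chain: dict | None = None,
) -> dict:
    """End-to-end synthetic benchmark inputs.

    Generates a cohort, fits the two- and five-dimensional IRT models
    (short chains by default), assembles the score bundle, applies the
    packaged composite fixtures (except the RT-unit-flagged
    Composite2, replaced by a refit on the synthetic scores), and
    builds every feature-space matrix.

    Returns a dict with keys ``records, truth, scores, features``
    (``features`` maps F1..F16 to DataFrames).
    """
    from .bench import FEATURE_SPACES, build_feature_matrix
    from .composites import fit_composite

    chain = {"n_iter": 1200, "n_burn": 400} if chain is None else chain
    records, truth = generate_cohort(config)

    model2 = HigherOrderIRT.from_cohort(records, instruments_2d)
    res2 = model2.fit(HOIRTConfig(domains=instruments_2d, seed=config.seed, **chain))
    model5 = HigherOrderIRT.from_cohort(records, tuple(INSTRUMENTS))
    res5 = model5.fit(HOIRTConfig(domains=tuple(INSTRUMENTS), seed=config.seed, **chain))

    scores = assemble_scores(records, pd.concat([res2.scores(), res5.scores()], axis=1))
    scores = pd.concat([scores, encode_demographics(records).reset_index(drop=True)], axis=1)

    fixtures = load_composite_fixtures()
    for name, model in fixtures.items():
        if model.rt_unit_warning:
            # refit on synthetic second-scale inputs instead of applying
            # the sub-second-unit reference coefficients
            feats = scores[model.feature_names]
            refit = fit_composite(feats, scores["impaired"].to_numpy(), name=name)
            scores[name] = apply_composite(refit, scores)
        else:
            scores[name] = apply_composite(model, scores)

    features = {name: build_feature_matrix(scores, space) for name, space in FEATURE_SPACES.items()}
    return {"records": records, "truth": truth, "scores": scores, "features": features}
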