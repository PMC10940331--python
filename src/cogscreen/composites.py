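"""Classical instrument scores and composite risk scores.

A composite score is built in two steps: ordinary least squares of the
0/1 impairment label on a small set of score features,

    f(x) = beta_0 + sum_k beta_k x_k,

followed by a logistic transform P = exp(f) / (1 + exp(f)).  Note this
is deliberately OLS-then-sigmoid, not logistic regression: the
reference coefficient table and the printed composite values are only
mutually consistent under that construction.

Five reference composites ship as a packaged coefficient fixture:

* Composite1 — classical scores of all five instruments (accuracy
  rates, correct/second, for DCCS and ARW; number-correct for the rest)
* Composite2 — five-dimensional IRT scores plus three response times
  (its RT coefficients are on a finer time unit than seconds; see
  ``rt_unit_warning``)
* Composite3 — two-dimensional IRT scores {SSHO2D, psm2D, dccs2D} + age
* Composite4 — {SSHO2D, psm2D, dccs2D}
* Composite5 — {PSM number-correct, DCCS accuracy rate, age}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .instruments import INSTRUMENTS, RT_INSTRUMENTS, PatientRecord

__all__ = [
    "CompositeModel",
    "CompositeRegression",
    "CompositeResults",
    "classical_scores",
    "assemble_scores",
    "fit_composite",
    "apply_composite",
    "load_composite_fixtures",
]

#: Instruments scored as number-correct / total RT (1/seconds).
RATE_INSTRUMENTS = ("DCCS", "ARW")

#: Canonical feature lists of the five reference composites.
_FIXTURE_FEATURES: dict[str, list[tuple[str, str]]] = {
    # composite -> [(fixture row name, score-bundle column)]
    "Composite1": [("arw", "arw_rate"), ("psm", "psm"), ("nsm", "nsm"), ("dccs", "dccs_rate"), ("mfs", "mfs")],
    "Composite2": [
        ("SSHO", "SSHO"), ("arw", "arw5D"), ("psm", "psm5D"), ("nsm", "nsm5D"),
        ("dccs", "dccs5D"), ("mfs", "mfs5D"), ("arw_rt", "arw_rt"),
        ("dccs_rt", "dccs_rt"), ("psm_rt", "psm_rt"),
    ],
    "Composite3": [("SSHO", "SSHO2D"), ("psm", "psm2D"), ("dccs", "dccs2D"), ("age", "age")],
    "Composite4": [("SSHO", "SSHO2D"), ("psm", "psm2D"), ("dccs", "dccs2D")],
    "Composite5": [("psm", "psm"), ("dccs", "dccs_rate"), ("age", "age")],
}


@dataclass
class CompositeModel:
    """Intercept + coefficients + logistic link over named features."""

    name: str
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    rt_unit_warning: bool = False

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != self.coefficients.shape[0]:
            raise ValueError(
                f"{self.name}: {len(self.feature_names)} features but "
                f"{self.coefficients.shape[0]} coefficients"
            )

    def linear_predictor(self, scores: pd.DataFrame) -> pd.Series:
        for feat in self.feature_names:
            if feat not in scores.columns:
                raise ValueError(f"{self.name}: score bundle is missing feature {feat!r}")
        X = scores[self.feature_names].to_numpy(dtype=float)
        return pd.Series(self.intercept + X @ self.coefficients, index=scores.index, name=self.name)


def classical_scores(records: list[PatientRecord]) -> pd.DataFrame:
    """Classical per-instrument scores for a cohort.

    Columns: number-correct per instrument (lowercase code), accuracy
    rates ``dccs_rate``/``arw_rate``/``psm_rate`` (correct per second)
    where the RT is present, RT totals, age, the impairment label, and
    per-instrument observed-item counts (``<code>_observed``) so an
    all-missing vector is distinguishable from an all-wrong one.
    """
    rows = []
    for rec in records:
        row: dict[str, float] = {"age": rec.age, "impaired": rec.impaired}
        for name in INSTRUMENTS:
            row[name.lower()] = rec.number_correct(name)
            row[f"{name.lower()}_observed"] = rec.n_observed(name)
        for name in RT_INSTRUMENTS:
            if name in rec.rt_total:
                rt = rec.rt_total[name]
                if rt <= 0:
                    raise ValueError(f"patient {rec.patient_id}: non-positive rt_total for {name}")
                row[f"{name.lower()}_rt"] = rt
                row[f"{name.lower()}_rate"] = rec.number_correct(name) / rt
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_scores(
    records: list[PatientRecord], irt_scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Classical scores joined with IRT EAP score columns (if given)."""
    bundle = classical_scores(records)
    if irt_scores is not None:
        irt_scores = irt_scores.reset_index(drop=True)
        bundle = pd.concat([bundle, irt_scores], axis=1)
    return bundle


class CompositeRegression:
    """OLS of a binary label on score features (statsmodels backend)."""

    def __init__(self, labels: np.ndarray, features: pd.DataFrame, name: str = "Composite") -> None:
        self.labels = np.asarray(labels, dtype=float)
        if not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary 0/1")
        self.features = features
        self.name = name
        if features.isna().any().any():
            bad = list(features.columns[features.isna().any()])
            raise ValueError(f"features contain missing values: {bad}")
        if len(features) <= features.shape[1]:
            raise ValueError("need more patients than features")

    def fit(self) -> "CompositeResults":
        X = sm.add_constant(self.features.to_numpy(dtype=float), has_constant="add")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = scipy.linalg.qr(X, pivoting=True)
            dropped = [i for i in piv[rank:] if i > 0]
            names = [self.features.columns[i - 1] for i in dropped]
            raise ValueError(f"{self.name}: design matrix is rank deficient; collinear features: {names}")
        res = sm.OLS(self.labels, X).fit()
        return CompositeResults(self, res)


class CompositeResults:
    """Fitted composite: OLS estimates plus the logistic score map."""

    def __init__(self, model: CompositeRegression, ols_results) -> None:
        self.model = model
        self.ols = ols_results

    @property
    def intercept(self) -> float:
        return float(self.ols.params[0])

    @property
    def coefficients(self) -> np.ndarray:
        return np.asarray(self.ols.params[1:])

    def to_model(self) -> CompositeModel:
        return CompositeModel(
            name=self.model.name,
            feature_names=list(self.model.features.columns),
            intercept=self.intercept,
            coefficients=self.coefficients,
        )

    def predict_proba(self, scores: pd.DataFrame | None = None) -> pd.Series:
        scores = self.model.features if scores is None else scores
        return apply_composite(self.to_model(), scores)

    def summary(self) -> str:
        lines = [f"Composite regression {self.model.name} (OLS + logistic transform)"]
        lines.append(f"  n = {len(self.model.labels)}, R^2 = {self.ols.rsquared:.3f}")
        lines.append(f"  {'term':>12}  {'coef':>10}  {'se':>8}")
        lines.append(f"  {'intercept':>12}  {self.intercept:>10.4f}  {self.ols.bse[0]:>8.4f}")
        for name, c, se in zip(self.model.features.columns, self.coefficients, self.ols.bse[1:]):
            lines.append(f"  {name:>12}  {c:>10.4f}  {se:>8.4f}")
        return "\n".join(lines)


def fit_composite(features: pd.DataFrame, labels: np.ndarray, name: str = "Composite") -> CompositeModel:
    """OLS of the binary label on the features; deterministic."""
    return CompositeRegression(labels, features, name).fit().to_model()


def apply_composite(model: CompositeModel, scores: pd.DataFrame) -> pd.Series:
    """Per-patient probability P = sigma(intercept + sum coef * feature)."""
    f = model.linear_predictor(scores)
    return pd.Series(1.0 / (1.0 + np.exp(-f)), index=scores.index, name=model.name)


def load_composite_fixtures() -> dict[str, CompositeModel]:
    """The packaged reference coefficient table as CompositeModels.

    Composite2 carries ``rt_unit_warning=True``: its response-time
    coefficients (~1e-5) imply a sub-second time unit, so it must not
    be applied to second-scale RT columns as-is.
    """
    path = resources.files("cogscreen.data").joinpath("composite_coefficients.csv")
    from io import BytesIO

    table = pd.read_csv(BytesIO(path.read_bytes()), index_col="term")
    models = {}
    for name, feats in _FIXTURE_FEATURES.items():
        col = table[name]
        coefs = np.array([float(col[row]) for row, _ in feats])
        models[name] = CompositeModel(
            name=name,
            feature_names=[feat for _, feat in feats],
            intercept=float(col["intercept"]),
            coefficients=coefs,
            rt_unit_warning=(name == "Composite2"),
        )
    return models
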