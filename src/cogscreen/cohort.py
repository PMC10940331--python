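"""Cohort I/O and descriptive summaries.

The cohort CSV dialect is one row per patient:

* ``patient_id, impaired, age, gender, race, income, education``
* ``arw_rt, dccs_rt, psm_rt`` — total response times in seconds
* per-instrument response columns named ``<instrument>_<item>`` with a
  1-based item index (``dccs_1 .. dccs_30, psm_1 .. psm_12, ...``);
  missing responses are empty cells.

The module also ships a packaged fixture transcribed once from the
printed per-patient score tables of the source cohort (86 patients:
67 normal cognition, 19 cognitive impairment), guarded by a checksum.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .instruments import INSTRUMENTS, RT_INSTRUMENTS, InstrumentSpec, PatientRecord

__all__ = [
    "PrintedScoreRow",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_printed_fixture",
    "load_printed_fixture_frame",
    "cronbach_alpha",
    "summarize_cohort",
    "CohortSummary",
]

DEMOGRAPHIC_COLUMNS = ("patient_id", "impaired", "age", "gender", "race", "income", "education")

#: sha256 of the packaged fixture, recorded at transcription time.
_FIXTURE_SHA256 = "7d61eb4c6fae8973ca800aa2d74b2bf23c43fa377a6b4874da8ea484259668aa"


@dataclass(frozen=True)
class PrintedScoreRow:
    """One row of the printed per-patient score table.

    Carries the clinical label, the three printed scores (Composite3,
    SSHO2D, Composite5), the four printed predicted-label columns, and
    demographics.
    """

    impaired: int
    composite3: float
    ssho2d: float
    composite5: float
    pd_composite3_rf: int
    pd_ssho2d_linear: int
    pd_composite5_linear: int
    pd_f16: int
    age: int
    gender: str
    income: str
    education: str
    race: str


def _response_columns(specs: dict[str, InstrumentSpec]) -> list[tuple[str, str, int]]:
    cols = []
    for name, spec in specs.items():
        for j in range(1, spec.n_items + 1):
            cols.append((f"{name.lower()}_{j}", name, j - 1))
    return cols


def read_cohort_csv(
    path: str | Path, specs: dict[str, InstrumentSpec] | None = None
) -> list[PatientRecord]:
    """Read and validate a cohort CSV; row order is preserved.

    Raises ``ValueError`` naming the offending row/column on malformed
    input, and naming the instrument on a response-length mismatch.
    """
    specs = INSTRUMENTS if specs is None else specs
    df = pd.read_csv(path, dtype={"income": str, "education": str, "patient_id": str})
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort file {path}: missing column {col!r}")
    resp_cols = _response_columns(specs)
    for col, name, _ in resp_cols:
        if col not in df.columns:
            raise ValueError(
                f"cohort file {path}: instrument {name} is missing response column {col!r}"
            )
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        try:
            responses = {}
            for name, spec in specs.items():
                vec = row[[f"{name.lower()}_{j}" for j in range(1, spec.n_items + 1)]]
                responses[name] = pd.to_numeric(vec, errors="raise").to_numpy(dtype=float)
            rt_total = {}
            for name in RT_INSTRUMENTS:
                col = f"{name.lower()}_rt"
                if col in df.columns and pd.notna(row[col]):
                    rt_total[name] = float(row[col])
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                impaired=int(row["impaired"]),
                age=int(row["age"]),
                gender=str(row["gender"]),
                race=str(row["race"]),
                income=str(row["income"]),
                education=str(row["education"]),
                responses=responses,
                rt_total=rt_total,
            ).validate(specs)
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"cohort file {path}, row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_cohort_csv(
    records: list[PatientRecord],
    path: str | Path,
    specs: dict[str, InstrumentSpec] | None = None,
) -> None:
    """Write records in the dialect :func:`read_cohort_csv` reads."""
    specs = INSTRUMENTS if specs is None else specs
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "impaired": rec.impaired,
            "age": rec.age,
            "gender": rec.gender,
            "race": rec.race,
            "income": rec.income,
            "education": rec.education,
        }
        for name in RT_INSTRUMENTS:
            if name in rec.rt_total:
                row[f"{name.lower()}_rt"] = rec.rt_total[name]
        for name, spec in specs.items():
            vec = rec.responses[name]
            for j in range(spec.n_items):
                v = vec[j]
                row[f"{name.lower()}_{j + 1}"] = "" if np.isnan(v) else int(v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fixture_bytes() -> bytes:
    return resources.files("cogscreen.data").joinpath("printed_scores.csv").read_bytes()


def load_printed_fixture_frame() -> pd.DataFrame:
    """The packaged printed score table as a DataFrame (86 rows).

    Raises ``RuntimeError`` if the packaged file fails its recorded
    checksum (corrupted transcription).
    """
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            "packaged printed-score fixture is corrupted: "
            f"sha256 {digest} != recorded {_FIXTURE_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), dtype={"income": str, "education": str})


def load_printed_fixture() -> list[PrintedScoreRow]:
    """The printed per-patient score table as validated rows."""
    df = load_printed_fixture_frame()
    rows = []
    for _, r in df.iterrows():
        row = PrintedScoreRow(
            impaired=int(r.impaired),
            composite3=float(r.composite3),
            ssho2d=float(r.ssho2d),
            composite5=float(r.composite5),
            pd_composite3_rf=int(r.pd_composite3_rf),
            pd_ssho2d_linear=int(r.pd_ssho2d_linear),
            pd_composite5_linear=int(r.pd_composite5_linear),
            pd_f16=int(r.pd_f16),
            age=int(r.age),
            gender=str(r.gender),
            income=str(r.income),
            education=str(r.education),
            race=str(r.race),
        )
        for name in ("impaired", "pd_composite3_rf", "pd_ssho2d_linear", "pd_composite5_linear", "pd_f16"):
            if getattr(row, name) not in (0, 1):
                raise RuntimeError(f"fixture column {name} is not binary")
        rows.append(row)
    if len(rows) != 86:
        raise RuntimeError(f"fixture must have 86 rows, found {len(rows)}")
    return rows


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an (n_patients, k_items) score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total),
    with sample (ddof=1) variances.  Columns containing any missing
    value are dropped first, so instruments with monotone missingness
    are summarised over their completely observed items.  Returns nan
    when fewer than two complete items remain or the total score has
    zero variance.
    """
    items = np.asarray(items, dtype=float)
    complete = items[:, ~np.isnan(items).any(axis=0)]
    k = complete.shape[1]
    if k < 2 or complete.shape[0] < 2:
        return float("nan")
    item_var = complete.var(axis=0, ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class CohortSummary:
    """Descriptive tables for a cohort.

    Attributes
    ----------
    counts : pd.DataFrame
        Category counts for label and demographics.
    group_tables : dict[str, pd.DataFrame]
        Mean (SD) of per-instrument number-correct scores keyed by
        impaired / gender / race / education / income.
    correlations : pd.DataFrame | None
        Pearson correlations among impaired, education, race, income,
        age, gender, PSM and DCCS number-correct (categoricals
        integer-coded).  None when n < 2.
    alpha : dict[str, float] | None
        Per-instrument Cronbach's alpha.  None when n < 2.
    variance_defined : bool
        False when the cohort is too small for variance statistics.
    """

    counts: pd.DataFrame
    group_tables: dict[str, pd.DataFrame]
    correlations: pd.DataFrame | None
    alpha: dict[str, float] | None
    variance_defined: bool


def _codes(series: pd.Series) -> pd.Series:
    """Integer-code a categorical column by sorted category order."""
    return pd.Series(pd.Categorical(series).codes, index=series.index, dtype=float)


def summarize_cohort(
    records: list[PatientRecord], specs: dict[str, InstrumentSpec] | None = None
) -> CohortSummary:
    """Group summaries, score correlations and internal consistency."""
    specs = INSTRUMENTS if specs is None else specs
    if not records:
        raise ValueError("summarize_cohort requires at least one patient")
    demo = pd.DataFrame(
        {
            "impaired": [r.impaired for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "race": [r.race for r in records],
            "income": [r.income for r in records],
            "education": [r.education for r in records],
        }
    )
    scores = pd.DataFrame(
        {name: [r.number_correct(name) for r in records] for name in specs}
    )
    counts = (
        demo.melt(value_vars=["impaired", "gender", "race", "income", "education"])
        .groupby(["variable", "value"])
        .size()
        .rename("count")
        .reset_index()
    )
    if len(records) < 2:
        return CohortSummary(counts, {}, None, None, variance_defined=False)

    group_tables = {}
    for key in ("impaired", "gender", "race", "education", "income"):
        grouped = scores.groupby(demo[key])
        group_tables[key] = pd.concat(
            {"mean": grouped.mean(), "sd": grouped.std(ddof=1)}, axis=1
        )

    numeric = pd.DataFrame(
        {
            "impaired": demo["impaired"].astype(float),
            "education": _codes(demo["education"]),
            "race": _codes(demo["race"]),
            "income": _codes(demo["income"]),
            "age": demo["age"].astype(float),
            "gender": _codes(demo["gender"]),
            "PSM": scores["PSM"],
            "DCCS": scores["DCCS"],
        }
    )
    correlations = numeric.corr()

    alpha = {}
    for name, spec in specs.items():
        mat = np.vstack([r.responses[name] for r in records])
        alpha[name] = cronbach_alpha(mat)
    return CohortSummary(counts, group_tables, correlations, alpha, variance_defined=True)
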