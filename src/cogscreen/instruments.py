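"""Cognitive instrument definitions and the per-patient record.

The screening battery consists of five tablet/smartphone instruments:

========  ======================  =====================  =======
code      construct               full name              items
========  ======================  =====================  =======
DCCS      cognitive flexibility   Dimensional Change     30
                                  Card Sort
PSM       episodic memory         Picture Sequence       12
                                  Memory
ARW       inhibitory control      Arrow Matching         50
MFS       working memory          Sequences              30
NSM       processing speed        Number-Symbol Match    144
========  ======================  =====================  =======

DCCS, PSM and ARW record a total response time; MFS and NSM use
adaptive stopping / a 90-second limit, so their later items may be
unattempted and are coded as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InstrumentSpec",
    "INSTRUMENTS",
    "INSTRUMENT_ORDER",
    "RT_INSTRUMENTS",
    "PatientRecord",
    "total_items",
]


@dataclass(frozen=True)
class InstrumentSpec:
    """One instrument of the battery.

    Parameters
    ----------
    name : str
        Instrument code, one of ``DCCS, PSM, ARW, MFS, NSM``.
    n_items : int
        Number of dichotomously scored items.
    allows_missing : bool
        Whether unanswered items are permitted (adaptive stop / time limit).
    """

    name: str
    n_items: int
    allows_missing: bool = False

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValueError(f"n_items must be positive, got {self.n_items}")


#: Canonical battery, in administration order.
INSTRUMENTS: dict[str, InstrumentSpec] = {
    "DCCS": InstrumentSpec("DCCS", 30, allows_missing=False),
    "PSM": InstrumentSpec("PSM", 12, allows_missing=False),
    "ARW": InstrumentSpec("ARW", 50, allows_missing=False),
    "MFS": InstrumentSpec("MFS", 30, allows_missing=True),
    "NSM": InstrumentSpec("NSM", 144, allows_missing=True),
}

INSTRUMENT_ORDER: tuple[str, ...] = tuple(INSTRUMENTS)

#: Instruments for which a total response time is recorded (seconds).
RT_INSTRUMENTS: tuple[str, ...] = ("ARW", "DCCS", "PSM")


def total_items(specs: dict[str, InstrumentSpec] | None = None) -> int:
    """Total item count across the battery (266 for the default)."""
    specs = INSTRUMENTS if specs is None else specs
    return sum(s.n_items for s in specs.values())


@dataclass
class PatientRecord:
    """One subject: label, demographics, item responses, response times.

    ``responses`` maps instrument code to a float vector of {0.0, 1.0,
    nan}; nan marks a missing (unattempted) item and is only legal for
    instruments whose spec allows it.  ``rt_total`` maps instrument code
    to total response time in seconds (DCCS, PSM, ARW).  Income and
    education are kept as opaque string codes: the cohort contains the
    special codes ``"D"`` (income) and ``"777"`` (education), which are
    preserved, never imputed.
    """

    patient_id: str
    impaired: int
    age: int
    gender: str
    race: str
    income: str
    education: str
    responses: dict[str, np.ndarray] = field(default_factory=dict)
    rt_total: dict[str, float] = field(default_factory=dict)

    def validate(self, specs: dict[str, InstrumentSpec] | None = None) -> "PatientRecord":
        """Check invariants; return self, raise ``ValueError`` otherwise."""
        specs = INSTRUMENTS if specs is None else specs
        if self.impaired not in (0, 1):
            raise ValueError(
                f"patient {self.patient_id}: impaired must be 0 or 1, got {self.impaired}"
            )
        for name, vec in self.responses.items():
            spec = specs[name]
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (spec.n_items,):
                raise ValueError(
                    f"patient {self.patient_id}: instrument {name} expects "
                    f"{spec.n_items} responses, got {vec.shape[0]}"
                )
            observed = vec[~np.isnan(vec)]
            if not np.isin(observed, (0.0, 1.0)).all():
                raise ValueError(
                    f"patient {self.patient_id}: instrument {name} has responses "
                    "outside {0, 1, missing}"
                )
            if np.isnan(vec).any() and not spec.allows_missing:
                raise ValueError(
                    f"patient {self.patient_id}: instrument {name} does not allow "
                    "missing responses"
                )
            self.responses[name] = vec
        for name, rt in self.rt_total.items():
            if not rt > 0:
                raise ValueError(
                    f"patient {self.patient_id}: rt_total for {name} must be > 0, got {rt}"
                )
        return self

    def number_correct(self, instrument: str) -> int:
        """Observed number of correct responses (missing items excluded)."""
        vec = self.responses[instrument]
        return int(np.nansum(vec))

    def n_observed(self, instrument: str) -> int:
        vec = self.responses[instrument]
        return int(np.sum(~np.isnan(vec)))
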