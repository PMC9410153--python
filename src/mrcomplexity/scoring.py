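"""MRCI and MRC-ICU scoring over post-admission evaluation windows.

Both instruments are computed per patient at 24 h and 48 h after ICU
admission (other windows are allowed).  Windows are cumulative by default —
the 48 h regimen contains every order active at any point in the first
48 h — which makes the 24 h and 48 h covariates nested; a ``daily`` mode
scoring only the second day ([24, 48) h) is provided.

Scoring is regimen-level: duplicate orders of the same drug/form (MRCI
section A), drug (sections B and C keys) or drug/item (MRC-ICU) within a
window count once, so the score reflects the complexity of the regimen,
not the number of administrations charted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .records import MedicationOrder, PatientRecord
from .weights import WeightTable

#: published high-complexity cutoffs: cohort medians of the 24 h scores
DEFAULT_MRCI_CUTOFF = 63.0
DEFAULT_MRC_ICU_CUTOFF = 6.0

WindowMode = Literal["cumulative", "daily"]


@dataclass(frozen=True)
class ScorePanel:
    """Per-patient scores for every evaluated window end (hours)."""

    patient_id: str
    mrci: Mapping[int, float]
    mrc_icu: Mapping[int, float]
    windows_evaluated: tuple[int, ...]

    def __post_init__(self):
        for scores in (self.mrci, self.mrc_icu):
            for window, value in scores.items():
                if value < 0:
                    raise ValueError(
                        f"negative score {value} at window {window} for "
                        f"patient {self.patient_id}"
                    )

    @property
    def mrci_24h(self) -> float:
        return self.mrci[24]

    @property
    def mrci_48h(self) -> float:
        return self.mrci[48]

    @property
    def mrc_icu_24h(self) -> float:
        return self.mrc_icu[24]

    @property
    def mrc_icu_48h(self) -> float:
        return self.mrc_icu[48]


def active_orders(
    orders: Iterable[MedicationOrder],
    admission_time: float,
    window_end_hours: float,
    window_start_hours: float = 0.0,
) -> list[MedicationOrder]:
    """Orders whose activity interval intersects the evaluation window.

    The window is ``[admission + start, admission + end)`` in hours.  An open
    order (no stop time) is treated as active until the window closes; an
    order started before admission is retained only if still active at (or
    after) the window start.
    """
    if window_end_hours <= window_start_hours:
        raise ValueError("window end must exceed window start")
    lo = admission_time + window_start_hours
    hi = admission_time + window_end_hours
    selected = []
    for order in orders:
        if order.start_time >= hi:
            continue
        if order.stop_time is not None and order.stop_time < lo:
            continue
        selected.append(order)
    return selected


def mrci_score(
    orders_subset: Sequence[MedicationOrder],
    tables: Mapping[str, WeightTable],
    frequency_rule: Literal["per_drug_max", "per_schedule"] = "per_drug_max",
) -> float:
    """Total MRCI: section A + B + C weighted sums over the regimen.

    Section A sums dosage-form weights over distinct (drug, form) pairs;
    section B sums one frequency weight per drug (the highest-weight schedule
    when a drug has several, or every distinct schedule under
    ``per_schedule``); section C sums additional-direction weights over
    distinct (drug, direction) pairs.  Scheduled and as-needed (PRN)
    medications both contribute.
    """
    table_a, table_b, table_c = tables["MRCI_A"], tables["MRCI_B"], tables["MRCI_C"]

    section_a = sum(
        table_a.weight(form)
        for drug, form in {(o.drug_name, o.dosage_form) for o in orders_subset}
    )

    freq_by_drug: dict[str, set[str]] = {}
    for o in orders_subset:
        freq_by_drug.setdefault(o.drug_name, set()).add(o.frequency_code)
    if frequency_rule == "per_drug_max":
        section_b = sum(
            max(table_b.weight(code) for code in codes)
            for codes in freq_by_drug.values()
        )
    elif frequency_rule == "per_schedule":
        section_b = sum(
            table_b.weight(code)
            for codes in freq_by_drug.values()
            for code in codes
        )
    else:
        raise ValueError(f"unknown frequency_rule {frequency_rule!r}")

    section_c = sum(
        table_c.weight(direction)
        for drug, direction in {
            (o.drug_name, d) for o in orders_subset for d in o.additional_directions
        }
    )
    return float(section_a + section_b + section_c)


def mrc_icu_score(
    orders_subset: Sequence[MedicationOrder],
    table: WeightTable,
) -> float:
    """Sum of item weights over distinct (drug, item) pairs in the regimen.

    Orders whose drug maps to no instrument item contribute nothing.
    """
    pairs = {
        (o.drug_name, o.mrc_icu_item)
        for o in orders_subset
        if o.mrc_icu_item is not None
    }
    return float(sum(table.weight(item) for _, item in pairs))


def score_panel(
    patient: PatientRecord,
    orders: Sequence[MedicationOrder],
    tables: Mapping[str, WeightTable],
    windows: Sequence[int] = (24, 48),
    window_mode: WindowMode = "cumulative",
    frequency_rule: Literal["per_drug_max", "per_schedule"] = "per_drug_max",
) -> ScorePanel:
    """Score one patient's regimen at each window end.

    ``cumulative`` windows run from admission to the window end; ``daily``
    windows cover only the 24 h preceding each window end.
    """
    mrci: dict[int, float] = {}
    mrc: dict[int, float] = {}
    for end in windows:
        start = 0.0 if window_mode == "cumulative" else max(0.0, end - 24.0)
        subset = active_orders(orders, patient.icu_admission, end, start)
        mrci[int(end)] = mrci_score(subset, tables, frequency_rule)
        mrc[int(end)] = mrc_icu_score(subset, tables["MRC_ICU"])
    return ScorePanel(
        patient_id=patient.patient_id,
        mrci=mrci,
        mrc_icu=mrc,
        windows_evaluated=tuple(int(w) for w in windows),
    )


def score_cohort(
    patients: Sequence[PatientRecord],
    orders_by_pid: Mapping[str, Sequence[MedicationOrder]],
    tables: Mapping[str, WeightTable],
    windows: Sequence[int] = (24, 48),
    window_mode: WindowMode = "cumulative",
) -> dict[str, ScorePanel]:
    return {
        p.patient_id: score_panel(
            p, orders_by_pid.get(p.patient_id, ()), tables, windows, window_mode
        )
        for p in patients
    }


def dichotomize(
    panels: Mapping[str, ScorePanel] | Sequence[ScorePanel],
    mrci_cutoff: float = DEFAULT_MRCI_CUTOFF,
    mrc_icu_cutoff: float = DEFAULT_MRC_ICU_CUTOFF,
    mode: Literal["fixed", "median"] = "fixed",
    window: int = 24,
) -> dict[str, dict[str, bool]]:
    """High/low regimen-complexity labels from the 24 h score distribution.

    ``high`` means strictly greater than the cutoff.  In ``median`` mode the
    cutoffs are recomputed as the cohort medians of the window's scores (the
    rule used to set the 63 / 6 defaults).
    """
    panel_list = list(panels.values()) if isinstance(panels, Mapping) else list(panels)
    if mode == "median":
        if not panel_list:
            raise ValueError("cannot take median cutoffs of an empty cohort")
        mrci_cutoff = float(np.median([p.mrci[window] for p in panel_list]))
        mrc_icu_cutoff = float(np.median([p.mrc_icu[window] for p in panel_list]))
    elif mode != "fixed":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    return {
        p.patient_id: {
            "mrci_high": p.mrci[window] > mrci_cutoff,
            "mrc_icu_high": p.mrc_icu[window] > mrc_icu_cutoff,
        }
        for p in panel_list
    }
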