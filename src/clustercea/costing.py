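"""Valuation and aggregation of health-sector and program costs.

All aggregation happens in reference-year USD. Historical local-currency
amounts are inflated with a rural consumer price index and converted
once at the reference-year exchange rate; mixing unadjusted currency
years in one sum is an error, never a silent addition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import RunConfig, ValidationError

#: closed set of cost categories; every item maps to exactly one
CATEGORIES = frozenset(
    {
        "inpatient_stroke",
        "inpatient_cvd_nonstroke",
        "inpatient_other",
        "outpatient",
        "med_antiplatelet",
        "med_statin",
        "med_antihypertensive",
        "program_component",
    }
)

INPATIENT_CATEGORIES = ("inpatient_stroke", "inpatient_cvd_nonstroke", "inpatient_other")
MEDICATION_CATEGORIES = ("med_antiplatelet", "med_statin", "med_antihypertensive")


def adjust_currency(
    amount: float,
    source_year: int,
    cfg: RunConfig,
    currency: str = "local",
) -> float:
    """Express ``amount`` (recorded in ``source_year``) in reference-year USD.

    The amount is inflated by ``cpi[reference_year] / cpi[source_year]``
    and, when recorded in local currency, divided once by the
    reference-year exchange rate. The map is linear in ``amount``.
    """
    if currency not in ("local", "usd"):
        raise ValueError(f"unknown currency {currency!r}")
    for year in (source_year, cfg.reference_year):
        if year not in cfg.cpi_table:
            raise KeyError(f"cpi_table has no entry for year {year}")
    out = amount * cfg.cpi_table[cfg.reference_year] / cfg.cpi_table[source_year]
    if currency == "local":
        out /= cfg.exchange_rate
    return out


def medication_cost(quantity: float, unit_price: float, adherence: float) -> float:
    """Cost of a medication item: quantity x unit price, discounted by adherence."""
    if quantity < 0 or unit_price < 0:
        raise ValidationError("quantity and unit_price must be >= 0")
    if not 0 <= adherence <= 1:
        raise ValidationError(f"adherence must lie in [0, 1], got {adherence}")
    return quantity * unit_price * adherence


def person_total_cost(
    items: pd.DataFrame,
    outpatient_flat: float,
    cfg: RunConfig,
) -> float:
    """Total reference-year USD cost for one participant.

    ``items`` holds that participant's currency-adjusted cost items
    (possibly none); a flat per-participant outpatient cost is always
    added, so participants without any hospitalization or medication
    use contribute ``outpatient_flat`` alone.
    """
    if len(items) == 0:
        return float(outpatient_flat)
    bad = set(items["category"]) - CATEGORIES
    if bad:
        raise ValidationError(f"unknown cost categories: {sorted(bad)}")
    years = set(items["source_year"].unique())
    if years - {cfg.reference_year}:
        raise ValidationError(
            f"items carry currency-year(s) {sorted(years)} != reference "
            f"{cfg.reference_year}; adjust_currency them first"
        )
    if (items["amount"] < 0).any():
        raise ValidationError("cost amounts must be >= 0")
    return float(items["amount"].sum() + outpatient_flat)


@dataclass(frozen=True)
class ProgramLedger:
    """Itemized program-delivery costs with per-participant amortization.

    ``components`` are (name, unit_cost, quantity, total) rows — the
    structure of a program implementation-cost table (staff
    compensation, messaging fees, printing, system maintenance,
    development) — and ``n_participants`` is the head count the grand
    total is amortized over.
    """

    components: tuple[tuple[str, float, float, float], ...]
    n_participants: int

    def __post_init__(self) -> None:
        if any(c[3] < 0 for c in self.components):
            raise ValidationError("component totals must be >= 0")


def program_per_participant(ledger: ProgramLedger) -> tuple[float, float]:
    """Grand total of the program ledger and its per-participant share."""
    if ledger.n_participants <= 0:
        raise ValidationError("n_participants must be > 0 to amortize program costs")
    grand = float(sum(c[3] for c in ledger.components))
    return grand, grand / ledger.n_participants


def read_program_ledger(path, n_participants: int) -> ProgramLedger:
    """Read a program-cost CSV with columns component,unit_cost,quantity,total."""
    df = pd.read_csv(path)
    rows = tuple(
        (str(r.component), float(r.unit_cost), float(r.quantity), float(r.total))
        for r in df.itertuples()
    )
    return ProgramLedger(rows, n_participants)


def estimate_posttrial_inpatient(
    visit_counts: Mapping[str, float],
    mean_cost_per_cause: Mapping[str, float],
) -> float:
    """Impute post-trial inpatient cost from self-reported visit counts.

    Each reported visit of a given cause is valued at the within-trial
    mean episode cost for that cause: sum over causes of count x mean.
    """
    total = 0.0
    for cause, count in visit_counts.items():
        if cause not in mean_cost_per_cause:
            raise KeyError(f"no within-trial mean cost for cause {cause!r}")
        total += count * mean_cost_per_cause[cause]
    return total


def total_costs_by_participant(
    items: pd.DataFrame,
    participant_ids: Iterable,
    outpatient_flat: float,
    cfg: RunConfig,
) -> pd.Series:
    """Vectorized per-participant totals over the whole cohort.

    Equivalent to calling :func:`person_total_cost` per participant but
    suitable for bootstrap-scale use. Participants with no items get
    the flat outpatient cost only.
    """
    if len(items):
        bad = set(items["category"]) - CATEGORIES
        if bad:
            raise ValidationError(f"unknown cost categories: {sorted(bad)}")
        years = set(items["source_year"].unique())
        if years - {cfg.reference_year}:
            raise ValidationError(
                f"items carry currency-year(s) {sorted(years)} != reference "
                f"{cfg.reference_year}"
            )
        sums = items.groupby("participant_id")["amount"].sum()
    else:
        sums = pd.Series(dtype=float)
    idx = pd.Index(list(participant_ids), name="participant_id")
    return sums.reindex(idx, fill_value=0.0) + outpatient_flat
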