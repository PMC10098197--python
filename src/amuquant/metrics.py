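"""Dose-based antimicrobial-usage metrics.

For a substance with defined daily dose ``DDD_kg`` (mg/kg/day) given to an
animal of weight ``w`` (kg):

* ``ADD = DDD_kg x w / 1000``  (g/day) - the standard daily dose;
* ``nADD = mass_g / ADD``      - standardized exposure count;
* ``UDD = mass_mg / (n_treated x w_mean x days)``  (mg/kg/day) - the dose
  actually used;
* ``UADD = UDD x w``  (mg/day) and ``nUADD = mass_mg / UADD``;
* ``ADUR = mass_g x 1000 / (ADD x period_days x n_animals_at_risk)`` -
  usage rate per 1000 animal-days;
* ``UDD / DDD_kg`` - dosing-adequacy ratio; < 0.8 under-dosed, 0.8-1.2
  correct (edges inclusive), > 1.2 over-dosed.

Intramammary products are dosed per syringe, not per kg: their ADD is
``mg_per_unit x units_per_administration x administrations_per_day``.

All functions carry full precision; rounding is deferred to reporting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .catalogue import Catalogue, Route, resolve_dose_determining
from .errors import MetricsError
from .records import Herd, TreatmentEvent, CATTLE_MEDIAN_KG

__all__ = [
    "DosingClass",
    "DoseMetrics",
    "IntramammaryAdminSpec",
    "animal_daily_dose",
    "intramammary_add",
    "n_add",
    "used_daily_dose",
    "n_uadd",
    "adur",
    "dosing_classification",
    "compute_event_metrics",
    "compute_metrics",
    "write_metrics",
    "read_metrics",
]

DEFAULT_DOSING_BAND = (0.8, 1.2)


class DosingClass(str, enum.Enum):
    UNDER = "UNDER"
    CORRECT = "CORRECT"
    OVER = "OVER"


@dataclass(frozen=True)
class IntramammaryAdminSpec:
    """Per-administration dose of an intramammary product."""

    mg_per_unit: float  # dose (mg) per syringe/mL
    units_per_admin: float  # syringes or mL used per administration
    admins_per_day: float  # administrations per day

    def __post_init__(self) -> None:
        if min(self.mg_per_unit, self.units_per_admin, self.admins_per_day) <= 0:
            raise MetricsError("intramammary spec fields must all be > 0")


@dataclass
class DoseMetrics:
    """Per-event, per-substance computed metrics (full precision)."""

    event_id: str
    herd_id: str
    indication: str
    substance: str
    am_class: str
    who_category: str
    total_mass_mg: float
    add_g_per_day: float
    n_add: float
    udd_mg_per_kg_day: float
    uadd_mg_per_day: float
    n_uadd: float
    dose_ratio: float
    dosing_class: str


def animal_daily_dose(ddd_kg: float, weight_kg: float) -> float:
    """ADD (g/day) = DDD_kg (mg/kg/day) x weight (kg) / 1000."""
    if ddd_kg <= 0 or weight_kg <= 0:
        raise MetricsError("animal_daily_dose: inputs must be > 0")
    return ddd_kg * weight_kg / 1000.0


def intramammary_add(spec: IntramammaryAdminSpec) -> float:
    """ADD (mg/day) for a syringe-dosed product: MG x U x F."""
    return spec.mg_per_unit * spec.units_per_admin * spec.admins_per_day


def n_add(total_mass_mg: float, add_g_per_day: float) -> float:
    """Number of animal daily doses in a used mass."""
    if add_g_per_day <= 0:
        raise MetricsError("n_add: ADD must be > 0")
    if total_mass_mg < 0:
        raise MetricsError("n_add: mass must be >= 0")
    return (total_mass_mg / 1000.0) / add_g_per_day


def used_daily_dose(
    total_mass_mg: float,
    n_treated: int,
    avg_weight_kg: float,
    duration_days: float,
) -> float:
    """UDD (mg/kg/day): administered mass over animal x weight x days."""
    denom = n_treated * avg_weight_kg * duration_days
    if denom <= 0:
        raise MetricsError("used_daily_dose: denominator must be > 0")
    if total_mass_mg < 0:
        raise MetricsError("used_daily_dose: mass must be >= 0")
    return total_mass_mg / denom


def n_uadd(total_mass_mg: float, udd_mg_per_kg_day: float, weight_kg: float) -> float:
    """Number of used animal daily doses: mass over (UDD x weight)."""
    denom = udd_mg_per_kg_day * weight_kg
    if denom <= 0:
        raise MetricsError("n_uadd: UDD x weight must be > 0")
    if total_mass_mg < 0:
        raise MetricsError("n_uadd: mass must be >= 0")
    return total_mass_mg / denom


def adur(
    total_mass_g: float,
    add_g_per_day: float,
    period_days: float,
    n_animals_at_risk: float,
) -> float:
    """Antimicrobial drug use rate in ADD per 1000 animal-days."""
    denom = add_g_per_day * period_days * n_animals_at_risk
    if denom <= 0:
        raise MetricsError("adur: denominator must be > 0")
    if total_mass_g < 0:
        raise MetricsError("adur: mass must be >= 0")
    return total_mass_g * 1000.0 / denom


def dosing_classification(
    udd_mg_per_kg_day: float,
    ddd_kg: float,
    band: tuple[float, float] = DEFAULT_DOSING_BAND,
) -> tuple[float, DosingClass]:
    """Dose-adequacy ratio UDD/DDD_kg and its band classification.

    Band edges are inclusive: a ratio of exactly 0.8 or 1.2 is CORRECT.
    """
    if ddd_kg <= 0:
        raise MetricsError("dosing_classification: DDD_kg must be > 0")
    lo, hi = band
    if not lo < hi:
        raise MetricsError("dosing_classification: band lower must be < upper")
    ratio = udd_mg_per_kg_day / ddd_kg
    if ratio < lo:
        cls = DosingClass.UNDER
    elif ratio > hi:
        cls = DosingClass.OVER
    else:
        cls = DosingClass.CORRECT
    return ratio, cls


def compute_event_metrics(
    event: TreatmentEvent,
    catalogue: Catalogue,
    *,
    herds: dict[str, Herd] | None = None,
    band: tuple[float, float] = DEFAULT_DOSING_BAND,
) -> DoseMetrics:
    """Full metric chain for one event's dose-determining substance.

    The weight entering ADD/UDD/UADD is the arithmetic mean of the recorded
    per-animal weights; an event without weights falls back to the herd's
    species-mix weighted median adult weight (cattle 400 kg, buffalo 500 kg).
    Intramammary events take the syringe-dosed ADD branch; their
    per-administration unit count is derived from the total quantity used,
    the animals treated, the duration and the daily frequency.
    """
    try:
        product = catalogue.product(event.product_id)
        comp = resolve_dose_determining(product)
        masses = catalogue.total_active_mass(product, event.quantity_used)
        ddd = catalogue.lookup_ddd(comp.substance, route=event.route)
    except Exception as exc:
        raise MetricsError(f"event {event.event_id!r}: {exc}") from exc

    fallback = (
        herds[event.herd_id].fallback_weight_kg
        if herds and event.herd_id in herds
        else CATTLE_MEDIAN_KG
    )
    weight = event.mean_weight_kg(fallback)
    mass_mg = masses[comp.substance]

    if event.route is Route.INTRAMAMMARY:
        units_per_admin = event.quantity_used / (
            event.n_animals_treated * event.duration_days * event.admins_per_day
        )
        spec = IntramammaryAdminSpec(
            catalogue._mass_per_quantity(comp), units_per_admin, event.admins_per_day
        )
        add_g = intramammary_add(spec) / 1000.0
    else:
        add_g = animal_daily_dose(ddd.ddd_kg, weight)

    nadd = n_add(mass_mg, add_g)
    udd = used_daily_dose(
        mass_mg, event.n_animals_treated, weight, event.duration_days
    )
    uadd = udd * weight
    nuadd = n_uadd(mass_mg, udd, weight)
    ratio, cls = dosing_classification(udd, ddd.ddd_kg, band)

    substance = catalogue.substance(comp.substance)
    return DoseMetrics(
        event_id=event.event_id,
        herd_id=event.herd_id,
        indication=event.indication.value,
        substance=substance.name,
        am_class=substance.am_class,
        who_category=catalogue.who_category(substance.name).value,
        total_mass_mg=mass_mg,
        add_g_per_day=add_g,
        n_add=nadd,
        udd_mg_per_kg_day=udd,
        uadd_mg_per_day=uadd,
        n_uadd=nuadd,
        dose_ratio=ratio,
        dosing_class=cls.value,
    )


METRIC_COLUMNS = [
    "event_id", "herd_id", "indication", "substance", "am_class",
    "who_category", "total_mass_mg", "add_g_per_day", "n_add",
    "udd_mg_per_kg_day", "uadd_mg_per_day", "n_uadd", "dose_ratio",
    "dosing_class",
]


def compute_metrics(
    events: list[TreatmentEvent],
    catalogue: Catalogue,
    *,
    herds: dict[str, Herd] | None = None,
    band: tuple[float, float] = DEFAULT_DOSING_BAND,
) -> pd.DataFrame:
    """One metrics row per event (dose-determining substance)."""
    rows = [
        asdict(compute_event_metrics(e, catalogue, herds=herds, band=band))
        for e in events
    ]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    """Deterministic column order, full-precision floats."""
    metrics.to_csv(path, index=False, columns=METRIC_COLUMNS)


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise MetricsError(f"{path}: missing metric columns {missing}")
    return df[METRIC_COLUMNS]
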