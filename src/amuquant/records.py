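"""Treatment-event and bin-deposit records, schemas and reconciliation.

Two independent data streams describe on-farm antimicrobial use:

* a *treatment history*: one row per treatment episode with the product,
  quantity, animals treated, weights, duration, route and administrator,
  reported by the farm at monthly intervals; and
* *bin deposits*: counts of empty drug containers collected monthly from a
  dedicated receptacle on the farm (the "bin method"), with prescription
  notes standing in for partially used vials.

``reconcile`` compares the active-ingredient mass implied by each stream
per herd x month x product and reports agreement rather than forcing a
resolution: discrepancies are data.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path

from .catalogue import Catalogue, Route, resolve_dose_determining
from .errors import ValidationError

__all__ = [
    "HerdType",
    "Indication",
    "Administrator",
    "Herd",
    "Animal",
    "TreatmentEvent",
    "BinDeposit",
    "ReconciliationReport",
    "read_events",
    "write_events",
    "read_bin_deposits",
    "write_bin_deposits",
    "read_herds",
    "write_herds",
    "reconcile",
]

# Species-median adult bodyweights (kg) used when an event carries no
# recorded weights; plausibility bands for warnings.
CATTLE_MEDIAN_KG = 400.0
BUFFALO_MEDIAN_KG = 500.0
CATTLE_RANGE_KG = (300.0, 520.0)
BUFFALO_RANGE_KG = (425.0, 650.0)


class HerdType(str, enum.Enum):
    HOUSEHOLD = "HOUSEHOLD"  # 5-20 animals, family labour
    COMMERCIAL = "COMMERCIAL"  # > 20 animals, (semi-)mechanized


class Indication(str, enum.Enum):
    MASTITIS = "MASTITIS"
    FEVER = "FEVER"
    REPRODUCTIVE = "REPRODUCTIVE"
    DIARRHEA = "DIARRHEA"
    MISC = "MISC"


class Administrator(str, enum.Enum):
    VETERINARIAN = "VETERINARIAN"
    PARA_VETERINARIAN = "PARA_VETERINARIAN"
    UNAUTHORIZED = "UNAUTHORIZED"
    FARMER = "FARMER"


@dataclass(frozen=True)
class Herd:
    herd_id: str
    herd_type: HerdType
    n_cattle: int
    n_buffalo: int
    enrolment_days: int = 365

    def __post_init__(self) -> None:
        total = self.n_cattle + self.n_buffalo
        if self.enrolment_days <= 0:
            raise ValidationError(f"herd {self.herd_id!r}: enrolmentDays must be > 0")
        if self.herd_type is HerdType.HOUSEHOLD and not 5 <= total <= 20:
            raise ValidationError(
                f"herd {self.herd_id!r}: household herds hold 5-20 animals "
                f"(got {total})"
            )
        if self.herd_type is HerdType.COMMERCIAL and total <= 20:
            raise ValidationError(
                f"herd {self.herd_id!r}: commercial herds hold > 20 animals "
                f"(got {total})"
            )

    @property
    def n_animals(self) -> int:
        return self.n_cattle + self.n_buffalo

    @property
    def fallback_weight_kg(self) -> float:
        """Species-mix weighted median adult weight for weightless events."""
        if self.n_animals == 0:  # pragma: no cover - excluded by invariants
            return CATTLE_MEDIAN_KG
        return (
            self.n_cattle * CATTLE_MEDIAN_KG + self.n_buffalo * BUFFALO_MEDIAN_KG
        ) / self.n_animals


@dataclass(frozen=True)
class Animal:
    animal_id: str
    herd_id: str
    species: str  # "CATTLE" | "BUFFALO"
    weight_kg: float

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValidationError(f"animal {self.animal_id!r}: weight must be > 0")

    def weight_warning(self) -> str | None:
        lo, hi = (
            CATTLE_RANGE_KG if self.species == "CATTLE" else BUFFALO_RANGE_KG
        )
        if not lo <= self.weight_kg <= hi:
            return (
                f"animal {self.animal_id!r}: weight {self.weight_kg} kg outside "
                f"the plausible {self.species.lower()} range [{lo}, {hi}]"
            )
        return None


@dataclass(frozen=True)
class TreatmentEvent:
    """One treatment episode of one product in one herd."""

    event_id: str
    herd_id: str
    month: int  # calendar month index 1-12
    indication: Indication
    product_id: str
    quantity_used: float  # mL, or dispensing units for unit-dosed products
    n_animals_treated: int
    animal_weights_kg: tuple[float, ...] = ()
    duration_days: int = 1
    route: Route = Route.PARENTERAL
    administrator: Administrator = Administrator.VETERINARIAN
    admins_per_day: int = 1  # intramammary administration frequency F
    case_id: str | None = None  # explicit disease-case grouping

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError(f"event {self.event_id!r}: month must be 1-12")
        if self.n_animals_treated < 1:
            raise ValidationError(
                f"event {self.event_id!r}: nAnimalsTreated must be >= 1"
            )
        if self.duration_days < 1:
            raise ValidationError(
                f"event {self.event_id!r}: durationDays must be >= 1"
            )
        if self.quantity_used <= 0:
            raise ValidationError(
                f"event {self.event_id!r}: quantityUsed must be > 0"
            )
        if self.admins_per_day < 1:
            raise ValidationError(
                f"event {self.event_id!r}: adminsPerDay must be >= 1"
            )
        if self.animal_weights_kg and len(self.animal_weights_kg) != (
            self.n_animals_treated
        ):
            raise ValidationError(
                f"event {self.event_id!r}: weights list must be empty or have "
                "one entry per treated animal"
            )
        object.__setattr__(self, "animal_weights_kg", tuple(self.animal_weights_kg))

    @property
    def case_key(self) -> str:
        """Disease-case identifier: explicit caseId, else eventId stem."""
        if self.case_id:
            return self.case_id
        return self.event_id.rsplit("-", 1)[0]

    def mean_weight_kg(self, fallback: float = CATTLE_MEDIAN_KG) -> float:
        if self.animal_weights_kg:
            return sum(self.animal_weights_kg) / len(self.animal_weights_kg)
        return fallback


@dataclass(frozen=True)
class BinDeposit:
    """Monthly bin content for one product on one herd."""

    herd_id: str
    month: int
    product_id: str
    empties_count: int
    partial_use_note: str | None = None  # prescription stand-in

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValidationError("deposit: month must be 1-12")
        if self.empties_count < 0:
            raise ValidationError("deposit: emptiesCount must be >= 0")


@dataclass
class ReconciliationReport:
    """Agreement between the treatment history and the bin stream."""

    matched: int = 0
    history_only: int = 0
    bin_only: int = 0
    mass_discrepancy_mg: dict[str, float] = field(default_factory=dict)

    @property
    def total_events(self) -> int:
        return self.matched + self.history_only


# -- delimited-file I/O ----------------------------------------------------

EVENT_COLUMNS = [
    "eventId", "herdId", "month", "indication", "productId", "quantityUsed",
    "quantityUnit", "nAnimalsTreated", "weightsKg", "durationDays", "route",
    "administrator", "adminsPerDay", "caseId",
]
BIN_COLUMNS = ["herdId", "month", "productId", "emptiesCount", "partialUseNote"]
HERD_COLUMNS = ["herdId", "herdType", "nCattle", "nBuffalo", "enrolmentDays"]


def _open_reader(path: str | Path, required: list[str]):
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    fh = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        fh.close()
        raise ValidationError(f"{path}: missing columns {missing}")
    return fh, reader


def read_events(path: str | Path) -> tuple[list[TreatmentEvent], list[str]]:
    """Parse events.csv; invalid rows go to the error report, valid rows return."""
    required = [c for c in EVENT_COLUMNS if c not in ("quantityUnit", "caseId")]
    fh, reader = _open_reader(path, required)
    events: list[TreatmentEvent] = []
    errors: list[str] = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                weights = tuple(
                    float(w) for w in (row.get("weightsKg") or "").split(";") if w
                )
                events.append(
                    TreatmentEvent(
                        event_id=row["eventId"],
                        herd_id=row["herdId"],
                        month=int(row["month"]),
                        indication=Indication(row["indication"].strip().upper()),
                        product_id=row["productId"],
                        quantity_used=float(row["quantityUsed"]),
                        n_animals_treated=int(row["nAnimalsTreated"]),
                        animal_weights_kg=weights,
                        duration_days=int(row["durationDays"]),
                        route=Route(row["route"].strip().upper()),
                        administrator=Administrator(
                            row["administrator"].strip().upper()
                        ),
                        admins_per_day=int(row.get("adminsPerDay") or 1),
                        case_id=(row.get("caseId") or None),
                    )
                )
            except (ValidationError, ValueError, KeyError) as exc:
                errors.append(f"{path} line {lineno}: {exc}")
    return events, errors


def write_events(events: list[TreatmentEvent], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
        writer.writeheader()
        for e in events:
            writer.writerow(
                {
                    "eventId": e.event_id,
                    "herdId": e.herd_id,
                    "month": e.month,
                    "indication": e.indication.value,
                    "productId": e.product_id,
                    "quantityUsed": repr(e.quantity_used),
                    "quantityUnit": "mL" if e.route is not Route.INTRAMAMMARY
                    else "unit",
                    "nAnimalsTreated": e.n_animals_treated,
                    "weightsKg": ";".join(repr(w) for w in e.animal_weights_kg),
                    "durationDays": e.duration_days,
                    "route": e.route.value,
                    "administrator": e.administrator.value,
                    "adminsPerDay": e.admins_per_day,
                    "caseId": e.case_id or "",
                }
            )


def read_bin_deposits(path: str | Path) -> tuple[list[BinDeposit], list[str]]:
    fh, reader = _open_reader(path, BIN_COLUMNS[:4])
    deposits: list[BinDeposit] = []
    errors: list[str] = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                deposits.append(
                    BinDeposit(
                        herd_id=row["herdId"],
                        month=int(row["month"]),
                        product_id=row["productId"],
                        empties_count=int(row["emptiesCount"]),
                        partial_use_note=(row.get("partialUseNote") or None),
                    )
                )
            except (ValidationError, ValueError) as exc:
                errors.append(f"{path} line {lineno}: {exc}")
    return deposits, errors


def write_bin_deposits(deposits: list[BinDeposit], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=BIN_COLUMNS)
        writer.writeheader()
        for d in deposits:
            writer.writerow(
                {
                    "herdId": d.herd_id,
                    "month": d.month,
                    "productId": d.product_id,
                    "emptiesCount": d.empties_count,
                    "partialUseNote": d.partial_use_note or "",
                }
            )


def read_herds(path: str | Path) -> tuple[list[Herd], list[str]]:
    fh, reader = _open_reader(path, HERD_COLUMNS)
    herds: list[Herd] = []
    errors: list[str] = []
    with fh:
        for lineno, row in enumerate(reader, start=2):
            try:
                herds.append(
                    Herd(
                        herd_id=row["herdId"],
                        herd_type=HerdType(row["herdType"].strip().upper()),
                        n_cattle=int(row["nCattle"]),
                        n_buffalo=int(row["nBuffalo"]),
                        enrolment_days=int(row["enrolmentDays"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                errors.append(f"{path} line {lineno}: {exc}")
    return herds, errors


def write_herds(herds: list[Herd], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=HERD_COLUMNS)
        writer.writeheader()
        for h in herds:
            writer.writerow(
                {
                    "herdId": h.herd_id,
                    "herdType": h.herd_type.value,
                    "nCattle": h.n_cattle,
                    "nBuffalo": h.n_buffalo,
                    "enrolmentDays": h.enrolment_days,
                }
            )


# -- reconciliation --------------------------------------------------------

def _dd_mass_per_quantity(catalogue: Catalogue, product_id: str) -> float:
    """mg of the dose-determining substance per mL/unit of product."""
    product = catalogue.product(product_id)
    comp = resolve_dose_determining(product)
    return catalogue._mass_per_quantity(comp)


def match_cells(
    a: dict[tuple, float], b: dict[tuple, float], tolerance: float
) -> tuple[set, set, set]:
    """Symmetric cell matcher: keys with masses within relative tolerance.

    Returns (matched, a_only, b_only) key sets; a key present on both sides
    but with masses differing by more than ``tolerance`` x max(mass) lands
    in both a_only and b_only (each stream asserts an unmatched quantity).
    """
    matched, a_only, b_only = set(), set(), set()
    for key in set(a) | set(b):
        ma, mb = a.get(key), b.get(key)
        if ma is None:
            b_only.add(key)
        elif mb is None:
            a_only.add(key)
        elif abs(ma - mb) <= tolerance * max(ma, mb):
            matched.add(key)
        else:
            a_only.add(key)
            b_only.add(key)
    return matched, a_only, b_only


def reconcile(
    events: list[TreatmentEvent],
    deposits: list[BinDeposit],
    catalogue: Catalogue,
    *,
    tolerance: float = 0.05,
) -> ReconciliationReport:
    """Compare the two streams per herd x month x product.

    History-implied mass is quantityUsed x concentration summed over events;
    bin-implied mass is emptiesCount x unitSize x concentration (of the
    dose-determining substance in both cases). Cells agreeing within the
    relative ``tolerance`` corroborate their events; the report carries the
    absolute mass discrepancy per product. Discrepancies are not errors.
    """
    hist: dict[tuple, float] = {}
    events_per_cell: dict[tuple, int] = {}
    for e in events:
        key = (e.herd_id, e.month, e.product_id)
        hist[key] = hist.get(key, 0.0) + e.quantity_used * _dd_mass_per_quantity(
            catalogue, e.product_id
        )
        events_per_cell[key] = events_per_cell.get(key, 0) + 1

    binned: dict[tuple, float] = {}
    deposits_per_cell: dict[tuple, int] = {}
    for d in deposits:
        key = (d.herd_id, d.month, d.product_id)
        product = catalogue.product(d.product_id)
        mass = (
            d.empties_count
            * product.unit_size
            * _dd_mass_per_quantity(catalogue, d.product_id)
        )
        binned[key] = binned.get(key, 0.0) + mass
        deposits_per_cell[key] = deposits_per_cell.get(key, 0) + 1

    matched_keys, hist_keys, bin_keys = match_cells(hist, binned, tolerance)

    report = ReconciliationReport()
    report.matched = sum(events_per_cell[k] for k in matched_keys)
    report.history_only = sum(events_per_cell[k] for k in hist_keys)
    report.bin_only = sum(deposits_per_cell[k] for k in bin_keys)
    for key in set(hist) | set(binned):
        product_id = key[2]
        diff = abs(hist.get(key, 0.0) - binned.get(key, 0.0))
        report.mass_discrepancy_mg[product_id] = (
            report.mass_discrepancy_mg.get(product_id, 0.0) + diff
        )
    return report
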