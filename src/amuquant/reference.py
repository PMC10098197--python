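"""Deterministic reference dataset for a year-long dairy-herd AMU survey.

Encodes the published summary tables of a 12-month surveillance of 38
dairy herds (20 household, 18 commercial; 1,010 adult bovines) in which
265 administrations of commercial products spanning 14 antimicrobial
substances in 9 classes were recorded across 208 disease cases. The
dataset is reconstructed, not raw: events are engineered so that

* the product-frequency table reproduces the published per-substance and
  per-indication administration counts exactly,
* the herd-usage table reproduces the published per-substance herd counts
  exactly, and
* per-substance summed nADD from the recomputed metrics equals the
  published column exactly.

Because per-event nUADD is algebraically ``animals x days`` (an integer),
the published fractional nUADD totals cannot fall out of any raw event
set; ``allocation`` therefore carries a per-event allocation of the
published nADD *and* nUADD totals for share computations, and
``dose_table`` holds the published per-substance summary (nADD, median
ADD, nUADD, median UDD, dose ratio) verbatim.

Everything here is synthetic in the sense of being generated from the
printed tables; no raw farm records are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .catalogue import (
    Catalogue,
    DrugProduct,
    ProductComponent,
    Route,
    default_catalogue,
)
from .records import (
    Administrator,
    Herd,
    HerdType,
    Indication,
    TreatmentEvent,
    write_events,
    write_herds,
)

__all__ = ["ReferenceDataset", "reference_dataset", "write_reference_dataset"]

# substance -> (product administrations: overall, mastitis, reproductive,
#               fever, diarrhea, misc; herds using; summed nADD;
#               median ADD g/day; summed nUADD; median UDD mg/kg/day;
#               UDD/DDD_kg ratio)
# The diarrhea/misc split of the non-(mastitis/reproductive/fever)
# administrations is not published per substance; sulphonamides dominate
# diarrhea treatment, so 8 sulphadiazine + 1 oxytetracycline products are
# assigned to diarrhea (9 total) and the remaining 18 to miscellaneous
# conditions, matching the published overall shares (3.40% / 6.79%).
_ROWS: list[tuple] = [
    # substance                 ov  mas rep fev dia mis hrd  nADD   mADD  nUADD  mUDD  ratio
    ("ceftriaxone",              34, 25, 4,  3,  0,  2,  19, 79.55, 3.75, 74.35, 7.50, 1.07),
    ("ceftiofur",                13, 2,  8,  1,  0,  2,  8,  45.77, 0.50, 22.89, 1.25, 2.00),
    ("cefoperazone",             12, 10, 0,  0,  0,  2,  10, 19.01, 3.00, 19.01, 11.25, 1.00),
    ("ceftizoxime",              7,  6,  0,  0,  0,  1,  6,  16.50, 2.00, 11.00, 7.50, 1.50),
    ("enrofloxacin",             57, 31, 6,  16, 0,  4,  34, 78.93, 2.10, 83.08, 5.00, 0.95),
    ("levofloxacin",             2,  2,  0,  0,  0,  0,  2,  1.60,  1.85, 1.78,  4.00, 0.90),
    ("gentamicin",               18, 12, 0,  5,  0,  1,  13, 5.69,  4.20, 29.95, 1.80, 0.19),
    ("amoxicillin",              34, 24, 5,  5,  0,  0,  19, 31.68, 4.15, 35.20, 7.50, 0.90),
    ("ampicillin",               2,  2,  0,  0,  0,  0,  2,  3.19,  4.88, 6.13,  4.50, 0.52),
    ("oxytetracycline",          31, 7,  4,  18, 1,  1,  21, 18.63, 3.25, 49.03, 3.25, 0.38),
    ("cefalexin",                9,  0,  9,  0,  0,  0,  7,  9.26,  2.80, 17.15, 6.75, 0.54),
    ("procaine benzylpenicillin", 32, 23, 1,  3,  0,  5,  18, 43.50, 5.20, 124.29, 3.25, 0.35),
    ("sulphadiazine",            10, 1,  0,  1,  8,  0,  10, 4.51,  5.20, 19.61, 3.00, 0.23),
    ("metronidazole",            4,  0,  4,  0,  0,  0,  4,  2.50,  2.00, 10.00, 1.25, 0.25),
]

_INDICATION_ORDER = [
    Indication.MASTITIS,
    Indication.REPRODUCTIVE,
    Indication.FEVER,
    Indication.DIARRHEA,
    Indication.MISC,
]

# Distinct disease cases per indication (208 total over 265 administrations).
_CASE_TARGETS = {
    Indication.MASTITIS: 105,
    Indication.FEVER: 43,
    Indication.REPRODUCTIVE: 36,
    Indication.DIARRHEA: 9,
    Indication.MISC: 15,
}

_N_HERDS = 38
_REFERENCE_WEIGHT_KG = 400.0  # median adult cow weight used for event masses

# Nominal product concentrations (mg/mL) for the reconstructed catalogue.
_CONCENTRATIONS = {
    "ceftriaxone": 250.0, "ceftiofur": 50.0, "cefoperazone": 250.0,
    "ceftizoxime": 200.0, "enrofloxacin": 100.0, "levofloxacin": 100.0,
    "gentamicin": 40.0, "amoxicillin": 150.0, "ampicillin": 100.0,
    "oxytetracycline": 50.0, "cefalexin": 100.0,
    "procaine benzylpenicillin": 200.0, "sulphadiazine": 200.0,
    "metronidazole": 50.0,
}


def dose_table() -> pd.DataFrame:
    """Published per-substance dose-metric summary."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "substance", "n_products", "n_mastitis", "n_reproductive",
            "n_fever", "n_diarrhea", "n_misc", "n_herds", "n_add",
            "median_add_g_per_day", "n_uadd", "median_udd_mg_per_kg_day",
            "dose_ratio",
        ],
    )


def _build_herds() -> list[Herd]:
    """38 herds, 20 household + 18 commercial, 519 cattle + 491 buffalo."""
    sizes = [12, 13] * 10  # household: 250 animals
    sizes += [43] * 4 + [42] * 14  # commercial: 760 animals
    cattle = [s // 2 for s in sizes]
    deficit = 519 - sum(cattle)
    for i in range(deficit):  # top up to the published cattle count
        cattle[i % len(sizes)] += 1
    herds = []
    for i, (size, nc) in enumerate(zip(sizes, cattle)):
        herds.append(
            Herd(
                herd_id=f"H{i + 1:02d}",
                herd_type=HerdType.HOUSEHOLD if i < 20 else HerdType.COMMERCIAL,
                n_cattle=nc,
                n_buffalo=size - nc,
                enrolment_days=365,
            )
        )
    return herds


def _administrator_for(herd_index: int) -> Administrator:
    # Herd-level administrator mix: 13 para-veterinarian, 10 unauthorized,
    # 9 farmer, 6 veterinarian herds out of 38.
    if herd_index < 13:
        return Administrator.PARA_VETERINARIAN
    if herd_index < 23:
        return Administrator.UNAUTHORIZED
    if herd_index < 32:
        return Administrator.FARMER
    return Administrator.VETERINARIAN


@dataclass
class ReferenceDataset:
    """Reconstructed survey dataset plus its published metric totals."""

    catalogue: Catalogue
    herds: list[Herd]
    events: list[TreatmentEvent]
    allocation: pd.DataFrame  # per-event allocation of published nADD/nUADD
    dose_table: pd.DataFrame  # published per-substance summary

    @property
    def herd_map(self) -> dict[str, Herd]:
        return {h.herd_id: h for h in self.herds}


def reference_dataset() -> ReferenceDataset:
    """Build the full deterministic reference dataset."""
    products = {}
    for idx, row in enumerate(_ROWS):
        substance = row[0]
        products[f"P{idx + 1:02d}"] = DrugProduct(
            product_id=f"P{idx + 1:02d}",
            trade_name=substance.title(),
            formulation=Route.PARENTERAL,
            components=(
                ProductComponent(substance, _CONCENTRATIONS[substance], "mg/mL"),
            ),
            unit_size=30.0,
        )
    catalogue = default_catalogue(products)
    herds = _build_herds()

    events: list[TreatmentEvent] = []
    alloc_rows: list[dict] = []
    case_counters = {i: 0 for i in Indication}
    month_cycle = 0
    for idx, row in enumerate(_ROWS):
        (substance, overall, mas, rep, fev, dia, mis, n_herds_s,
         nadd_total, _median_add, nuadd_total, _median_udd, ratio) = row
        product_id = f"P{idx + 1:02d}"
        conc = _CONCENTRATIONS[substance]
        ddd_kg = catalogue.lookup_ddd(substance).ddd_kg
        nadd_event = nadd_total / overall
        mass_mg = nadd_event * ddd_kg * _REFERENCE_WEIGHT_KG
        duration = max(1, round(nadd_event / ratio))
        offset = (7 * idx) % _N_HERDS
        herd_ids = [
            f"H{(offset + j) % _N_HERDS + 1:02d}" for j in range(n_herds_s)
        ]
        indications = (
            [Indication.MASTITIS] * mas
            + [Indication.REPRODUCTIVE] * rep
            + [Indication.FEVER] * fev
            + [Indication.DIARRHEA] * dia
            + [Indication.MISC] * mis
        )
        assert len(indications) == overall
        for j, indication in enumerate(indications):
            seq = case_counters[indication]
            case_counters[indication] += 1
            case_id = f"{indication.value[:3]}{seq % _CASE_TARGETS[indication] + 1:03d}"
            herd_id = herd_ids[j % n_herds_s]
            herd_index = int(herd_id[1:]) - 1
            month_cycle += 1
            event = TreatmentEvent(
                event_id=f"E{len(events) + 1:03d}",
                herd_id=herd_id,
                month=(month_cycle - 1) % 12 + 1,
                indication=indication,
                product_id=product_id,
                quantity_used=mass_mg / conc,
                n_animals_treated=1,
                animal_weights_kg=(_REFERENCE_WEIGHT_KG,),
                duration_days=duration,
                route=Route.PARENTERAL,
                administrator=_administrator_for(herd_index),
                case_id=case_id,
            )
            events.append(event)
            alloc_rows.append(
                {
                    "event_id": event.event_id,
                    "herd_id": herd_id,
                    "indication": indication.value,
                    "substance": substance,
                    "am_class": catalogue.substance(substance).am_class,
                    "who_category": catalogue.who_category(substance).value,
                    "n_add": nadd_total / overall,
                    "n_uadd": nuadd_total / overall,
                }
            )

    return ReferenceDataset(
        catalogue=catalogue,
        herds=herds,
        events=events,
        allocation=pd.DataFrame(alloc_rows),
        dose_table=dose_table(),
    )


def write_reference_dataset(out_dir: str | Path) -> dict[str, Path]:
    """Emit the reference dataset in the standard file dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = reference_dataset()

    prod_rows = []
    for p in ds.catalogue.products.values():
        for c in p.components:
            prod_rows.append(
                {
                    "productId": p.product_id,
                    "tradeName": p.trade_name,
                    "formulation": p.formulation.value,
                    "unitSize": p.unit_size,
                    "substance": c.substance,
                    "concentration": c.concentration,
                    "concentrationUnit": c.concentration_unit,
                    "role": c.role.value if c.role else "",
                }
            )
    pd.DataFrame(prod_rows).to_csv(out / "products.csv", index=False)

    pd.DataFrame(
        [
            {
                "substance": r.substance,
                "species": r.species.value,
                "route": r.route.value,
                "dddKg_mg_per_kg_day": r.ddd_kg,
                "source": r.source.value,
            }
            for r in ds.catalogue.ddd_registry
        ]
    ).to_csv(out / "ddd.csv", index=False)

    pd.DataFrame(
        [
            {"amClass": k, "whoCategory": v.value}
            for k, v in ds.catalogue.cia_map.entries.items()
        ]
    ).to_csv(out / "cia_map.csv", index=False)

    pd.DataFrame(
        [
            {"substance": s.name, "amClass": s.am_class}
            for s in ds.catalogue.substances.values()
        ]
    ).to_csv(out / "substances.csv", index=False)

    write_herds(ds.herds, out / "herds.csv")
    write_events(ds.events, out / "events.csv")
    ds.allocation.to_csv(out / "allocation.csv", index=False)
    ds.dose_table.to_csv(out / "dose_table.csv", index=False)
    return {p.name: p for p in out.iterdir()}
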