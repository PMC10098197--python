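"""Synthetic herd-year generator with known ground truth.

Emulates the observed structure of a year of AMU surveillance on mixed
cattle/buffalo dairy herds: 20 household (5-20 animals) and 18 commercial
(>20 animals) herds totalling ~1,010 adults, ~208 disease cases per year
with the observed indication mix, ~1.27 product administrations per case
with indication-specific substance choice, per-substance dosing-behaviour
multipliers (target UDD/DDD_kg ratios), and a configurable probability
that an emptied vial actually reaches the farm bin.

What it does NOT emulate: disease transmission dynamics, seasonality,
within-herd correlation of treatments, combination products, or
intramammary dosing (all administrations are parenteral, as the bulk of
the surveyed ones were). Quantities are snapped to whole vials, which is
the only source of discrepancy between intended and administered dose.

Every drawn quantity is recorded in :class:`GroundTruth`, so pipeline
estimates can be checked against the generating truth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .catalogue import (
    Catalogue,
    DrugProduct,
    ProductComponent,
    Route,
    default_catalogue,
)
from .errors import AmuError
from .records import (
    Administrator,
    Animal,
    BinDeposit,
    Herd,
    HerdType,
    Indication,
    TreatmentEvent,
    write_bin_deposits,
    write_events,
    write_herds,
)
from .reference import _CONCENTRATIONS, _ROWS

__all__ = [
    "WeightDistribution",
    "SimulationConfig",
    "GroundTruth",
    "generate_population",
    "generate_treatments",
    "simulation_catalogue",
    "write_dataset",
]


@dataclass(frozen=True)
class WeightDistribution:
    """Adult bodyweight summarized by min/median/mean/max, realized as a
    Beta distribution scaled to [min, max] with shapes fitted to match the
    stated median and mean as closely as the family allows."""

    min_kg: float
    median_kg: float
    mean_kg: float
    max_kg: float

    def shapes(self) -> tuple[float, float]:
        return _fit_beta_shapes(
            (self.median_kg - self.min_kg) / (self.max_kg - self.min_kg),
            (self.mean_kg - self.min_kg) / (self.max_kg - self.min_kg),
        )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = self.shapes()
        return self.min_kg + (self.max_kg - self.min_kg) * rng.beta(a, b, size=n)


@lru_cache(maxsize=None)
def _fit_beta_shapes(median_unit: float, mean_unit: float) -> tuple[float, float]:
    """Least-squares fit of Beta shapes to a unit-interval median and mean.

    Shapes are constrained to >= 1 (unimodal); without that bound the
    optimizer can collapse to a degenerate two-point distribution at the
    interval endpoints. A stated median/mean pair can be unattainable
    jointly within the unimodal family, so the median (the distribution's
    tested invariant) is weighted more heavily than the mean.
    """

    def loss(log_ab: np.ndarray) -> float:
        a, b = np.exp(log_ab)
        mean = a / (a + b)
        median = stats.beta.ppf(0.5, a, b)
        return (median - median_unit) ** 2 + 0.25 * (mean - mean_unit) ** 2

    res = optimize.minimize(
        loss,
        x0=np.log([2.0, 2.0]),
        method="Nelder-Mead",
        bounds=[(0.0, 10.0), (0.0, 10.0)],  # shapes in [1, e^10]
    )
    a, b = np.exp(res.x)
    return float(a), float(b)


_INDICATION_MIX = {
    Indication.MASTITIS: 0.5048,
    Indication.FEVER: 0.2067,
    Indication.REPRODUCTIVE: 0.1731,
    Indication.DIARRHEA: 0.0432,
    Indication.MISC: 0.0722,
}

_ADMIN_MIX = {
    Administrator.PARA_VETERINARIAN: 0.3421,
    Administrator.UNAUTHORIZED: 0.2632,
    Administrator.FARMER: 0.2368,
    Administrator.VETERINARIAN: 0.1579,
}

# Indication-specific substance-choice weights, from the surveyed
# per-indication administration counts.
def _default_substance_weights() -> dict[Indication, dict[str, float]]:
    cols = {
        Indication.MASTITIS: 2,
        Indication.REPRODUCTIVE: 3,
        Indication.FEVER: 4,
        Indication.DIARRHEA: 5,
        Indication.MISC: 6,
    }
    out: dict[Indication, dict[str, float]] = {}
    for ind, col in cols.items():
        weights = {row[0]: float(row[col]) for row in _ROWS if row[col] > 0}
        out[ind] = weights
    return out


def _default_dose_ratio_targets() -> dict[str, float]:
    """Per-substance dosing-behaviour multipliers = observed UDD/DDD ratios."""
    return {row[0]: float(row[12]) for row in _ROWS}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic herd-year."""

    n_household_herds: int = 20
    n_commercial_herds: int = 18
    household_size_range: tuple[int, int] = (5, 20)
    commercial_size_range: tuple[int, int] = (21, 64)
    cattle_share: float = 519 / 1010
    cattle_weight: WeightDistribution = field(
        default_factory=lambda: WeightDistribution(300, 400, 421, 520)
    )
    buffalo_weight: WeightDistribution = field(
        default_factory=lambda: WeightDistribution(425, 500, 525, 650)
    )
    period_days: int = 365
    expected_total_cases: float = 208.0
    indication_mix: dict[Indication, float] = field(
        default_factory=lambda: dict(_INDICATION_MIX)
    )
    substance_weights: dict[Indication, dict[str, float]] = field(
        default_factory=_default_substance_weights
    )
    dose_ratio_targets: dict[str, float] = field(
        default_factory=_default_dose_ratio_targets
    )
    dose_noise_sigma: float = 0.05  # lognormal sigma; median unaffected
    administrator_mix: dict[Administrator, float] = field(
        default_factory=lambda: dict(_ADMIN_MIX)
    )
    commercial_rate_multiplier: float = 1.5
    extra_products_per_case: float = 265 / 208 - 1  # Poisson excess
    treated_excess: float = 0.15  # Poisson excess over 1 animal per event
    duration_range: tuple[int, int] = (2, 5)
    bin_compliance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bin_compliance <= 1.0:
            raise AmuError("binCompliance must be within [0, 1]")
        mix_sum = sum(self.indication_mix.values())
        if abs(mix_sum - 1.0) > 1e-6:
            raise AmuError(f"indication mix sums to {mix_sum}, expected 1")
        if min(self.n_household_herds, self.n_commercial_herds) < 0:
            raise AmuError("herd counts must be >= 0")
        lo, hi = self.household_size_range
        if not 5 <= lo <= hi <= 20:
            raise AmuError("household herds hold 5-20 animals")
        lo, hi = self.commercial_size_range
        if not 20 < lo <= hi:
            raise AmuError("commercial herds hold > 20 animals")


@dataclass
class GroundTruth:
    """Generating truth recorded alongside the emitted records."""

    total_mass_mg: dict[str, float] = field(default_factory=dict)
    deposited_mass_mg: dict[str, float] = field(default_factory=dict)
    dose_ratios: dict[str, list[float]] = field(default_factory=dict)
    indication_counts: dict[str, int] = field(default_factory=dict)
    herd_n_add: dict[str, float] = field(default_factory=dict)
    n_cases: int = 0
    n_events: int = 0

    def median_dose_ratio(self, substance: str) -> float:
        return float(np.median(self.dose_ratios[substance]))

    def to_json(self) -> str:
        payload = asdict(self)
        payload["median_dose_ratio"] = {
            s: self.median_dose_ratio(s) for s in self.dose_ratios
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulation_catalogue() -> Catalogue:
    """Catalogue of one single-substance parenteral product per substance.

    Vial sizes are scaled to roughly a quarter of a median-weight animal's
    daily dose, so whole-vial snapping perturbs administered quantities by
    only a few percent.
    """
    cat = default_catalogue()
    products = {}
    for idx, row in enumerate(_ROWS):
        substance = row[0]
        conc = _CONCENTRATIONS[substance]
        ddd_kg = cat.lookup_ddd(substance).ddd_kg
        unit_size = max(1.0, round(ddd_kg * 400.0 * 0.25 / conc))
        products[f"SP{idx + 1:02d}"] = DrugProduct(
            product_id=f"SP{idx + 1:02d}",
            trade_name=substance.title(),
            formulation=Route.PARENTERAL,
            components=(ProductComponent(substance, conc, "mg/mL"),),
            unit_size=unit_size,
        )
    return default_catalogue(products)


@dataclass
class Population:
    herds: list[Herd]
    animals: list[Animal]

    @property
    def animals_by_herd(self) -> dict[str, list[Animal]]:
        out: dict[str, list[Animal]] = {}
        for a in self.animals:
            out.setdefault(a.herd_id, []).append(a)
        return out


def generate_population(
    config: SimulationConfig, seed: int
) -> tuple[list[Herd], list[Animal]]:
    """Draw herds and animals; deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    herds: list[Herd] = []
    animals: list[Animal] = []
    specs = [(HerdType.HOUSEHOLD, config.household_size_range)] * (
        config.n_household_herds
    ) + [(HerdType.COMMERCIAL, config.commercial_size_range)] * (
        config.n_commercial_herds
    )
    for i, (htype, (lo, hi)) in enumerate(specs):
        size = int(rng.integers(lo, hi + 1))
        n_cattle = int(rng.binomial(size, config.cattle_share))
        # herds need at least one animal of some species; binomial guarantees 0<=n<=size
        herd = Herd(f"H{i + 1:02d}", htype, n_cattle, size - n_cattle)
        herds.append(herd)
        cattle_w = config.cattle_weight.sample(rng, n_cattle)
        buffalo_w = config.buffalo_weight.sample(rng, size - n_cattle)
        for j, w in enumerate(list(cattle_w) + list(buffalo_w)):
            species = "CATTLE" if j < n_cattle else "BUFFALO"
            animals.append(
                Animal(f"{herd.herd_id}-A{j + 1:03d}", herd.herd_id, species, float(w))
            )
    return herds, animals


def _weighted_choice(rng, weights: dict) -> object:
    keys = list(weights)
    probs = np.asarray([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_treatments(
    population: tuple[list[Herd], list[Animal]] | Population,
    config: SimulationConfig,
    seed: int,
    *,
    catalogue: Catalogue | None = None,
) -> tuple[list[TreatmentEvent], list[BinDeposit], GroundTruth]:
    """Draw a year of treatment events and bin deposits with ground truth.

    Disease cases arrive Poisson per herd with rate proportional to herd
    size (commercial herds scaled by ``commercial_rate_multiplier``),
    calibrated so the expected total equals ``expected_total_cases``. Each
    case emits one or more product administrations; the administered dose
    targets ``DDD_kg x dose_ratio_target(substance)`` per kg per day with
    multiplicative lognormal noise, then snaps to whole vials.
    """
    if isinstance(population, tuple):
        population = Population(*population)
    herds, animals = population.herds, population.animals
    if not animals:
        raise AmuError("generate_treatments: empty population")
    catalogue = catalogue or simulation_catalogue()
    rng = np.random.default_rng(seed)
    by_herd = population.animals_by_herd
    product_of = {
        resolve.substance: pid
        for pid, prod in catalogue.products.items()
        for resolve in [catalogue.dose_determining(pid)]
    }

    mults = {
        h.herd_id: (
            config.commercial_rate_multiplier
            if h.herd_type is HerdType.COMMERCIAL
            else 1.0
        )
        for h in herds
    }
    weight_total = sum(mults[h.herd_id] * h.n_animals for h in herds)
    base = config.expected_total_cases / weight_total  # cases per animal-year

    truth = GroundTruth()
    events: list[TreatmentEvent] = []
    bin_cells: dict[tuple, int] = {}
    admins = {
        h.herd_id: _weighted_choice(rng, config.administrator_mix) for h in herds
    }

    for herd in herds:
        lam = base * mults[herd.herd_id] * herd.n_animals * (
            config.period_days / 365.0
        )
        n_cases = int(rng.poisson(lam))
        herd_animals = by_herd[herd.herd_id]
        for _ in range(n_cases):
            truth.n_cases += 1
            case_id = f"C{truth.n_cases:04d}"
            indication = _weighted_choice(rng, config.indication_mix)
            truth.indication_counts[indication.value] = (
                truth.indication_counts.get(indication.value, 0) + 1
            )
            month = int(rng.integers(1, 13))
            n_admin = 1 + int(rng.poisson(config.extra_products_per_case))
            for _ in range(n_admin):
                substance = _weighted_choice(
                    rng, config.substance_weights[indication]
                )
                product = catalogue.product(product_of[substance])
                conc = product.components[0].concentration
                ddd_kg = catalogue.lookup_ddd(substance).ddd_kg
                n_treated = min(
                    1 + int(rng.poisson(config.treated_excess)), len(herd_animals)
                )
                chosen = rng.choice(len(herd_animals), size=n_treated, replace=False)
                weights = tuple(
                    round(herd_animals[int(k)].weight_kg, 1) for k in chosen
                )
                mean_w = sum(weights) / len(weights)
                lo_d, hi_d = config.duration_range
                duration = int(rng.integers(lo_d, hi_d + 1))
                target_udd = (
                    ddd_kg
                    * config.dose_ratio_targets[substance]
                    * float(rng.lognormal(0.0, config.dose_noise_sigma))
                )
                intended_mass = target_udd * n_treated * mean_w * duration
                vials = max(1, round(intended_mass / conc / product.unit_size))
                quantity = vials * product.unit_size
                mass = quantity * conc

                truth.n_events += 1
                event = TreatmentEvent(
                    event_id=f"SE{truth.n_events:04d}",
                    herd_id=herd.herd_id,
                    month=month,
                    indication=indication,
                    product_id=product.product_id,
                    quantity_used=quantity,
                    n_animals_treated=n_treated,
                    animal_weights_kg=weights,
                    duration_days=duration,
                    route=Route.PARENTERAL,
                    administrator=admins[herd.herd_id],
                    case_id=case_id,
                )
                events.append(event)

                truth.total_mass_mg[substance] = (
                    truth.total_mass_mg.get(substance, 0.0) + mass
                )
                udd_actual = mass / (n_treated * mean_w * duration)
                truth.dose_ratios.setdefault(substance, []).append(
                    udd_actual / ddd_kg
                )
                truth.herd_n_add[herd.herd_id] = truth.herd_n_add.get(
                    herd.herd_id, 0.0
                ) + mass / (ddd_kg * mean_w)

                if rng.random() < config.bin_compliance:
                    key = (herd.herd_id, month, product.product_id)
                    bin_cells[key] = bin_cells.get(key, 0) + vials
                    truth.deposited_mass_mg[substance] = (
                        truth.deposited_mass_mg.get(substance, 0.0) + mass
                    )

    deposits = [
        BinDeposit(herd_id, month, product_id, count)
        for (herd_id, month, product_id), count in sorted(bin_cells.items())
    ]
    return events, deposits, truth


def write_dataset(
    out_dir: str | Path, config: SimulationConfig, seed: int
) -> dict[str, Path]:
    """Generate a complete synthetic dataset and write every file dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    herds, animals = generate_population(config, seed)
    catalogue = simulation_catalogue()
    events, deposits, truth = generate_treatments(
        (herds, animals), config, seed + 1, catalogue=catalogue
    )

    prod_rows = [
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
        for p in catalogue.products.values()
        for c in p.components
    ]
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
            for r in catalogue.ddd_registry
        ]
    ).to_csv(out / "ddd.csv", index=False)
    pd.DataFrame(
        [
            {"amClass": k, "whoCategory": v.value}
            for k, v in catalogue.cia_map.entries.items()
        ]
    ).to_csv(out / "cia_map.csv", index=False)
    write_herds(herds, out / "herds.csv")
    write_events(events, out / "events.csv")
    write_bin_deposits(deposits, out / "bins.csv")
    (out / "ground_truth.json").write_text(truth.to_json())
    return {p.name: p for p in out.iterdir()}
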