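# Methods note

## Scope

`amuquant` quantifies antibiotic use on dairy farms from
treatment-history records: per-event dose metrics, WHO importance
categorization, dosing-adequacy verdicts, and herd-level summary tables,
with a synthetic generator for validation. It covers adult bovines
(cattle and buffalo) and the parenteral and intramammary routes.

## Dose-metric model

For a treatment event with total active mass `M` (mg), `n` treated
animals of mean bodyweight `w̄` (kg), duration `d` days, and a defined
daily dose `DDD_kg` (mg/kg/day) for the dose-determining substance:

| metric | definition | units |
|---|---|---|
| ADD | `DDD_kg × w̄ / 1000` | g/day |
| nADD | `(M / 1000) / ADD` | doses |
| UDD | `M / (n × w̄ × d)` | mg/kg/day |
| UADD | `UDD × w̄` | mg/day |
| nUADD | `M / UADD = n × d` | doses |
| dose ratio | `UDD / DDD_kg` | — |
| ADUR | `nADD × 1000 / animal-days` | ADD per 1,000 animal-days |

For intramammary products the daily dose is `MG × U × F` (mg active per
syringe × syringes per administration × administrations per day), with
`U` derived from the recorded quantity as `quantity / (n × d × F)`.

Dosing adequacy classifies the dose ratio against a band with inclusive
edges, default `[0.8, 1.2]`: UNDER below, CORRECT within, OVER above.

Per-event nUADD equals `n × d` exactly because the same mean weight
enters UDD and UADD. Consequently a dataset-level nUADD total that is
not an integer cannot be produced by any raw event set; the reference
dataset therefore carries its published fractional per-substance nUADD
totals in a separate per-event `allocation` frame used only for share
computations, while nADD is fully recomputed from events.

## Catalogue

Products carry one or more active components with concentrations in
mg/mL, mg/unit or IU/mL (IU converted at a configurable factor,
default 1,598 IU/mg for benzylpenicillin). The dose-determining
substance of a combination is resolved by rule (explicit annotation;
trimethoprim–sulphonamide → trimethoprim; β-lactam + inhibitor →
β-lactam; penicillin + salt partner → penicillin), otherwise the
combination is rejected as ambiguous. DDD lookups prefer an exact
species match, then fall back to a generic bovine entry.

Most shipped `DDD_kg` values are back-calculated as published median UDD
divided by published UDD/DDD ratio and tagged `BACKCALC`; they are
registry defaults, not label claims, and can be replaced via `ddd.csv`.

## Reference dataset

`fixtures/` (and `amuquant.reference`) reconstructs a 38-herd,
12-month survey from its published summary tables: per-substance
administration counts by indication, herd-usage counts, summed nADD and
nUADD, median UDD and dose ratios. Events are engineered so the pipeline
reproduces the published counts and summed nADD exactly; per-event
amounts, durations, herd assignments and months are constructed, not
observed. Published percentages were printed with occasional truncation
(e.g. 54/265 = 20.377 printed as 20.37), so tests assert counts exactly
and percentages to ±0.01.

## Synthetic generator

- **Population.** Herd counts and size ranges per type (household 5–20,
  commercial >20 animals); species assigned binomially at the configured
  cattle share; bodyweights drawn from a Beta distribution scaled to
  [min, max] with shapes fitted to the stated median and mean. The
  shapes are constrained to ≥1 (unimodal) — without that bound the
  fit can collapse to a two-point distribution at the endpoints — and
  the median is weighted more heavily than the mean because a given
  median/mean pair may be jointly unattainable within the unimodal
  family.
- **Cases.** Disease cases arrive Poisson per herd with rate
  proportional to herd size, commercial herds scaled by a configurable
  multiplier (default 1.5), calibrated so the expected total equals the
  configured value (default 208 per 38 herds per 365 days). Indications
  follow a configurable mix; substances follow per-indication weights.
- **Doses.** The administered dose targets
  `DDD_kg × dose-ratio target` per kg/day with multiplicative
  lognormal noise (σ = 0.05, median-preserving; chosen so the
  median-recovery standard error stays well inside a ±0.05 tolerance at
  realistic per-substance event counts), then snaps to whole vials.
  Vial sizes are about a quarter of a median-weight animal's daily dose
  so snapping perturbs quantities by only a few percent.
- **Bins.** Each event's empties reach the bin with probability
  `bin_compliance`; ground truth records true masses, dose ratios,
  case counts and per-herd nADD for recovery tests.

All draws come from a single integer-seeded `numpy` generator; output is
fully deterministic under a fixed seed.

## Numerical choices

- Percentages are rounded half-up (decimal) to 2 dp in the aggregate
  layer only; metrics carry full precision.
- The household-vs-commercial contrast is a Welch two-sample t-test on
  per-herd summed nADD, with treated-but-untreated enrolled herds
  contributing zeros; identical constant samples report t = 0, p = 1.
- ADUR supports a pooled denominator (period × total animals) or
  per-herd rates summarized by mean and median.
- CSV round-trips use `repr`-formatted floats so write→read→write is
  byte-stable.

## Limitations

- The reference dataset is a reconstruction from summary tables; any
  quantity not pinned by those tables (event-level amounts, durations,
  months, herd assignment details) is conventional and should not be
  read as observed data.
- Fractional published nUADD totals are carried, not re-derived (see
  above); per-indication herd-usage columns are not reproduced where the
  published marginals are mutually inconsistent — only overall herd
  counts are asserted.
- Herd-level drug-use-rate magnitudes and the original between-herd-type
  significance level depend on unpublished raw data; the generator's
  power check (commercial usage +50% detected at p < 0.05 in ≥80% of
  seeds) replaces them.
- Back-calculated DDD values inherit the rounding of the published
  medians and ratios.
- The generator models usage structure, not disease transmission;
  incidence is a rate parameter.
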