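# amuquant

Farm-level antimicrobial-usage (AMU) quantification for dairy herds:
dose-based metrics, WHO importance categorization, dosing-adequacy
classification, herd-level summaries, and a calibrated synthetic-data
generator for end-to-end validation.

## Background

Weight-based dose metrics make antibiotic use comparable across farms,
products and species. For each treatment event (one product administered
to one or more animals over a course of days) the pipeline computes:

- **ADD** (animal daily dose, g/day): `DDD_kg × bodyweight / 1000` — the
  expected daily dose for the treated animal, from the labelled defined
  daily dose `DDD_kg` (mg per kg per day).
- **nADD**: total active mass used divided by ADD — how many
  animal-daily-doses the used amount represents.
- **UDD** (used daily dose, mg/kg/day): the dose the farm actually gave,
  `mass / (animals × mean weight × days)`.
- **nUADD**: the number of used animal daily doses; algebraically equals
  animals × treatment days.
- **UDD/DDD ratio**: dosing adequacy, classified UNDER / CORRECT / OVER
  against a configurable band (default 0.8–1.2, inclusive).
- **ADUR**: antimicrobial drug use rate, nADD per 1,000 animal-days.

Substances are mapped to WHO medical-importance categories (highest
priority critically important, high priority critically important, highly
important, important), and events aggregate into frequency, herd-usage,
share-of-total, CIA and herd-type-comparison tables.

The package ships a deterministic **reference dataset** (`fixtures/`, and
`amuquant.reference`) reconstructing a 12-month surveillance of 38 Punjab
dairy herds — 20 household and 18 commercial herds, 1,010 adult bovines
(519 cattle, 491 buffalo), 265 antibiotic product administrations of 14
substances across 208 disease cases — from its published summary tables,
plus a **synthetic generator** (`amuquant.synthetic`) that draws whole
herd-years with known ground truth for parameter-recovery testing.

## Worked example

```python
from pathlib import Path
from amuquant import (
    cia_summary, compute_metrics, load_catalogue,
    product_frequency_table, read_events, read_herds, share_of_total,
)

fx = Path("fixtures")
catalogue = load_catalogue(fx / "products.csv", fx / "ddd.csv",
                           fx / "cia_map.csv", fx / "substances.csv")
herds, _ = read_herds(fx / "herds.csv")
events, _ = read_events(fx / "events.csv")

metrics = compute_metrics(events, catalogue,
                          herds={h.herd_id: h for h in herds})
print(share_of_total(metrics, "class", "nADD").head(3))
```

prints

```
                 group metric  value  pct_of_total
cephalosporins-3rd-gen   nADD 160.83         44.64
            quinolones   nADD  80.53         22.35
           penicillins   nADD  43.50         12.07
```

i.e. third-generation cephalosporins account for 44.64% and quinolones
for 22.35% of the 360.32 total animal daily doses. The frequency table
(`product_frequency_table(events, catalogue)`) shows enrofloxacin as the
most-administered substance (57 of 265 products, 21.51%), and
`cia_summary(events, catalogue)` categorizes 179 of 265 administrations
(67.55%) as WHO critically important antimicrobials — 125 (47.17%)
highest-priority and 54 (20.38%) high-priority. The narrative scripts in
`examples/` walk through quantification, simulation, dosing adequacy and
bin reconciliation.

## Command line

```bash
# end-to-end quantification
amuquant quantify --products fixtures/products.csv --ddd fixtures/ddd.csv \
    --cia fixtures/cia_map.csv --substances fixtures/substances.csv \
    --herds fixtures/herds.csv --events fixtures/events.csv --out reports/

# synthetic herd-year with ground truth
amuquant simulate --out simdata/ --seed 7

# re-aggregate stored metrics without recomputation
amuquant report --metrics reports/metrics.csv --herds fixtures/herds.csv \
    --out reports2/
```

Options can also come from a YAML config (`--config run.yaml`); CLI flags
take precedence over the file, which takes precedence over defaults.
Logs go to stderr; `reports/` gets the summary CSVs plus a JSON manifest
with the seed, option values and config hash.

## Reproduction

```bash
python -m pytest -q tests/              # full suite, ~10 s on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` re-derives every internally consistent
published percentage from the shipped fixtures through the real pipeline
and runs the property and parameter-recovery suites. The acceptance
script writes the headline computed quantities as
`{"<name>": {"value": ..., "n": ...}}`; all randomness derives from
`--seed`. `fixtures/` is byte-identical to the output of
`amuquant.reference.write_reference_dataset` (itself tested).

See `docs/methods.md` for the formal model, generator design and known
limitations.
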