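"""Quantify a year of antibiotic use in a 38-herd dairy survey.

Loads the reference dataset shipped in ``fixtures/`` (a reconstruction of
a 12-month surveillance of 38 Punjab dairy herds: 1,010 adult bovines,
265 antibiotic product administrations across 14 substances and 208
disease cases), pushes every treatment event through the dose-metric
chain, and prints the headline summary tables.
"""

from pathlib import Path

from amuquant import (
    cia_summary,
    compute_metrics,
    load_catalogue,
    product_frequency_table,
    read_events,
    read_herds,
    share_of_total,
)

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"

catalogue = load_catalogue(
    FIXTURES / "products.csv",
    FIXTURES / "ddd.csv",
    FIXTURES / "cia_map.csv",
    FIXTURES / "substances.csv",
)
herds, _ = read_herds(FIXTURES / "herds.csv")
events, errors = read_events(FIXTURES / "events.csv")
assert not errors

print(f"{len(events)} product administrations in {len(herds)} herds\n")

freq = product_frequency_table(events, catalogue)
print("== Products administered per substance ==")
print(freq[["substance", "n_products", "pct_products", "n_mastitis"]]
      .to_string(index=False))

metrics = compute_metrics(events, catalogue, herds={h.herd_id: h for h in herds})
print("\n== Share of total nADD (animal defined daily doses) ==")
print(share_of_total(metrics, "class", "nADD").to_string(index=False))

print("\n== WHO importance categories ==")
cia = cia_summary(events, catalogue)
print(cia[["who_category", "n_products", "pct_products"]].to_string(index=False))
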