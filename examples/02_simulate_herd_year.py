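"""Simulate a synthetic herd-year and recover its generating parameters.

Draws 38 herds with the configured size, species and weight structure,
generates a year of Poisson-arriving disease cases and treatments, then
runs the quantification pipeline on the emitted records and compares the
recovered quantities against the generator's ground truth.
"""

from amuquant import (
    SimulationConfig,
    compute_metrics,
    generate_population,
    generate_treatments,
    simulation_catalogue,
)

SEED = 2024

config = SimulationConfig()
catalogue = simulation_catalogue()
herds, animals = generate_population(config, seed=SEED)
events, deposits, truth = generate_treatments(
    (herds, animals), config, seed=SEED + 1, catalogue=catalogue
)

print(f"{len(herds)} herds, {len(animals)} animals")
print(f"{truth.n_cases} disease cases -> {len(events)} administrations\n")

metrics = compute_metrics(events, catalogue, herds={h.herd_id: h for h in herds})

print(f"{'substance':28s} {'true mass (g)':>14s} {'recovered (g)':>14s} "
      f"{'target ratio':>12s} {'median ratio':>12s}")
recovered_mass = metrics.groupby("substance")["total_mass_mg"].sum()
recovered_ratio = metrics.groupby("substance")["dose_ratio"].median()
for substance in sorted(truth.total_mass_mg):
    print(
        f"{substance:28s} {truth.total_mass_mg[substance] / 1000:14.2f} "
        f"{recovered_mass[substance] / 1000:14.2f} "
        f"{config.dose_ratio_targets[substance]:12.2f} "
        f"{recovered_ratio[substance]:12.2f}"
    )

mix = metrics.groupby("indication").size() / len(metrics)
print("\nIndication mix (share of administrations):")
for ind, share in mix.sort_values(ascending=False).items():
    print(f"  {ind:14s} {share:.3f}")
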