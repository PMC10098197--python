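"""Summary tables: frequency, herd usage, shares, WHO-CIA, herd-type test."""

import numpy as np
import pandas as pd
import pytest

from amuquant import (
    AmuError,
    Herd,
    HerdType,
    SimulationConfig,
    ValidationError,
    compute_metrics,
    condition_case_summary,
    generate_population,
    generate_treatments,
    herd_type_comparison,
    herd_usage_table,
    product_frequency_table,
    share_of_total,
    simulation_catalogue,
)
from amuquant.aggregate import adur_table, round_half_up


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(20.377, 20.38), (52.415, 52.42), (1.005, 1.01), (0.0, 0.0)]
    )
    def test_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestFrequency:
    def test_empty_events_give_empty_table(self, ref):
        assert product_frequency_table([], ref.catalogue).empty

    def test_column_percents_sum_to_100(self, ref):
        freq = product_frequency_table(ref.events, ref.catalogue)
        for col in ("pct_products", "pct_mastitis", "pct_fever"):
            assert freq[col].sum() == pytest.approx(100.0, abs=0.05)

    def test_totals_equal_event_count(self, ref):
        freq = product_frequency_table(ref.events, ref.catalogue)
        assert freq["n_products"].sum() == len(ref.events)


class TestHerdUsage:
    def test_substance_counts_once_per_herd(self, ref):
        single = [e for e in ref.events if e.herd_id == ref.events[0].herd_id][:2]
        table = herd_usage_table(single, ref.herds, ref.catalogue)
        assert (table["n_herds"] <= 1).all()

    def test_single_herd_single_event_is_100_pct(self, small_catalogue):
        from amuquant import Administrator, Indication, Route, TreatmentEvent

        event = TreatmentEvent(
            event_id="E1", herd_id="H01", month=1,
            indication=Indication.MASTITIS, product_id="ENRO",
            quantity_used=60.0, n_animals_treated=1,
            animal_weights_kg=(400.0,), duration_days=3,
            route=Route.PARENTERAL, administrator=Administrator.VETERINARIAN,
        )
        herds = [Herd("H01", HerdType.COMMERCIAL, 25, 0)]
        table = herd_usage_table([event], herds, small_catalogue)
        assert table.loc[0, "pct_herds"] == 100.0

    def test_unknown_herd_rejected(self, ref):
        with pytest.raises(ValidationError, match="unknown herd"):
            herd_usage_table(ref.events, ref.herds[:1], ref.catalogue)


class TestShares:
    def test_single_group_normalizes_to_100(self):
        df = pd.DataFrame(
            {"substance": ["enrofloxacin"] * 3, "n_add": [1.0, 2.0, 3.0]}
        )
        shares = share_of_total(df, "substance", "nADD")
        assert shares.loc[0, "pct_of_total"] == 100.0

    def test_invariant_under_uniform_rescaling(self, ref):
        a = share_of_total(ref.allocation, "substance", "nUADD")
        scaled = ref.allocation.assign(n_uadd=ref.allocation["n_uadd"] * 7.3)
        b = share_of_total(scaled, "substance", "nUADD")
        assert list(a["pct_of_total"]) == list(b["pct_of_total"])

    def test_zero_total_rejected(self):
        df = pd.DataFrame({"substance": ["x"], "n_add": [0.0]})
        with pytest.raises(AmuError, match="zero"):
            share_of_total(df, "substance", "nADD")

    def test_shares_sum_to_100(self, ref):
        for group in ("substance", "class", "whoCategory"):
            shares = share_of_total(ref.allocation, group, "nADD")
            assert shares["pct_of_total"].sum() == pytest.approx(100.0, abs=0.05)


class TestConditionCases:
    def test_no_events_empty_summary(self):
        assert condition_case_summary([]).empty

    def test_multiple_events_per_case_count_once(self, ref):
        summary = condition_case_summary(ref.events)
        assert summary["n_cases"].sum() == 208


class TestAdurTable:
    def test_pooled_rate_reduces_to_nadd_per_animal_days(self, ref):
        metrics = compute_metrics(
            ref.events, ref.catalogue, herds=ref.herd_map
        )
        table = adur_table(metrics, ref.herds, denominator="pooled")
        animal_days = 365 * sum(h.n_animals for h in ref.herds)
        row = table[table["substance"] == "ceftriaxone"].iloc[0]
        assert row["adur"] == pytest.approx(row["n_add"] * 1000 / animal_days)

    def test_herd_mode_reports_mean_and_median(self, ref):
        metrics = compute_metrics(ref.events, ref.catalogue, herds=ref.herd_map)
        table = adur_table(metrics, ref.herds, denominator="herd")
        assert {"mean_herd_adur", "median_herd_adur"} <= set(table.columns)
        assert (table["mean_herd_adur"] >= 0).all()

    def test_unknown_mode_rejected(self, ref):
        metrics = compute_metrics(ref.events[:5], ref.catalogue)
        with pytest.raises(AmuError, match="denominator"):
            adur_table(metrics, ref.herds, denominator="weekly")


class TestHerdTypeComparison:
    def _metrics(self, herds, values):
        return pd.DataFrame(
            {
                "herd_id": [h.herd_id for h in herds],
                "substance": "enrofloxacin",
                "n_add": values,
            }
        )

    def _herds(self, n_hh=3, n_com=3):
        return [
            Herd(f"HH{i}", HerdType.HOUSEHOLD, 10, 0) for i in range(n_hh)
        ] + [Herd(f"CM{i}", HerdType.COMMERCIAL, 30, 0) for i in range(n_com)]

    def test_identical_totals_give_zero_statistic(self):
        herds = self._herds()
        cmp = herd_type_comparison(self._metrics(herds, [5.0] * 6), herds)
        assert cmp.t_statistic == 0.0 and cmp.p_value == 1.0

    def test_single_type_rejected(self):
        herds = [Herd(f"HH{i}", HerdType.HOUSEHOLD, 10, 0) for i in range(4)]
        with pytest.raises(AmuError, match="commercial"):
            herd_type_comparison(self._metrics(herds, [1.0] * 4), herds)

    def test_commercial_shift_detected_in_most_seeds(self):
        """Power check: the default +50% commercial usage rate is detectable."""
        config = SimulationConfig()
        detected = 0
        n_runs = 20
        catalogue = simulation_catalogue()
        for seed in range(n_runs):
            herds, animals = generate_population(config, seed)
            events, _, _ = generate_treatments(
                (herds, animals), config, seed + 1000, catalogue=catalogue
            )
            metrics = compute_metrics(
                events, catalogue, herds={h.herd_id: h for h in herds}
            )
            cmp = herd_type_comparison(metrics, herds)
            detected += cmp.p_value < 0.05
            assert cmp.commercial_mean > cmp.household_mean
        assert detected >= 0.8 * n_runs

    def test_per_substance_breakdown_shape(self, ref):
        metrics = compute_metrics(ref.events, ref.catalogue, herds=ref.herd_map)
        cmp = herd_type_comparison(metrics, ref.herds)
        assert {"HOUSEHOLD", "COMMERCIAL"} <= set(cmp.per_substance.columns)
        total = (
            cmp.per_substance["HOUSEHOLD"].sum()
            + cmp.per_substance["COMMERCIAL"].sum()
        )
        assert total == pytest.approx(metrics["n_add"].sum())
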