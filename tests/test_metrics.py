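"""Dose-metric formulas, their identities, and the per-event metric chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amuquant import (
    Administrator,
    DosingClass,
    Indication,
    IntramammaryAdminSpec,
    MetricsError,
    Route,
    TreatmentEvent,
    adur,
    animal_daily_dose,
    compute_event_metrics,
    compute_metrics,
    dosing_classification,
    intramammary_add,
    n_add,
    n_uadd,
    read_metrics,
    used_daily_dose,
    write_metrics,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "ddd_kg, weight, expected",
        [(7.5, 500, 3.75), (1.0, 1000, 1.0), (0.625, 400, 0.25)],
    )
    def test_animal_daily_dose(self, ddd_kg, weight, expected):
        assert animal_daily_dose(ddd_kg, weight) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "spec, expected",
        [((200, 1, 2), 400.0), ((100, 1, 1), 100.0), ((250, 2, 3), 1500.0)],
    )
    def test_intramammary_add(self, spec, expected):
        assert intramammary_add(IntramammaryAdminSpec(*spec)) == expected

    @pytest.mark.parametrize(
        "mass, add, expected",
        [(3750, 3.75, 1.0), (0, 3.75, 0.0), (11250, 3.75, 3.0)],
    )
    def test_n_add(self, mass, add, expected):
        assert n_add(mass, add) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "args, expected",
        [((7500, 1, 500, 2), 7.5), ((30000, 2, 500, 3), 10.0)],
    )
    def test_used_daily_dose(self, args, expected):
        assert used_daily_dose(*args) == pytest.approx(expected)

    def test_udd_recovers_ddd_for_consistent_mass(self):
        # mass laid down at exactly DDD_kg for n animals x d days
        ddd_kg, n, w, d = 5.0, 3, 450.0, 4
        mass = ddd_kg * n * w * d
        assert used_daily_dose(mass, n, w, d) == pytest.approx(ddd_kg)

    @pytest.mark.parametrize(
        "args, expected",
        [((7500, 7.5, 500), 2.0), ((30000, 10.0, 500), 6.0)],
    )
    def test_n_uadd(self, args, expected):
        assert n_uadd(*args) == pytest.approx(expected)

    def test_adur_hand_value(self):
        assert adur(300.0, 2.0, 365, 1010) == pytest.approx(
            300.0 * 1000 / (2.0 * 365 * 1010)
        )
        assert adur(0.0, 2.0, 365, 1010) == 0.0

    @pytest.mark.parametrize(
        "func, args",
        [
            (animal_daily_dose, (0, 400)),
            (n_add, (100, 0)),
            (used_daily_dose, (100, 0, 400, 1)),
            (n_uadd, (100, 0, 400)),
            (adur, (100, 0, 365, 10)),
            (dosing_classification, (1.0, 0)),
        ],
    )
    def test_degenerate_denominators_raise(self, func, args):
        with pytest.raises(MetricsError):
            func(*args)


class TestDosingClassification:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.95, DosingClass.CORRECT),
            (2.00, DosingClass.OVER),
            (0.19, DosingClass.UNDER),
            (0.8, DosingClass.CORRECT),  # band edges inclusive
            (1.2, DosingClass.CORRECT),
            (1.2000001, DosingClass.OVER),
        ],
    )
    def test_band(self, ratio, expected):
        got_ratio, got_class = dosing_classification(ratio * 4.0, 4.0)
        assert got_ratio == pytest.approx(ratio)
        assert got_class is expected

    def test_custom_band(self):
        _, cls = dosing_classification(1.3, 1.0, band=(0.5, 1.5))
        assert cls is DosingClass.CORRECT


def _event(**kwargs):
    defaults = dict(
        event_id="E1", herd_id="H01", month=1, indication=Indication.MASTITIS,
        product_id="ENRO", quantity_used=60.0, n_animals_treated=1,
        animal_weights_kg=(400.0,), duration_days=3,
        route=Route.PARENTERAL, administrator=Administrator.VETERINARIAN,
    )
    defaults.update(kwargs)
    return TreatmentEvent(**defaults)


class TestEventChain:
    def test_parenteral_chain_internal_identity(self, small_catalogue):
        m = compute_event_metrics(_event(), small_catalogue)
        assert m.total_mass_mg == pytest.approx(6000.0)
        assert m.n_add * m.add_g_per_day == pytest.approx(m.total_mass_mg / 1000)
        assert m.n_uadd == pytest.approx(1 * 3)  # animals x days
        assert m.dose_ratio == pytest.approx(
            m.uadd_mg_per_day / (m.add_g_per_day * 1000)
        )

    def test_intramammary_chain(self, intramammary_catalogue):
        # 2 syringes per administration, 2 administrations/day, 3 days
        event = _event(
            product_id="IMM", route=Route.INTRAMAMMARY, quantity_used=12.0,
            duration_days=3, admins_per_day=2,
        )
        m = compute_event_metrics(event, intramammary_catalogue)
        assert m.total_mass_mg == pytest.approx(2400.0)
        assert m.add_g_per_day == pytest.approx(0.800)  # 800 mg/day
        assert m.n_add == pytest.approx(3.0)

    def test_unknown_product_names_event(self, small_catalogue):
        with pytest.raises(MetricsError, match="E1"):
            compute_event_metrics(_event(product_id="NOPE"), small_catalogue)

    def test_weightless_event_uses_herd_species_fallback(self, small_catalogue):
        from amuquant import Herd, HerdType

        herd = Herd("H01", HerdType.COMMERCIAL, 0, 25)  # all buffalo -> 500 kg
        m = compute_event_metrics(
            _event(animal_weights_kg=()), small_catalogue,
            herds={"H01": herd},
        )
        expected_add = 5.0 / 0.95 * 500 / 1000
        assert m.add_g_per_day == pytest.approx(expected_add)

    def test_metrics_csv_round_trip(self, tmp_path, small_catalogue):
        events = [_event(event_id=f"E{i}", quantity_used=10.0 + i) for i in range(5)]
        df = compute_metrics(events, small_catalogue)
        write_metrics(df, tmp_path / "m.csv")
        back = read_metrics(tmp_path / "m.csv")
        assert np.allclose(back["n_add"], df["n_add"])
        assert list(back.columns) == list(df.columns)


def _random_events(rng, n):
    events = []
    for i in range(n):
        k = int(rng.integers(1, 5))
        events.append(
            _event(
                event_id=f"R{i}",
                quantity_used=float(rng.uniform(1, 200)),
                n_animals_treated=k,
                animal_weights_kg=tuple(rng.uniform(300, 650, size=k)),
                duration_days=int(rng.integers(1, 8)),
            )
        )
    return events


class TestProperties:
    def test_nuadd_equals_animal_treatment_days(self, small_catalogue):
        """nUADD = animals x days for every event computed end-to-end."""
        rng = np.random.default_rng(42)
        for e in _random_events(rng, 1000):
            m = compute_event_metrics(e, small_catalogue)
            assert m.n_uadd == pytest.approx(
                e.n_animals_treated * e.duration_days, rel=1e-9
            )

    def test_mass_conservation_event_to_herd(self, small_catalogue):
        rng = np.random.default_rng(7)
        events = _random_events(rng, 50)
        df = compute_metrics(events, small_catalogue)
        herd_mass = df.groupby(["herd_id", "substance"])["total_mass_mg"].sum()
        expected = sum(
            small_catalogue.total_active_mass("ENRO", e.quantity_used)[
                "enrofloxacin"
            ]
            for e in events
        )
        assert herd_mass.sum() == pytest.approx(expected, rel=1e-12)

    def test_brute_force_per_animal_day_oracle(self, small_catalogue):
        """Herd nADD equals an expansion into per-animal, per-day doses."""
        rng = np.random.default_rng(3)
        events = _random_events(rng, 10)
        df = compute_metrics(events, small_catalogue)
        ddd = small_catalogue.lookup_ddd("enrofloxacin").ddd_kg
        oracle = 0.0
        for e in events:
            w = sum(e.animal_weights_kg) / len(e.animal_weights_kg)
            mass_per_animal_day = (100.0 * e.quantity_used) / (
                e.n_animals_treated * e.duration_days
            )
            for _ in range(e.n_animals_treated):
                for _ in range(e.duration_days):
                    oracle += (mass_per_animal_day / 1000) / (ddd * w / 1000)
        assert df["n_add"].sum() == pytest.approx(oracle, rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        mass=st.floats(0.1, 1e5),
        add=st.floats(0.1, 20),
        days=st.integers(1, 365),
        animals=st.integers(1, 2000),
        scale=st.floats(0.1, 10),
    )
    def test_adur_homogeneity(self, mass, add, days, animals, scale):
        base = adur(mass, add, days, animals)
        assert adur(scale * mass, add, days, animals) == pytest.approx(
            scale * base, rel=1e-9
        )
        assert adur(mass, add, days, 2 * animals) == pytest.approx(
            base / 2, rel=1e-9
        )
        assert adur(mass, scale * add, days, animals) == pytest.approx(
            base / scale, rel=1e-9
        )
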