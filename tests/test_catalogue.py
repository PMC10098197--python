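"""Catalogue: mass resolution, combination rules, DDD lookup, WHO mapping."""

import pytest
from hypothesis import given, settings, strategies as st

from amuquant import (
    CatalogueError,
    ComponentRole,
    DrugProduct,
    ProductComponent,
    Route,
    Species,
    ValidationError,
    WhoCategory,
    default_catalogue,
    load_catalogue,
    normalize_substance,
    resolve_dose_determining,
)
from amuquant.reference import write_reference_dataset


def _product(*components, pid="P", formulation=Route.PARENTERAL, unit=30.0):
    return DrugProduct(pid, pid, formulation, tuple(components), unit)


class TestResolveDoseDetermining:
    def test_single_component_is_its_own_dose_determiner(self):
        p = _product(ProductComponent("enrofloxacin", 100.0))
        assert resolve_dose_determining(p).substance == "enrofloxacin"

    @pytest.mark.parametrize(
        "components, expected",
        [
            # trimethoprim-sulphonamide: the minor substance determines dose
            (
                [("trimethoprim", 80.0), ("sulphadiazine", 400.0)],
                "trimethoprim",
            ),
            # beta-lactam + inhibitor
            (
                [("amoxicillin", 150.0), ("clavulanic acid", 37.5)],
                "amoxicillin",
            ),
            (
                [("ampicillin", 100.0), ("sulbactam", 50.0)],
                "ampicillin",
            ),
            # penicillin + depot salt
            (
                [("benzylpenicillin", 200.0), ("procaine", 120.0)],
                "benzylpenicillin",
            ),
        ],
    )
    def test_combination_rules(self, components, expected):
        p = _product(*(ProductComponent(n, c) for n, c in components))
        comp = resolve_dose_determining(p)
        assert comp.substance == expected
        # idempotent and never the partner
        assert resolve_dose_determining(p).substance == expected

    def test_explicit_annotation_wins(self):
        p = _product(
            ProductComponent("oxytetracycline", 50.0),
            ProductComponent("gentamicin", 40.0, role=ComponentRole.DOSE_DETERMINING),
        )
        assert resolve_dose_determining(p).substance == "gentamicin"

    def test_unknown_combination_is_ambiguous(self):
        p = _product(
            ProductComponent("oxytetracycline", 50.0),
            ProductComponent("gentamicin", 40.0),
        )
        with pytest.raises(CatalogueError, match="ambiguous combination"):
            resolve_dose_determining(p)


class TestTotalActiveMass:
    def test_concentration_times_volume(self, small_catalogue):
        assert small_catalogue.total_active_mass("ENRO", 60.0) == {
            "enrofloxacin": 6000.0
        }

    def test_zero_quantity_gives_zero_masses(self, small_catalogue):
        assert small_catalogue.total_active_mass("ENRO", 0.0) == {
            "enrofloxacin": 0.0
        }

    def test_negative_quantity_rejected(self, small_catalogue):
        with pytest.raises(ValidationError, match="negative quantity"):
            small_catalogue.total_active_mass("ENRO", -1.0)

    def test_combination_masses_per_component(self):
        cat = default_catalogue()
        p = _product(
            ProductComponent("trimethoprim", 80.0),
            ProductComponent("sulphadiazine", 400.0),
        )
        masses = cat.total_active_mass(p, 10.0)
        assert masses == {"trimethoprim": 800.0, "sulphadiazine": 4000.0}
        assert resolve_dose_determining(p).substance == "trimethoprim"

    def test_iu_concentration_converts_via_factor(self):
        cat = default_catalogue()
        p = _product(ProductComponent("benzylpenicillin", 1598.0, "IU/mL"))
        assert cat.total_active_mass(p, 10.0)["benzylpenicillin"] == (
            pytest.approx(10.0)
        )

    @settings(max_examples=50, derandomize=True)
    @given(q=st.floats(min_value=0, max_value=1e4, allow_nan=False))
    def test_mass_linear_in_quantity(self, small_catalogue, q):
        m1 = small_catalogue.total_active_mass("ENRO", q)["enrofloxacin"]
        m2 = small_catalogue.total_active_mass("ENRO", 2 * q)["enrofloxacin"]
        assert m2 == pytest.approx(2 * m1)


class TestWhoCategory:
    @pytest.mark.parametrize(
        "substance, category",
        [
            ("enrofloxacin", WhoCategory.HPCIA),
            ("ceftriaxone", WhoCategory.HPCIA),
            ("gentamicin", WhoCategory.HIGH_PRIORITY_CIA),
            ("amoxicillin", WhoCategory.HIGH_PRIORITY_CIA),
            ("oxytetracycline", WhoCategory.HIGHLY_IMPORTANT),
            ("metronidazole", WhoCategory.IMPORTANT),
        ],
    )
    def test_default_map(self, substance, category):
        cat = default_catalogue()
        assert cat.who_category(substance) is category
        assert cat.who_category(substance).is_cia == (
            category in (WhoCategory.HPCIA, WhoCategory.HIGH_PRIORITY_CIA)
        )

    def test_class_absent_from_map_raises(self):
        cat = default_catalogue()
        cat.substances["novelmycin"] = type(cat.substance("enrofloxacin"))(
            "novelmycin", "novel-class"
        )
        with pytest.raises(CatalogueError, match="novel-class"):
            cat.who_category("novelmycin")


class TestDddLookup:
    def test_backcalculated_defaults(self):
        cat = default_catalogue()
        assert cat.lookup_ddd(
            "ceftiofur", Species.CATTLE, Route.PARENTERAL
        ).ddd_kg == pytest.approx(0.625)
        assert cat.lookup_ddd(
            "enrofloxacin", Species.CATTLE, Route.PARENTERAL
        ).ddd_kg == pytest.approx(5.26, abs=0.01)

    def test_exact_species_preferred_over_generic(self):
        from amuquant import DddRecord, DddSource

        cat = default_catalogue(
            extra_ddd=[
                DddRecord(
                    "enrofloxacin", Species.BUFFALO, Route.PARENTERAL, 4.0,
                    DddSource.LABEL,
                )
            ]
        )
        assert cat.lookup_ddd("enrofloxacin", Species.BUFFALO).ddd_kg == 4.0
        assert cat.lookup_ddd("enrofloxacin", Species.CATTLE).ddd_kg == (
            pytest.approx(5.0 / 0.95)
        )

    def test_unknown_substance_raises(self):
        with pytest.raises(CatalogueError, match="unobtainium"):
            default_catalogue().lookup_ddd("unobtainium")


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, canonical",
        [
            ("Procaine Penicillin", "procaine benzylpenicillin"),
            ("procaine-benzylpenicillin", "procaine benzylpenicillin"),
            ("Cephalexin", "cefalexin"),
            ("Sulfadiazine", "sulphadiazine"),
            ("ENROFLOXACIN ", "enrofloxacin"),
        ],
    )
    def test_synonyms_and_case(self, raw, canonical):
        assert normalize_substance(raw) == canonical


class TestLoadCatalogue:
    def test_round_trip_through_files(self, tmp_path):
        files = write_reference_dataset(tmp_path)
        cat = load_catalogue(
            files["products.csv"], files["ddd.csv"], files["cia_map.csv"],
            files["substances.csv"],
        )
        assert len(cat.products) == 14
        used = {cat.dose_determining(p).substance for p in cat.products}
        assert len(used) == 14
        classes = {cat.substance(s).am_class for s in used}
        assert len(classes) == 9

    def test_empty_product_file_rejected(self, tmp_path):
        files = write_reference_dataset(tmp_path)
        empty = tmp_path / "empty_products.csv"
        empty.write_text(
            "productId,tradeName,formulation,unitSize,substance,"
            "concentration,concentrationUnit,role\n"
        )
        with pytest.raises(ValidationError, match="no products"):
            load_catalogue(empty, files["ddd.csv"], files["cia_map.csv"])

    def test_unknown_substance_named_in_error(self, tmp_path):
        files = write_reference_dataset(tmp_path)
        bad = tmp_path / "bad_products.csv"
        bad.write_text(
            "productId,tradeName,formulation,unitSize,substance,"
            "concentration,concentrationUnit,role\n"
            "PX,Foo-ject,PARENTERAL,30,foo,100,mg/mL,\n"
        )
        with pytest.raises(CatalogueError, match="'foo'"):
            load_catalogue(bad, files["ddd.csv"], files["cia_map.csv"])
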