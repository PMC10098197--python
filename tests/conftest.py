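import pytest

from amuquant import (
    Catalogue,
    DddRecord,
    DrugProduct,
    ProductComponent,
    Route,
    Species,
    default_catalogue,
    reference_dataset,
)


@pytest.fixture(scope="session")
def ref():
    """The deterministic reference survey dataset (38 herds, 265 events)."""
    return reference_dataset()


@pytest.fixture(scope="session")
def small_catalogue() -> Catalogue:
    """One-product enrofloxacin catalogue for formula-level tests."""
    products = {
        "ENRO": DrugProduct(
            "ENRO", "Enro-100", Route.PARENTERAL,
            (ProductComponent("enrofloxacin", 100.0, "mg/mL"),), 30.0,
        )
    }
    return default_catalogue(products)


@pytest.fixture(scope="session")
def intramammary_catalogue() -> Catalogue:
    products = {
        "IMM": DrugProduct(
            "IMM", "UdderSyringe", Route.INTRAMAMMARY,
            (ProductComponent("cefoperazone", 200.0, "mg/unit"),), 1.0,
        )
    }
    return default_catalogue(
        products,
        extra_ddd=[
            DddRecord("cefoperazone", Species.BOVINE_ANY, Route.INTRAMAMMARY, 1.0)
        ],
    )
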