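import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from bcbalance import (
    BarcodePanel,
    Barcode,
    WeightedBarcodeSet,
    make_balanced_set,
)


@pytest.fixture
def homopolymer_panel() -> BarcodePanel:
    """Four barcodes that are each a single repeated base: the canonical
    exactly-balanced quartet at equal weights."""
    return BarcodePanel(
        [
            Barcode("BC1", "A" * 10),
            Barcode("BC2", "C" * 10),
            Barcode("BC3", "G" * 10),
            Barcode("BC4", "T" * 10),
        ]
    )


@pytest.fixture
def homopolymer_set(homopolymer_panel) -> WeightedBarcodeSet:
    return WeightedBarcodeSet.equal(homopolymer_panel.ids)


@pytest.fixture
def balanced_panel_16() -> BarcodePanel:
    return make_balanced_set(16, L=10, seed=42)
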