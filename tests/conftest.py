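import pytest

from sgnn.features import (
    FeatureConfig,
    NormalizationBounds,
    PKaEntry,
    PKaTable,
    PropensityScale,
)
from sgnn.sequence_io import CANONICAL_RESIDUES


def make_uniform_scale(c: float) -> PropensityScale:
    return PropensityScale(
        name=f"uniform-{c}", values={r: c for r in CANONICAL_RESIDUES}
    )


@pytest.fixture
def uniform_zero_scale():
    return make_uniform_scale(0.0)


@pytest.fixture
def kde_scale():
    """Toy scale used in hand-computed sliding-window examples."""
    values = {r: 0.0 for r in CANONICAL_RESIDUES}
    values.update({"K": 0.0, "D": 3.0, "E": -3.0})
    return PropensityScale(name="kde-toy", values=values)


@pytest.fixture(scope="session")
def pka_table():
    """The conventional pKa set used throughout the tests, termini off."""
    return PKaTable(
        entries={
            "D": PKaEntry(3.65, "acidic"),
            "E": PKaEntry(4.25, "acidic"),
            "C": PKaEntry(8.30, "acidic"),
            "Y": PKaEntry(10.07, "acidic"),
            "H": PKaEntry(6.00, "basic"),
            "K": PKaEntry(10.53, "basic"),
            "R": PKaEntry(12.48, "basic"),
        },
        include_termini=False,
    )


@pytest.fixture
def toy_feature_config(uniform_zero_scale, pka_table):
    return FeatureConfig(
        scale=uniform_zero_scale,
        pka_table=pka_table,
        bounds=NormalizationBounds(na4vss_min=-100.0, na4vss_max=100.0),
    )
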