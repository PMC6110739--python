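import numpy as np
import pandas as pd
import pytest

from survmeta.metadata import (
    CategoryEntry,
    Layer1Roles,
    Layer2VariableSpec,
    Layer3CategoryMap,
    MetadataBundle,
)
from survmeta.etl import code_table
from survmeta.simdata import colon_like_spec, make_fixture_files, simulate_cohort


def _make_toy_bundle() -> MetadataBundle:
    return MetadataBundle(
        layer1=Layer1Roles(
            "TimeOS", "EventDeath", id_column="pid",
            extend_columns={"OS_months": "TimeOS"},
        ),
        layer2=[
            Layer2VariableSpec("pid", "ratio", "ignore"),
            Layer2VariableSpec("TimeOS", "ratio", "time"),
            Layer2VariableSpec("EventDeath", "nominal", "event"),
            Layer2VariableSpec("sex", "nominal", "covariate"),
            Layer2VariableSpec("age", "ratio", "covariate"),
        ],
        layer3=[
            Layer3CategoryMap(
                "EventDeath",
                [
                    CategoryEntry(0, frozenset({"0", "alive"}), "alive"),
                    CategoryEntry(1, frozenset({"1", "dead"}), "dead"),
                ],
            ),
            Layer3CategoryMap(
                "sex",
                [
                    CategoryEntry(1, frozenset({"1", "m", "M"}), "male"),
                    CategoryEntry(0, frozenset({"0", "f", "F"}), "female"),
                ],
            ),
        ],
    )


@pytest.fixture
def toy_bundle() -> MetadataBundle:
    """Minimal trial codebook: TimeOS/EventDeath plus sex and age."""
    return _make_toy_bundle()


@pytest.fixture(scope="session")
def toy_bundle_factory():
    """Session-safe constructor for use inside hypothesis-driven tests."""
    return _make_toy_bundle


@pytest.fixture
def toy_raw() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pid": ["1", "2", "3", "4", "5", "6"],
            "OS_months": ["12", "30", "7", "55", "20", "41"],
            "EventDeath": ["1", "0", "dead", "alive", "1", "0"],
            "sex": ["M", "f", "1", "F", "m", "M"],
            "age": ["61", "55", "", "70", "48", "66"],
        }
    )


@pytest.fixture
def toy_dataset(toy_bundle, toy_raw):
    raw = toy_raw.rename(columns=toy_bundle.layer1.rename_map)
    return code_table(raw, toy_bundle)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic colon-shaped cohort shared across tests."""
    return simulate_cohort(colon_like_spec(n=400, seed=20180827 % 2**31))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_cohort):
    out = tmp_path_factory.mktemp("fixture")
    make_fixture_files(small_cohort, out)
    return out
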