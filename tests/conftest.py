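import numpy as np
import pandas as pd
import pytest

import regcap as rc
from regcap.datasets import (
    load_clinical_trials,
    load_indicator_schema,
    load_provincial_scores_2022,
)


@pytest.fixture(scope="session")
def schema():
    """The bundled 5-dimension / 14-indicator schema with frozen weights."""
    return load_indicator_schema()


@pytest.fixture(scope="session")
def ref_scores():
    """2022 reference provincial score table (31 regions)."""
    return load_provincial_scores_2022()


@pytest.fixture(scope="session")
def frozen_weights(schema):
    return rc.WeightSet.from_schema(schema)


@pytest.fixture(scope="session")
def trials():
    return load_clinical_trials()


@pytest.fixture()
def tiny_schema():
    """Two dimensions, three indicators, one negative indicator."""
    return rc.IndicatorSchema(
        dimensions=(
            rc.Dimension("d1", "Dimension one"),
            rc.Dimension("d2", "Dimension two"),
        ),
        indicators=(
            rc.IndicatorDef("a", "A", "piece", "d1", rc.Nature.POSITIVE),
            rc.IndicatorDef("b", "B", "%", "d1", rc.Nature.NEGATIVE),
            rc.IndicatorDef("c", "C", "", "d2", rc.Nature.POSITIVE),
        ),
    )


def make_panel_frame(values, years=(2018,), categories=None):
    """Build a tidy long frame from {region: {indicator: [by-year values]}}."""
    categories = categories or {}
    rows = []
    for region, inds in values.items():
        cat = categories.get(region, "eastern")
        for ind, series in inds.items():
            for year, v in zip(years, series):
                rows.append(
                    {"region": region, "category": cat, "year": year,
                     "indicator": ind, "value": v}
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def panel_factory(tiny_schema):
    def _make(values, years=(2018,), categories=None, schema=tiny_schema):
        from regcap.panel_model import panel_from_frame

        return panel_from_frame(make_panel_frame(values, years, categories), schema)

    return _make
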