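import hypothesis
import pandas as pd
import pytest

from epiwave import CaseSeries

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=100
)
hypothesis.settings.load_profile("default")


def make_series(values, region="Ruritania", start="2020-03-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return CaseSeries(region=region, dates=dates, raw=values)


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def csv_factory(tmp_path):
    """Write a wide-format CSV from a dict of region -> cell strings."""

    def write(columns, dates=None, name="cases.csv"):
        n = len(next(iter(columns.values())))
        if dates is None:
            dates = [str(d.date()) for d in pd.date_range("2020-03-01", periods=n, freq="D")]
        lines = ["date," + ",".join(columns)]
        for k, day in enumerate(dates):
            lines.append(day + "," + ",".join(str(columns[c][k]) for c in columns))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
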