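"""Bundled example data.

Two 10-row excerpts of orchard microclimate recordings from a wireless
sensor network (temperature in deg C, relative humidity in %, soil-moisture
resistance), sampled on consecutive nights, plus the pair of symbol strings
used throughout the documentation.  These are the canonical worked examples:
with a window of 3 the temperature columns share a common subsequence of
length 8, which humidity refinement reduces to 7.
"""

from __future__ import annotations

from importlib import resources

from .core import MultivariateSeries, SymbolSequence
from .io_formats import read_fasta, read_series_csv

__all__ = ["load_sensor_pair", "load_example_strings"]


def _data_path(name: str):
    return resources.files("swlcss.data").joinpath(name)


def load_sensor_pair() -> tuple[MultivariateSeries, MultivariateSeries]:
    """The two bundled 10-row sensor series (variables: temperature, humidity, soil_moisture)."""
    with resources.as_file(_data_path("sensor_s.csv")) as p:
        S = read_series_csv(p, timestamp_column="timestamp", identifier="sensor_s")
    with resources.as_file(_data_path("sensor_t.csv")) as p:
        T = read_series_csv(p, timestamp_column="timestamp", identifier="sensor_t")
    return S, T


def load_example_strings() -> tuple[SymbolSequence, SymbolSequence]:
    """The worked-example string pair (AEBACFDADB, CABDACDADB)."""
    with resources.as_file(_data_path("example_sequences.fasta")) as p:
        records = read_fasta(p)
    return records[0], records[1]
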