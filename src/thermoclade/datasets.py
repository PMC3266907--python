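"""Packaged example datasets."""

from importlib import resources

import pandas as pd

__all__ = ["load_dictyota_ranges"]


def load_dictyota_ranges() -> pd.DataFrame:
    """Published geographic-range and SST summaries for ten *Dictyota*
    species (brown algae).

    Columns: species, n (record count), lat_range / lon_range (degrees),
    max_c / mean_c / min_c (per-species means of the per-record
    max/mean/min SST, deg C) and max_range_c (largest per-record maximum
    SST minus smallest per-record minimum SST, deg C).  Used as the worked
    example for the tolerance-vs-range regression.
    """
    with resources.files("thermoclade.data").joinpath(
        "dictyota_ranges.csv"
    ).open() as fh:
        return pd.read_csv(fh)
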