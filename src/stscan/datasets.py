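"""Bundled reference tables.

The package ships the published summary table of the twelve retrospective
space-time clusters detected in County Cork, Ireland, over 2008-2017
(388 cases in total), as printed: start/end dates, duration in days,
expected and observed counts, Monte-Carlo p-value and the Poisson LLR test
statistic.  The underlying case-level data are access-restricted; this
table supports worked examples and internal-consistency checks of the LLR
arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import parse_date

__all__ = ["load_cork_cluster_table", "CORK_TOTAL_CASES"]

#: Grand total of cases in the County Cork 2008-2017 study dataset.
CORK_TOTAL_CASES = 388


def load_cork_cluster_table() -> pd.DataFrame:
    """The published County Cork 2008-2017 cluster summary table.

    Columns: cluster, start_date, end_date (datetime.date), duration_days,
    expected, observed, p_value, test_statistic.
    """
    with resources.files("stscan.data").joinpath("cork_clusters_2008_2017.csv").open() as fh:
        frame = pd.read_csv(fh)
    for col in ("start_date", "end_date"):
        frame[col] = frame[col].map(parse_date)
    return frame
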