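"""Bundled example data.

The Delhi street-children survey table: substance-using children counted
in nine districts of Delhi by three age classes (years), collected in
2015 via respondent-driven sampling.  Row analyses give the diversity of
age composition within a district; column analyses give the diversity of
the geographic spread within an age class.
"""

from __future__ import annotations

import pandas as pd

from .tables import CountTable

__all__ = ["delhi_fixture", "DELHI_AGE_CLASSES", "DELHI_DISTRICTS"]

DELHI_AGE_CLASSES = ("7-10", "11-14", "15-18")

_DELHI_COUNTS = {
    "Central Delhi": (2, 2, 3),
    "East Delhi": (10, 12, 8),
    "New Delhi": (0, 14, 35),
    "North East Delhi": (16, 35, 16),
    "North West Delhi": (7, 19, 13),
    "South Delhi": (11, 14, 8),
    "South East Delhi": (2, 13, 8),
    "South West Delhi": (7, 36, 35),
    "West Delhi": (14, 20, 16),
}

DELHI_DISTRICTS = tuple(_DELHI_COUNTS)


def delhi_fixture() -> CountTable:
    """The 9-district × 3-age-class Delhi substance-use count table."""
    df = pd.DataFrame.from_dict(_DELHI_COUNTS, orient="index",
                                columns=list(DELHI_AGE_CLASSES)).astype(int)
    return CountTable(df)
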