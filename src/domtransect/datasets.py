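"""Example summary tables from a mangrove-fringed river-to-ocean transect.

Relative abundances measured on eight pooled SPE-DOM samples: a river
endmember (RW), four brackish mangrove-fringed samples (BW1-BW4), a
coastal seawater endmember (SW) and two tidal-creek samples collected
at neap (NT) and spring (ST) tide.  The first table gives the percent
of 1H NMR intensity in the six structural-feature sections; the second
the percent of FT-ICR-MS signal intensity in each van Krevelen compound
group.  They serve as a worked example for the section/group summary
utilities and for transect trend statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "transect_section_abundances",
    "transect_compound_group_abundances",
    "TRANSECT_ORDER",
]

#: River-to-ocean salinity order of the transect subset.
TRANSECT_ORDER = ["RW", "BW1", "BW2", "BW3", "BW4", "SW"]

_SECTION_ROWS = {
    # aliphatic, acetyl, alpha_carbonyl, alpha_oxygen, olefinic, aromatic (%)
    "SW": (37.2, 11.1, 18.0, 27.0, 2.4, 4.3),
    "BW4": (34.1, 10.7, 17.5, 29.3, 3.0, 5.4),
    "BW3": (35.0, 11.0, 18.0, 28.9, 1.7, 5.3),
    "BW2": (34.9, 11.1, 17.9, 28.9, 2.1, 5.2),
    "BW1": (30.4, 9.8, 15.9, 30.3, 4.2, 9.4),
    "RW": (30.0, 9.3, 15.4, 31.6, 4.5, 9.1),
    "NT": (30.3, 10.2, 18.6, 31.0, 2.8, 7.0),
    "ST": (34.6, 10.9, 18.9, 27.5, 1.4, 6.7),
}

_GROUP_ROWS = {
    # saturated, unsaturated, highly_unsaturated, aromatic, PAC, saccharide (%)
    "SW": (0.16, 10.1, 77.8, 8.3, 2.1, 0.09),
    "BW4": (0.12, 10.0, 71.2, 11.9, 4.7, 0.14),
    "BW3": (0.18, 9.7, 68.9, 13.4, 5.6, 0.11),
    "BW2": (0.13, 9.3, 67.8, 14.3, 6.2, 0.14),
    "BW1": (0.11, 7.9, 68.4, 14.8, 6.6, 0.11),
    "RW": (0.42, 7.8, 65.4, 15.8, 8.2, 0.25),
    "NT": (0.20, 7.5, 70.7, 14.4, 4.9, 0.02),
    "ST": (0.04, 7.0, 75.1, 12.8, 3.0, 0.00),
}


def transect_section_abundances() -> pd.DataFrame:
    """Percent of 1H NMR intensity per structural-feature section."""
    cols = ["aliphatic", "acetyl", "alpha_carbonyl", "alpha_oxygen", "olefinic", "aromatic"]
    return pd.DataFrame.from_dict(_SECTION_ROWS, orient="index", columns=cols)


def transect_compound_group_abundances() -> pd.DataFrame:
    """Percent of FT-ICR-MS intensity per van Krevelen compound group."""
    cols = ["saturated", "unsaturated", "highly_unsaturated", "aromatic", "PAC", "saccharide"]
    return pd.DataFrame.from_dict(_GROUP_ROWS, orient="index", columns=cols)
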