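"""Printed summary counts of the Korean nationwide OHCA cohort (2013-2019).

These are the published descriptive counts of the National Health Insurance
Database-linked OHCA registry the package's synthetic generator emulates:
group sizes by socioeconomic position (NHI premium quartiles Q1-Q4 and
Medical Aid) and selected event counts per group.  They serve as worked-example
inputs: the subject-level registry itself is not public, but these counts
suffice to reconstruct two-by-two tables, percentages and crude odds ratios
exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUP_SIZES: dict[str, int] = {
    "NHI_Q1": 40483,
    "NHI_Q2": 26955,
    "NHI_Q3": 21625,
    "NHI_Q4": 22201,
    "MA": 10252,
}

#: event counts per SEP group for selected rows of the published Table 1
EVENT_COUNTS: dict[str, dict[str, int]] = {
    "witnessed": {"NHI_Q1": 20090, "NHI_Q2": 13225, "NHI_Q3": 10392,
                  "NHI_Q4": 10717, "MA": 4378},
    "bystander_cpr": {"NHI_Q1": 24971, "NHI_Q2": 16487, "NHI_Q3": 13161,
                      "NHI_Q4": 13397, "MA": 5826},
    "shockable": {"NHI_Q1": 5690, "NHI_Q2": 4561, "NHI_Q3": 3771,
                  "NHI_Q4": 3723, "MA": 990},
    "ed_level12": {"NHI_Q1": 26384, "NHI_Q2": 17074, "NHI_Q3": 13765,
                   "NHI_Q4": 14339, "MA": 5939},
    "surv_admission": {"NHI_Q1": 7680, "NHI_Q2": 5546, "NHI_Q3": 4683,
                       "NHI_Q4": 4711, "MA": 1625},
    "surv_discharge": {"NHI_Q1": 2916, "NHI_Q2": 2250, "NHI_Q3": 1880,
                       "NHI_Q4": 1832, "MA": 465},
    "good_neuro": {"NHI_Q1": 1842, "NHI_Q2": 1458, "NHI_Q3": 1250,
                   "NHI_Q4": 1108, "MA": 216},
}

#: published age median (IQR) per group, years
AGE_MEDIAN_IQR: dict[str, tuple[float, float, float]] = {
    "NHI_Q1": (77, 66, 83),
    "NHI_Q2": (71, 59, 80),
    "NHI_Q3": (67, 55, 78),
    "NHI_Q4": (70, 58, 79),
    "MA": (74, 59, 82),
}

#: additional binary-covariate counts per group (female sex etc.)
COVARIATE_COUNTS: dict[str, dict[str, int]] = {
    "female": {"NHI_Q1": 15006, "NHI_Q2": 8988, "NHI_Q3": 6982,
               "NHI_Q4": 7866, "MA": 5070},
    "diabetes": {"NHI_Q1": 10346, "NHI_Q2": 6451, "NHI_Q3": 5046,
                 "NHI_Q4": 5301, "MA": 2756},
    "hypertension": {"NHI_Q1": 21185, "NHI_Q2": 12898, "NHI_Q3": 9781,
                     "NHI_Q4": 10625, "MA": 5307},
    "metropolitan": {"NHI_Q1": 17594, "NHI_Q2": 11385, "NHI_Q3": 9254,
                     "NHI_Q4": 9525, "MA": 4207},
}


def total_n() -> int:
    return sum(GROUP_SIZES.values())


def prevalence(variable: str, group: str) -> float:
    """Event proportion of `variable` within one SEP group."""
    return EVENT_COUNTS[variable][group] / GROUP_SIZES[group]


def percentages(variable: str, decimals: int = 1) -> dict[str, float]:
    """Per-group percentages of a counted variable, rounded like the source table."""
    return {g: round(100.0 * EVENT_COUNTS[variable][g] / GROUP_SIZES[g], decimals)
            for g in GROUP_SIZES}


def two_by_two(variable: str, group1: str, group0: str) -> np.ndarray:
    """2x2 table [[events1, nonevents1], [events0, nonevents0]]."""
    a = EVENT_COUNTS[variable][group1]
    b = GROUP_SIZES[group1] - a
    c = EVENT_COUNTS[variable][group0]
    d = GROUP_SIZES[group0] - c
    return np.array([[a, b], [c, d]], dtype=float)


def expand_two_group(variable: str, group1: str, group0: str) -> pd.DataFrame:
    """Expand printed counts to subject level for two groups.

    Returns a DataFrame with columns `exposed` (1 = group1) and `event`,
    suitable for feeding the logistic engine directly.
    """
    rows = []
    for g, exposed in ((group1, 1), (group0, 0)):
        k = EVENT_COUNTS[variable][g]
        n = GROUP_SIZES[g]
        rows.append(pd.DataFrame({"exposed": exposed,
                                  "event": np.r_[np.ones(k), np.zeros(n - k)]}))
    return pd.concat(rows, ignore_index=True)
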