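"""Rate formatting and summary-table helpers.

All headline percentages are rounded half-up to one decimal, the convention
used throughout the study's tables (e.g. 35/62 -> 56.5%).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = ["percent", "cross_summary", "EXAMPLE_CROSS_RECORDS"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


# Cross-compatibility records of the four apple x pear populations that
# motivate the pipeline's defaults (flowers pollinated, fruits set, seeds
# obtained, seedlings germinated). Used as worked-example input for
# cross_summary; the rates are computed, never stored.
EXAMPLE_CROSS_RECORDS = [
    {"female": "Golden Delicious", "male": "Yan Zhuang", "n_flower": 500, "n_fruit": 126, "n_seed": 170, "n_seedling": 62},
    {"female": "Golden Delicious", "male": "Jin Zhui", "n_flower": 500, "n_fruit": 110, "n_seed": 141, "n_seedling": 46},
    {"female": "Fuji", "male": "Yan Zhuang", "n_flower": 500, "n_fruit": 132, "n_seed": 178, "n_seedling": 76},
    {"female": "Fuji", "male": "Jin Zhui", "n_flower": 500, "n_fruit": 103, "n_seed": 134, "n_seedling": 40},
]


def cross_summary(records) -> pd.DataFrame:
    """Fruit-set and germination rates of hybridization crosses.

    ``records`` is an iterable of mappings (or a DataFrame) with columns
    n_flower, n_fruit, n_seed, n_seedling; returns the same rows with
    fruit_set_pct = fruits/flowers and germination_pct = seedlings/seeds.
    """
    df = pd.DataFrame(records).copy()
    df["fruit_set_pct"] = [
        percent(fr, fl) for fr, fl in zip(df["n_fruit"], df["n_flower"])
    ]
    df["germination_pct"] = [
        percent(sl, sd) for sl, sd in zip(df["n_seedling"], df["n_seed"])
    ]
    return df
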