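"""Run-level summary tables: DE totals, class distributions, percentages.

All percentages are rounded half-up to one decimal so that printed
summaries are consistent with their integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (e.g. 10.65 -> 10.7),
    unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DESummary:
    n_de_total: int
    n_up: int
    n_down: int
    pct_up: float
    pct_down: float
    class_distribution: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_de_total": self.n_de_total,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "pct_up": self.pct_up,
            "pct_down": self.pct_down,
            "class_distribution": self.class_distribution,
        }


def summarize_de(
    records: pd.DataFrame,
    te_class_map: Optional[Mapping[str, str]] = None,
) -> DESummary:
    """Totals and percentages of UP/DOWN calls, plus the TE-class
    distribution (percent of total) separately among up- and
    down-regulated features when a feature -> class mapping is given.

    ``records`` needs columns ``feature_id`` and ``call``.
    """
    up = records[records["call"] == "UP"]
    down = records[records["call"] == "DOWN"]
    n_up, n_down = len(up), len(down)
    total = n_up + n_down
    pct_up = round_half_up(100.0 * n_up / total) if total else 0.0
    pct_down = round_half_up(100.0 * n_down / total) if total else 0.0

    class_distribution: dict[str, dict[str, float]] = {}
    if te_class_map is not None:
        for direction, sub in (("UP", up), ("DOWN", down)):
            dist: dict[str, float] = {}
            if len(sub):
                classes = sub["feature_id"].map(lambda f: te_class_map.get(f))
                counts = classes.dropna().value_counts()
                denom = int(counts.sum())
                for cls, n in sorted(counts.items()):
                    dist[str(cls)] = round_half_up(100.0 * int(n) / denom)
            class_distribution[direction] = dist
    return DESummary(
        n_de_total=total,
        n_up=n_up,
        n_down=n_down,
        pct_up=pct_up,
        pct_down=pct_down,
        class_distribution=class_distribution,
    )
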