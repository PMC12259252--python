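"""Group-comparison statistics for pipeline outputs.

Two-group designs use the two-tailed Student's t test; multi-group designs
use one-way ANOVA followed by Tukey HSD all-pairs comparisons. Significance
is flagged at p < 0.05 (presentation only; p-values are reported at full
precision).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["compare_groups", "ALPHA"]

ALPHA = 0.05


def _degenerate(groups: list[np.ndarray]) -> bool:
    means = [g.mean() for g in groups]
    return (all(g.std() == 0 for g in groups)
            and np.ptp(means) == 0)


def compare_groups(table: pd.DataFrame, design: str = "two-group") -> pd.DataFrame:
    """Compare animal-level metric values between groups.

    ``table`` has columns (group, animal_id, metric, value) with one value
    per animal and metric. Returns a tidy report with one row per metric and
    comparison: columns (metric, comparison, test, statistic, p_value,
    significant).
    """
    if design not in ("two-group", "multi-group"):
        raise ValueError(f"unknown design: {design!r}")
    required = {"group", "animal_id", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")

    rows = []
    for metric, sub in table.groupby("metric"):
        names = sorted(sub["group"].unique())
        if len(names) < 2:
            raise ValueError(f"metric {metric!r}: need >= 2 groups")
        groups = [sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
                  for g in names]
        for g, name in zip(groups, names):
            if len(g) < 2:
                raise ValueError(f"group {name!r} has n={len(g)} < 2")
        if design == "two-group":
            if len(names) != 2:
                raise ValueError(f"two-group design requires exactly 2 "
                                 f"groups, got {len(names)}")
            if _degenerate(groups):
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(groups[0], groups[1])
                if np.isnan(p):  # zero variance in both, equal means
                    stat, p = 0.0, 1.0
            rows.append((metric, f"{names[0]} vs {names[1]}",
                         "t (two-tailed)", float(stat), float(p),
                         p < ALPHA))
        else:
            if _degenerate(groups):
                f, p = 0.0, 1.0
            else:
                f, p = sps.f_oneway(*groups)
                if np.isnan(p):
                    f, p = 0.0, 1.0
            rows.append((metric, "omnibus", "one-way ANOVA", float(f),
                         float(p), p < ALPHA))
            values = np.concatenate(groups)
            labels = np.concatenate([[n] * len(g)
                                     for n, g in zip(names, groups)])
            if np.ptp(values) > 0:
                tk = pairwise_tukeyhsd(values, labels, alpha=ALPHA)
                for res in tk.summary().data[1:]:
                    g1, g2, meandiff, p_adj, *_ , reject = res
                    rows.append((metric, f"{g1} vs {g2}", "Tukey HSD",
                                 float(meandiff), float(p_adj), bool(reject)))
            else:
                from itertools import combinations
                for g1, g2 in combinations(names, 2):
                    rows.append((metric, f"{g1} vs {g2}", "Tukey HSD",
                                 0.0, 1.0, False))
    return pd.DataFrame(rows, columns=["metric", "comparison", "test",
                                       "statistic", "p_value", "significant"])
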