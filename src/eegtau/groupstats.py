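"""Group-level statistics: tap-vs-rest t-tests, Wilcoxon band comparisons
with Holm-Bonferroni correction, and the pooled feature comparison.

Per participant, per-trial mean relaxation time over the onset windows
([-0.5, +1.0] s by default) is compared tap vs rest with Welch's two-sample
t-test.  Across participants, peak sensitivities of the four standard bands
are compared pairwise (6 pairs) with the paired Wilcoxon signed-rank test,
Holm-corrected; pooling participant x band pairs compares the two feature
families against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySetError

STANDARD_BAND_NAMES = ("low", "mu", "beta", "wide")


@dataclass
class TestReport:
    comparison: str
    statistic: float
    p_value: float
    reject: bool
    alpha: float = 0.05
    correction: str = "none"
    note: str = ""


def holm_bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Step-down Holm decisions, returned in the original order.

    Sorted ascending, p_(i) is rejected while p_(i) <= alpha / (m - i + 1)
    (1-based); the procedure stops at the first failure.
    """
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    decisions = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):  # rank 0-based
        if p[idx] <= alpha / (m - rank):
            decisions[idx] = True
        else:
            break
    return decisions.tolist()


def paired_wilcoxon(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test (Pratt zeros; exact for <= 25 pairs).

    Returns (statistic, p). Identical pairs give p = 1 by convention.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x - np.asarray(y, dtype=np.float64) if y is not None else x
    if np.all(d == 0):
        return 0.0, 1.0
    has_zeros = np.any(d == 0)
    method = "exact" if (d.size <= 25 and not has_zeros) else "approx"
    res = stats.wilcoxon(d, zero_method="pratt", correction=True,
                         method=method)
    return float(res.statistic), float(res.pvalue)


def tau_tap_vs_rest_test(
    features: pd.DataFrame,
    onset_window: tuple[float, float] = (-0.5, 1.0),
    tap_conditions=("right",),
    rest_condition: str = "rest",
    value_column: str = "tau",
    alpha: float = 0.05,
) -> TestReport:
    """Welch t-test on per-trial mean tau over onset windows, tap vs rest."""
    if isinstance(tap_conditions, str):
        tap_conditions = (tap_conditions,)
    df = features
    if "valid" in df.columns:
        df = df[df["valid"]]
    df = df[(df["end_time"] >= onset_window[0])
            & (df["end_time"] <= onset_window[1])
            & np.isfinite(df[value_column])]
    per_trial = df.groupby(["trial", "condition"])[value_column].mean()
    per_trial = per_trial.reset_index()
    tap = per_trial.loc[per_trial["condition"].isin(tap_conditions),
                        value_column].to_numpy()
    rest = per_trial.loc[per_trial["condition"] == rest_condition,
                         value_column].to_numpy()
    if len(tap) < 5 or len(rest) < 5:
        raise EmptySetError(
            f"need >= 5 per-trial values per group; got {len(tap)} tap, "
            f"{len(rest)} rest"
        )
    scale = max(1e-30, abs(tap.mean()), abs(rest.mean()))
    if tap.std() < 1e-12 * scale and rest.std() < 1e-12 * scale:
        return TestReport("tau tap vs rest", np.nan, np.nan, False,
                          alpha=alpha, note="degenerate variance; skipped")
    t, p = stats.ttest_ind(tap, rest, equal_var=False)
    return TestReport("tau tap vs rest", float(t), float(p), p < alpha,
                      alpha=alpha)


def band_comparison(
    summaries: pd.DataFrame,
    feature: str,
    alpha: float = 0.05,
    bands=STANDARD_BAND_NAMES,
) -> list[TestReport]:
    """Pairwise Wilcoxon on per-participant peak sensitivities across bands.

    ``summaries`` columns: participant, band, feature, peak_sensitivity.
    The six band-pair p-values are Holm-corrected jointly.
    """
    df = summaries[summaries["feature"] == feature]
    wide = df.pivot_table(index="participant", columns="band",
                          values="peak_sensitivity")
    missing = [b for b in bands if b not in wide.columns]
    if missing:
        raise EmptySetError(f"missing bands in summaries: {missing}")
    if len(wide) < 6:
        raise EmptySetError(
            f"band comparison needs >= 6 participants; got {len(wide)}"
        )
    pairs = list(combinations(bands, 2))
    stats_p = [paired_wilcoxon(wide[a].to_numpy(), wide[b].to_numpy())
               for a, b in pairs]
    decisions = holm_bonferroni([p for _, p in stats_p], alpha)
    return [
        TestReport(f"{feature}: {a} vs {b}", s, p, rej, alpha=alpha,
                   correction="holm-bonferroni")
        for (a, b), (s, p), rej in zip(pairs, stats_p, decisions)
    ]


def feature_comparison(
    summaries: pd.DataFrame,
    features: tuple[str, str] = ("acf", "erd"),
    alpha: float = 0.05,
) -> TestReport:
    """Paired Wilcoxon on peak sensitivities pooled over participant x band."""
    f1, f2 = features
    wide = summaries.pivot_table(index=["participant", "band"],
                                 columns="feature",
                                 values="peak_sensitivity").dropna()
    x = wide[f1].to_numpy()
    y = wide[f2].to_numpy()
    note = ""
    if len(x) < 6:
        note = f"underpowered: only {len(x)} pairs"
    s, p = paired_wilcoxon(x, y)
    return TestReport(f"{f1} vs {f2} pooled over bands", s, p, p < alpha,
                      alpha=alpha, note=note)
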