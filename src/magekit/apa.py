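"""Significance filtering and direction testing of alternative-polyadenylation events.

Events are gene-level tables of PDUI (Percentage of Distal polyA-site Usage
Index, in [0, 1]) per replicate in two conditions, with 3'-UTR read coverage
and a per-event p-value supplied by the upstream APA caller.  The filter keeps
events with coverage > 20, Benjamini-Hochberg adjusted p <= 0.05, absolute
mean dPDUI >= 0.2 and mean-PDUI fold change >= 1.5.  The direction of the
global 3'-UTR shift among survivors is assessed with an exact binomial test
against a null proportion of 0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests


def _replicate_columns(events: pd.DataFrame, group: int) -> list[str]:
    cols = [c for c in events.columns if c.startswith(f"pdui_g{group}_")]
    if not cols:
        raise ValueError(f"no replicate PDUI columns for group {group}")
    return cols


def summarize_events(events: pd.DataFrame) -> pd.DataFrame:
    """Add per-event group means, dPDUI and fold change.

    ``delta_pdui = mean(group2) - mean(group1)`` — positive means increased
    distal-site usage (3'-UTR lengthening) in group 2.  Fold change is
    orientation-symmetric: ``max(mean1, mean2) / min(mean1, mean2)``.
    """
    g1 = _replicate_columns(events, 1)
    g2 = _replicate_columns(events, 2)
    if events[g1 + g2].isna().any().any():
        raise ValueError("missing replicate PDUI values")
    out = events.copy()
    m1 = events[g1].mean(axis=1)
    m2 = events[g2].mean(axis=1)
    out["mean_pdui_g1"] = m1
    out["mean_pdui_g2"] = m2
    out["delta_pdui"] = m2 - m1
    hi = np.maximum(m1, m2)
    lo = np.minimum(m1, m2)
    with np.errstate(divide="ignore"):
        out["fold_change"] = np.where(lo > 0, hi / lo, np.inf)
    return out


def filter_significant(
    events: pd.DataFrame,
    alpha: float = 0.05,
    min_coverage: float = 20.0,
    min_delta: float = 0.2,
    min_fold_change: float = 1.5,
    adj_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Apply the APA significance filter and return surviving events.

    Rules, with their boundary conventions:

    1. 3'-UTR read coverage strictly > ``min_coverage``;
    2. adjusted p-value (``adj_method``, computed across the post-coverage
       set) <= ``alpha``;
    3. |mean dPDUI| >= ``min_delta``;
    4. mean-PDUI fold change >= ``min_fold_change``.

    The filter is order-invariant and idempotent, and tightening any
    threshold never adds survivors.
    """
    if events["p_value"].isna().any():
        raise ValueError("missing p-values")
    df = summarize_events(events)
    df = df[df["coverage"] > min_coverage].copy()
    if df.empty:
        df["adj_p"] = pd.Series(dtype=float)
        return df
    df["adj_p"] = multipletests(df["p_value"].to_numpy(), method=adj_method)[1]
    keep = (
        (df["adj_p"] <= alpha)
        & (df["delta_pdui"].abs() >= min_delta)
        & (df["fold_change"] >= min_fold_change)
    )
    return df[keep].reset_index(drop=True)


def direction_shift_test(
    events: pd.DataFrame,
    direction: str = "lengthened",
    alternative: str = "greater",
) -> float:
    """Exact binomial test of the direction of 3'-UTR shift among events.

    Counts events whose dPDUI sign matches ``direction`` ("lengthened" =
    positive, "shortened" = negative) among all events with nonzero dPDUI and
    tests against a null proportion of 0.5.  ``alternative`` follows the
    standard convention (default one-sided toward the stated direction).
    """
    if direction not in ("lengthened", "shortened"):
        raise ValueError("direction must be 'lengthened' or 'shortened'")
    if "delta_pdui" not in events.columns:
        events = summarize_events(events)
    delta = events["delta_pdui"].to_numpy()
    nonzero = delta[delta != 0]
    if nonzero.size == 0:
        raise ValueError("all dPDUI values are zero")
    sign = 1 if direction == "lengthened" else -1
    k = int(np.sum(np.sign(nonzero) == sign))
    return float(binomtest(k, nonzero.size, 0.5, alternative=alternative).pvalue)
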