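"""Trait correlations on entry means, hybrid ranking against checks, and
percent yield advantage."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .tables import EntryMeans, TraitMeta


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with exact t-based critical values."""

    r: pd.DataFrame
    n: pd.DataFrame
    crit_05: pd.DataFrame
    crit_01: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        crit = self.crit_05 if alpha == 0.05 else self.crit_01
        return self.r.abs() > crit


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical Pearson r at sample size n (t distribution).

    At n = 160 entries this gives ~0.155 at the 5% level and ~0.203 at the
    1% level, the blanket thresholds often quoted for trait-correlation
    heatmaps of that size.
    """
    df = n - 2
    if df < 1:
        return float("nan")
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t ** 2))


def correlate_traits(blups: Union[EntryMeans, pd.DataFrame]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between traits on entry means.

    Constant traits give an undefined correlation, reported as NaN.  Each
    pair's critical value uses the pairwise-complete sample size.
    """
    mat = blups.across if isinstance(blups, EntryMeans) else blups
    traits = list(mat.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    c05 = np.full((k, k), np.nan)
    c01 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = mat[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if i == j:
                r[i, j] = 1.0 if x.std() > 0 else np.nan
            elif x.std() == 0 or y.std() == 0:
                r[i, j] = r[j, i] = np.nan
            else:
                r[i, j] = r[j, i] = float(stats.pearsonr(x, y)[0])
            c05[i, j] = c05[j, i] = critical_r(len(pair), 0.05)
            c01[i, j] = c01[j, i] = critical_r(len(pair), 0.01)
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        crit_05=pd.DataFrame(c05, index=idx, columns=idx),
        crit_01=pd.DataFrame(c01, index=idx, columns=idx))


# ---------------------------------------------------------------------------
# ranking

@dataclass
class RankingTable:
    """Entries ordered on a focal trait, with check flags and summaries."""

    table: pd.DataFrame              # ordered entries, 'is_check' column
    focal_trait: str
    direction: str
    top_k_mean: float
    hybrid_mean: float
    check_mean: float
    best_hybrid: str
    best_check: Optional[str]
    percent_advantage_best: Optional[float]


def percent_advantage(best_entry_value: float, best_check_value: float) -> float:
    """Percent yield advantage, 100 * (entry / check - 1); sign preserved.

    Display convention rounds to the nearest integer; the exact value is
    returned.
    """
    if best_check_value <= 0:
        raise ValueError("check value must be positive")
    return 100.0 * (best_entry_value / best_check_value - 1.0)


def rank_hybrids(means: Union[EntryMeans, pd.DataFrame], focal_trait: str,
                 checks: Sequence[str] = (), k: int = 10,
                 trait_meta: Optional[Mapping[str, TraitMeta]] = None
                 ) -> RankingTable:
    """Rank entries on a focal trait, respecting its selection direction.

    Grain yield ranks descending; damage/disease scores (direction
    ``'lower'``) rank ascending.  Ties are broken by entry label so the
    ordering is total and reruns are byte-identical.  Summary means cover the
    top-k hybrids, all hybrids, and the checks; the percent advantage
    compares the best hybrid with the best check.
    """
    if isinstance(means, EntryMeans):
        mat = means.across
        trait_meta = trait_meta or means.trait_meta
    else:
        mat = means
    if focal_trait not in mat.columns:
        raise ValueError(f"trait {focal_trait!r} not in entry means")
    meta = (trait_meta or {}).get(focal_trait, TraitMeta())
    ascending = meta.direction == "lower"

    df = mat.copy()
    df = df[df[focal_trait].notna()]
    df["is_check"] = df.index.isin(set(checks))
    # pre-sort on label, then stable-sort on the trait: label breaks ties
    df = df.loc[sorted(df.index)].sort_values(
        by=[focal_trait], ascending=ascending, kind="mergesort")

    hybrids = df[~df["is_check"]]
    checks_df = df[df["is_check"]]
    if k > len(hybrids):
        warnings.warn(f"k={k} exceeds the {len(hybrids)} hybrids; truncated",
                      stacklevel=2)
        k = len(hybrids)
    top = hybrids.head(k)
    best_hybrid = top.index[0] if len(top) else None
    best_check = None
    pct = None
    if len(checks_df):
        cvals = checks_df[focal_trait]
        best_check = cvals.idxmin() if ascending else cvals.idxmax()
        pct = percent_advantage(float(hybrids[focal_trait].iloc[0]),
                                float(cvals.loc[best_check]))
    return RankingTable(
        table=df, focal_trait=focal_trait, direction=meta.direction,
        top_k_mean=float(top[focal_trait].mean()),
        hybrid_mean=float(hybrids[focal_trait].mean()),
        check_mean=float(checks_df[focal_trait].mean()) if len(checks_df)
        else float("nan"),
        best_hybrid=best_hybrid, best_check=best_check,
        percent_advantage_best=pct)
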