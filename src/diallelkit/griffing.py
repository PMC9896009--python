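"""Griffing Method 4 (half-diallel, F1s only) fixed-model combining-ability analysis.

Given the ``p(p-1)/2`` cross means of a complete half-diallel, the model

    Y_ij = mu + g_i + g_j + s_ij

decomposes each cross mean into general combining ability (GCA) effects
``g_i`` of the two parents and a specific combining ability (SCA) deviation
``s_ij``, under the constraints ``sum_i g_i = 0`` and ``sum_j s_ij = 0`` for
every parent ``i``.  The closed-form solutions are

    g_i  = [p * Y_i. - 2 Y..] / [p (p - 2)]
    s_ij = Y_ij - (Y_i. + Y_j.) / (p - 2) + 2 Y.. / [(p - 1)(p - 2)]

where ``Y_i.`` sums the means of all crosses containing parent ``i`` and
``Y..`` sums over all crosses.  These coincide with the constrained
least-squares solution and reconstruct the data exactly:
``Y_ij = Ybar + g_i + g_j + s_ij``.

The multi-environment ANOVA partitions the hybrid sum of squares into GCA
and SCA and the hybrid-by-environment interaction into GCAxE and SCAxE, with
F-tests wired as is conventional for entry-mean combined analyses: hybrids
and environments are tested against the hybrid-by-environment mean square,
GCA and SCA against their own environment interactions, and the interaction
terms against the pooled plot error divided by the number of replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import Cross, DiallelDesign, cross_id, max_complete_subset  # noqa: F401

CrossMeans = Union[pd.Series, Mapping[Cross, float]]


# ---------------------------------------------------------------------------
# internal matrix plumbing

def _as_matrix(cross_means: CrossMeans, design: DiallelDesign) -> np.ndarray:
    """Symmetric p x p matrix of cross means (diagonal NaN)."""
    idx = design.parent_index()
    p = design.n_parents
    Y = np.full((p, p), np.nan)
    for key, val in cross_means.items():
        a, b = key if isinstance(key, tuple) else key.split("/")
        i, j = idx[a], idx[b]
        Y[i, j] = Y[j, i] = val
    missing = [c for c in design.crosses if np.isnan(Y[idx[c[0]], idx[c[1]]])]
    if missing:
        raise ValueError(
            f"{len(missing)} cross means missing (e.g. {missing[:3]}); "
            "restrict the design with max_complete_subset first")
    return Y


def _effects_from_matrix(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = Y.shape[0]
    if p < 3:
        raise ValueError("need at least 3 parents for the decomposition")
    Yi = np.nansum(Y, axis=1)           # row totals over crosses with parent i
    Ytot = Yi.sum() / 2.0               # grand total over crosses
    g = (p * Yi - 2.0 * Ytot) / (p * (p - 2.0))
    S = Y - (Yi[:, None] + Yi[None, :]) / (p - 2.0) \
        + 2.0 * Ytot / ((p - 1.0) * (p - 2.0))
    np.fill_diagonal(S, 0.0)
    return g, S


def sca_df(p: int) -> int:
    """Degrees of freedom of the SCA term in Method 4: p(p-3)/2."""
    return p * (p - 3) // 2


# ---------------------------------------------------------------------------
# effects

def gca_sca_effects(cross_means: CrossMeans,
                    design: DiallelDesign) -> tuple[pd.Series, pd.Series]:
    """GCA effects per parent and SCA effects per cross from cross means.

    Returns
    -------
    (gca, sca):
        ``gca`` indexed by parent label, ``sca`` by canonical cross tuple.
        ``sum(gca) == 0`` and ``sum_j sca[i, j] == 0`` for every parent.
    """
    Y = _as_matrix(cross_means, design)
    g, S = _effects_from_matrix(Y)
    gca = pd.Series(g, index=list(design.parents), name="gca")
    idx = design.parent_index()
    sca = pd.Series(
        [S[idx[a], idx[b]] for a, b in design.crosses],
        index=pd.Index(design.crosses, tupleize_cols=False), name="sca")
    return gca, sca


# ---------------------------------------------------------------------------
# ANOVA

def anova_method4(per_env_cross_means: Mapping[str, CrossMeans],
                  pooled_error_ms: float,
                  n_reps: int,
                  design: DiallelDesign,
                  error_df: Optional[float] = None,
                  rep_ms: Optional[float] = None,
                  rep_df: Optional[float] = None) -> pd.DataFrame:
    """Combined-environment combining-ability ANOVA on entry-mean basis.

    Parameters
    ----------
    per_env_cross_means:
        Mapping environment -> cross means (complete in every environment).
    pooled_error_ms:
        Plot-level pooled residual mean square from the stage-1 fits; the
        entry-mean error is ``pooled_error_ms / n_reps``.
    error_df:
        Degrees of freedom of the pooled error; defaults to
        ``n_envs * (n_crosses - 1) * (n_reps - 1)``.
    rep_ms, rep_df:
        Optional replicate-within-environment mean square for display.

    Returns a table with rows Environments, [Rep(Env)], Hybrids, GCA, SCA,
    HxE, GCAxE, SCAxE, Error and columns ``df, SS, MS, F, p``.  Sums of
    squares are additive: ``SS_H = SS_GCA + SS_SCA`` and
    ``SS_HxE = SS_GCAxE + SS_SCAxE``.
    """
    envs = sorted(per_env_cross_means)
    K = len(envs)
    p = design.n_parents
    nc = design.n_crosses
    mats = np.stack([_as_matrix(per_env_cross_means[e], design) for e in envs])
    iu = np.triu_indices(p, k=1)
    Yck = np.stack([m[iu] for m in mats], axis=1)       # crosses x envs
    grand = Yck.mean()
    env_means = Yck.mean(axis=0)
    cross_across = Yck.mean(axis=1)

    ss_env = nc * float(((env_means - grand) ** 2).sum())
    ss_h = K * float(((cross_across - grand) ** 2).sum())

    Yacross = mats.mean(axis=0)
    g, S = _effects_from_matrix(Yacross)
    ss_gca = K * (p - 2.0) * float((g ** 2).sum())
    ss_sca = K * float((S[iu] ** 2).sum())

    ss_gxe = ss_sxe = 0.0
    for k in range(K):
        gk, Sk = _effects_from_matrix(mats[k])
        ss_gxe += (p - 2.0) * float(((gk - g) ** 2).sum())
        ss_sxe += float(((Sk - S)[iu] ** 2).sum())
    ss_hxe = float(((Yck - cross_across[:, None] - env_means[None, :] + grand) ** 2).sum())

    df_g, df_s = p - 1, sca_df(p)
    df_h = nc - 1
    err_mean_ms = pooled_error_ms / n_reps
    if error_df is None:
        error_df = K * (nc - 1) * max(n_reps - 1, 1)

    rows = []

    def add(source, df, ss, ms, f_den_ms, f_den_df):
        if df <= 0 or ms is None:
            rows.append((source, df, ss, ms, np.nan, np.nan))
            return
        if f_den_ms is None or f_den_ms <= 0 or f_den_df <= 0:
            rows.append((source, df, ss, ms, np.nan, np.nan))
            return
        F = ms / f_den_ms
        pval = stats.f.sf(F, df, f_den_df)
        rows.append((source, df, ss, ms, F, pval))

    if K >= 2:
        ms_hxe = ss_hxe / (df_h * (K - 1))
        ms_gxe = ss_gxe / (df_g * (K - 1))
        ms_sxe = ss_sxe / (df_s * (K - 1)) if df_s > 0 else np.nan
        add("Environments", K - 1, ss_env, ss_env / (K - 1), ms_hxe, df_h * (K - 1))
        if rep_ms is not None:
            add("Rep(Env)", rep_df, np.nan, rep_ms, err_mean_ms, error_df)
        add("Hybrids", df_h, ss_h, ss_h / df_h, ms_hxe, df_h * (K - 1))
        add("GCA", df_g, ss_gca, ss_gca / df_g, ms_gxe, df_g * (K - 1))
        if df_s > 0:
            add("SCA", df_s, ss_sca, ss_sca / df_s, ms_sxe, df_s * (K - 1))
        add("HxE", df_h * (K - 1), ss_hxe, ms_hxe, err_mean_ms, error_df)
        add("GCAxE", df_g * (K - 1), ss_gxe, ms_gxe, err_mean_ms, error_df)
        if df_s > 0:
            add("SCAxE", df_s * (K - 1), ss_sxe, ms_sxe, err_mean_ms, error_df)
    else:
        warnings.warn(
            "single environment: interaction terms unavailable; GCA and SCA "
            "are tested against the entry-mean error", stacklevel=2)
        add("Hybrids", df_h, ss_h, ss_h / df_h, err_mean_ms, error_df)
        add("GCA", df_g, ss_gca, ss_gca / df_g, err_mean_ms, error_df)
        if df_s > 0:
            add("SCA", df_s, ss_sca, ss_sca / df_s, err_mean_ms, error_df)
    rows.append(("Error", error_df, err_mean_ms * error_df, err_mean_ms,
                 np.nan, np.nan))

    out = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
    return out.set_index("source")


# ---------------------------------------------------------------------------
# variance components, Baker's ratio, heritability

@dataclass
class VarianceComponents:
    var_gca: float
    var_sca: float
    truncated: bool = False
    method: str = "effects"


def variance_components(gca: pd.Series, sca: pd.Series,
                        anova: Optional[pd.DataFrame] = None,
                        n_envs: int = 1,
                        method: str = "effects") -> VarianceComponents:
    """GCA and SCA variance components from the combining-ability effects.

    The default ``'effects'`` estimator is the quadratic mean of the
    estimated effects, ``sum(g^2)/(p-1)`` and ``sum(s^2)/[p(p-3)/2]``.  When
    an ANOVA table is supplied, the sampling variance of the effects is
    subtracted using the corresponding environment-interaction mean squares
    (``MS_GCAxE / [K (p-2)]`` and ``MS_SCAxE / K``), which in the balanced
    case makes the estimator identical to the ``'ems'`` expected-mean-square
    form ``(MS - MS_xE) / [K (p-2)]`` resp. ``(MS - MS_xE)/K``.  Negative
    estimates are truncated at zero and flagged.
    """
    p = len(gca)
    if p < 4:
        raise ValueError("variance components need at least 4 parents")
    dfs = sca_df(p)
    if method == "ems":
        if anova is None:
            raise ValueError("method='ems' requires an ANOVA table")
        vg = (anova.loc["GCA", "MS"] - anova.loc["GCAxE", "MS"]) / (n_envs * (p - 2))
        vs = (anova.loc["SCA", "MS"] - anova.loc["SCAxE", "MS"]) / n_envs
    elif method == "effects":
        vg = float((gca ** 2).sum()) / (p - 1)
        vs = float((sca ** 2).sum()) / dfs
        if anova is not None and "GCAxE" in anova.index:
            vg -= anova.loc["GCAxE", "MS"] / (n_envs * (p - 2))
            vs -= anova.loc["SCAxE", "MS"] / n_envs
    else:
        raise ValueError(f"unknown method {method!r}")
    truncated = bool(vg < 0 or vs < 0)
    return VarianceComponents(max(vg, 0.0), max(vs, 0.0), truncated, method)


def baker_ratio(var_gca_hat: float, var_sca_hat: float) -> float:
    """Baker's ratio 2*var_GCA / (2*var_GCA + var_SCA).

    Values near 1 indicate predominantly additive gene action, hence high
    predictability of hybrid performance from parental GCA alone.  Undefined
    (NaN) when both components are zero.
    """
    if var_gca_hat < 0 or var_sca_hat < 0:
        raise ValueError("variance components must be nonnegative")
    denom = 2.0 * var_gca_hat + var_sca_hat
    if denom == 0:
        return float("nan")
    return 2.0 * var_gca_hat / denom


def heritability(var_g: float, var_ge: float, var_err: float,
                 n_envs: int, n_reps: int) -> float:
    """Entry-mean (broad-sense) heritability.

    H^2 = var_g / (var_g + var_ge / nE + var_err / (nE * nR)), the
    repeatability of genotype means across ``nE`` environments with ``nR``
    replicates each, clamped to [0, 1].
    """
    if min(var_g, var_ge, var_err) < 0:
        raise ValueError("variances must be nonnegative")
    if n_envs < 1 or n_reps < 1:
        raise ValueError("n_envs and n_reps must be >= 1")
    denom = var_g + var_ge / n_envs + var_err / (n_envs * n_reps)
    if denom == 0:
        raise ValueError("all variance components are zero")
    return float(np.clip(var_g / denom, 0.0, 1.0))


def heritability_from_anova(anova: pd.DataFrame, pooled_error_ms: float,
                            n_reps: int, n_envs: int) -> float:
    """Entry-mean heritability with components read off the combined ANOVA.

    On entry-mean basis, E[MS_H] = sigma_e^2/r + sigma_ge^2 + K sigma_g^2 and
    E[MS_HxE] = sigma_e^2/r + sigma_ge^2, so sigma_g^2 = (MS_H - MS_HxE)/K
    and sigma_ge^2 = MS_HxE - pooled_error/r (each truncated at zero).
    """
    ms_h = anova.loc["Hybrids", "MS"]
    ms_hxe = anova.loc["HxE", "MS"] if "HxE" in anova.index else np.nan
    err_mean = pooled_error_ms / n_reps
    if np.isnan(ms_hxe):
        var_g = max((ms_h - err_mean), 0.0)
        var_ge = 0.0
    else:
        var_g = max((ms_h - ms_hxe) / n_envs, 0.0)
        var_ge = max(ms_hxe - err_mean, 0.0)
    return heritability(var_g, var_ge, pooled_error_ms, n_envs, n_reps)


# ---------------------------------------------------------------------------
# t-tests on effects

def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def effect_tests(gca: pd.Series, sca: pd.Series, pooled_error_ms: float,
                 n_reps: int, n_envs: int, design: DiallelDesign,
                 error_df: Optional[float] = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standard errors, t statistics and two-sided p-values for the effects.

    With the entry-mean error variance ``s2 = pooled_error_ms/(r*E)``, the
    balanced Method 4 sampling variances are

        Var(g_i)  = (p - 1) / [p (p - 2)] * s2
        Var(s_ij) = (p - 3) / (p - 1)    * s2

    identical for every parent resp. cross by design symmetry.
    """
    if pooled_error_ms <= 0:
        raise ValueError("pooled error MS must be positive")
    p = design.n_parents
    s2 = pooled_error_ms / (n_reps * n_envs)
    if error_df is None:
        error_df = n_envs * (design.n_crosses - 1) * max(n_reps - 1, 1)
    se_g = float(np.sqrt((p - 1) / (p * (p - 2)) * s2))
    se_s = float(np.sqrt((p - 3) / (p - 1) * s2))

    def table(effects: pd.Series, se: float) -> pd.DataFrame:
        t = effects / se
        pvals = 2.0 * stats.t.sf(np.abs(t), error_df)
        return pd.DataFrame({
            "effect": effects, "se": se, "t": t, "p": pvals,
            "sig": [_stars(v) for v in pvals]})

    return table(gca, se_g), table(sca, se_s)


# ---------------------------------------------------------------------------
# bundled result

@dataclass
class CombiningAbilityResult:
    """Full combining-ability analysis for one management regime."""

    design: DiallelDesign
    n_envs: int
    n_reps: int
    gca: pd.DataFrame                 # parents x traits
    sca: pd.DataFrame                 # crosses x traits
    gca_tests: dict[str, pd.DataFrame] = field(default_factory=dict)
    sca_tests: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    var_gca: pd.Series = None
    var_sca: pd.Series = None
    baker: pd.Series = None
    heritability: pd.Series = None


def combining_ability_analysis(per_env_cross_means: Mapping[str, pd.DataFrame],
                               pooled_error_ms: Mapping[str, float],
                               n_reps: int,
                               design: DiallelDesign,
                               error_df: Optional[Mapping[str, float]] = None,
                               varcomp_method: str = "effects"
                               ) -> CombiningAbilityResult:
    """Run effects, ANOVA, variance components and tests for every trait.

    ``per_env_cross_means`` maps environment -> DataFrame (rows indexed by
    cross tuple, one column per trait), as produced by
    :func:`diallelkit.entry_means.cross_mean_tables`.
    """
    envs = sorted(per_env_cross_means)
    n_envs = len(envs)
    traits = list(per_env_cross_means[envs[0]].columns)
    across = sum(per_env_cross_means[e][traits] for e in envs) / n_envs

    gca_cols, sca_cols = {}, {}
    gca_tests, sca_tests, anovas = {}, {}, {}
    vg, vs, bk, h2 = {}, {}, {}, {}
    for trait in traits:
        gca, sca = gca_sca_effects(across[trait], design)
        gca_cols[trait], sca_cols[trait] = gca, sca
        err = float(pooled_error_ms[trait])
        edf = None if error_df is None else float(error_df[trait])
        an = anova_method4({e: per_env_cross_means[e][trait] for e in envs},
                           err, n_reps, design, error_df=edf)
        anovas[trait] = an
        g_t, s_t = effect_tests(gca, sca, err, n_reps, n_envs, design,
                                error_df=edf)
        gca_tests[trait], sca_tests[trait] = g_t, s_t
        comp = variance_components(gca, sca, anova=an, n_envs=n_envs,
                                   method=varcomp_method)
        vg[trait], vs[trait] = comp.var_gca, comp.var_sca
        bk[trait] = baker_ratio(comp.var_gca, comp.var_sca) \
            if (comp.var_gca or comp.var_sca) else float("nan")
        h2[trait] = heritability_from_anova(an, err, n_reps, n_envs)

    return CombiningAbilityResult(
        design=design, n_envs=n_envs, n_reps=n_reps,
        gca=pd.DataFrame(gca_cols), sca=pd.DataFrame(sca_cols),
        gca_tests=gca_tests, sca_tests=sca_tests, anova=anovas,
        var_gca=pd.Series(vg), var_sca=pd.Series(vs),
        baker=pd.Series(bk), heritability=pd.Series(h2))
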