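"""Stage-1 trial analysis: outlier screening, per-environment BLUEs/BLUPs,
and across-environment entry means.

Each environment (a management regime at a location/season) is analysed with
the model

    value = mean + replicate + block(replicate) + entry + residual

with replicate fixed, incomplete block random, and entry either fixed
(BLUEs) or random (BLUPs, shrunken towards the grand mean).  The
across-environment model adds a fixed environment effect and a random
entry-by-environment interaction.  Variance components come from EM-REML on
the mixed-model equations.  The pooled plot error mean square and the
replicate/environment counts are carried forward because the
combining-ability stage tests effects on an entry-mean basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import DiallelDesign, cross_label
from .mixedlm import MixedFit, dummies, fit_mixed
from .tables import EntryMeans, PhenotypeTable


# ---------------------------------------------------------------------------
# outlier screening

def detect_outliers(pheno: PhenotypeTable, z_threshold: float = 3.5) -> PhenotypeTable:
    """Flag plot values with extreme standardized residuals.

    Within each environment x trait the residual is taken from the additive
    two-way fit on entry and replicate means; values whose residual exceeds
    ``z_threshold`` residual standard deviations are flagged in a boolean
    ``outlier`` column.  Flagged rows are excluded by the downstream fits
    but never deleted.  Environments with fewer than two replicates cannot
    form residuals and are skipped with a warning.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    df = pheno.data.copy()
    flags = np.zeros(len(df), dtype=bool)
    for (env, trait), sub in df.groupby(["environment", "trait"], sort=False):
        sub = sub.dropna(subset=["value"])
        reps = sub["replicate"].unique()
        if len(reps) < 2:
            warnings.warn(
                f"environment {env!r}, trait {trait!r}: fewer than 2 "
                "replicates, outliers not screened", stacklevel=2)
            continue
        grand = sub["value"].mean()
        ent_mean = sub.groupby("entry")["value"].transform("mean")
        rep_mean = sub.groupby("replicate")["value"].transform("mean")
        resid = sub["value"] - ent_mean - rep_mean + grand
        a = sub["entry"].nunique()
        b = len(reps)
        dof = max((a - 1) * (b - 1), 1)
        sd = float(np.sqrt((resid ** 2).sum() / dof))
        if sd == 0:
            continue
        flags[df.index.get_indexer(sub.index)] |= (resid.abs() / sd > z_threshold).to_numpy()
    df["outlier"] = flags
    return PhenotypeTable(data=df, trait_meta=dict(pheno.trait_meta))


# ---------------------------------------------------------------------------
# per-environment model

@dataclass
class EnvFit:
    """Per-environment stage-1 fit for one trait."""

    entry_values: pd.Series          # BLUE or BLUP per entry
    resid_var: float
    resid_df: float
    var_components: dict
    converged: bool


def _design_one_env(sub: pd.DataFrame, entry_effect: str):
    """Build X / Z for ``value = mean + rep + block(rep) + entry + resid``."""
    n = len(sub)
    Xcols = [np.ones((n, 1))]
    rep_d, _ = dummies(sub["replicate"].tolist(), drop_first=True)
    if rep_d.shape[1]:
        Xcols.append(rep_d)
    entries = sorted(sub["entry"].unique())
    ent_d_full, _ = dummies(sub["entry"].tolist(), drop_first=False)

    Z_list, z_names = [], []
    blocks = (sub["replicate"].astype(str) + ":" + sub["block"].astype(str)).tolist()
    if sub.groupby("replicate")["block"].nunique().max() > 1:
        bd, _ = dummies(blocks)
        Z_list.append(bd)
        z_names.append("block")
    if entry_effect == "fixed":
        ent_d, _ = dummies(sub["entry"].tolist(), drop_first=True)
        Xcols.append(ent_d)
    else:
        Z_list.append(ent_d_full)
        z_names.append("entry")
    X = np.hstack(Xcols)
    return X, Z_list, z_names, entries, ent_d_full


def fit_env_model(pheno: PhenotypeTable, environment: str,
                  entry_effect: str = "fixed",
                  traits: Optional[Sequence[str]] = None) -> dict[str, EnvFit]:
    """Per-environment entry means (BLUEs if entry fixed, BLUPs if random)."""
    if entry_effect not in ("fixed", "random"):
        raise ValueError("entry_effect must be 'fixed' or 'random'")
    data = pheno.clean
    data = data[(data["environment"] == environment) & data["value"].notna()]
    if data.empty:
        raise ValueError(f"no data for environment {environment!r}")
    out: dict[str, EnvFit] = {}
    for trait in (traits or sorted(data["trait"].unique())):
        sub = data[data["trait"] == trait]
        if sub["entry"].nunique() < 2:
            raise ValueError(
                f"environment {environment!r}, trait {trait!r}: need >= 2 entries")
        X, Z_list, z_names, entries, ent_full = _design_one_env(sub, entry_effect)
        fit = fit_mixed(sub["value"].to_numpy(), X, Z_list)
        out[trait] = _extract_entry_values(fit, X, z_names, entries, ent_full,
                                           sub, entry_effect)
    return out


def _extract_entry_values(fit: MixedFit, X, z_names, entries, ent_full,
                          sub, entry_effect) -> EnvFit:
    n = X.shape[0]
    if entry_effect == "fixed":
        # LS-mean: entry coefficient plus the average of the other fixed terms
        n_ent_cols = len(entries) - 1
        base_cols = X[:, :X.shape[1] - n_ent_cols]
        base = base_cols.mean(axis=0) @ fit.beta[:X.shape[1] - n_ent_cols]
        coef = np.concatenate([[0.0], fit.beta[X.shape[1] - n_ent_cols:]])
        values = base + coef
    else:
        base = X.mean(axis=0) @ fit.beta
        u_entry = fit.u[z_names.index("entry")]
        values = base + u_entry
    series = pd.Series(values, index=entries, name="value")
    var_components = dict(zip(z_names, fit.var_u))
    var_components["residual"] = fit.var_e
    return EnvFit(entry_values=series, resid_var=fit.var_e,
                  resid_df=fit.resid_df, var_components=var_components,
                  converged=fit.converged)


# ---------------------------------------------------------------------------
# across-environment combination

def _nested_rep_dummies(env: Sequence[str], rep: Sequence[str]) -> np.ndarray:
    """Replicate-within-environment dummies, first replicate per env dropped."""
    cols = []
    envs = sorted(set(env))
    env = np.asarray(env)
    rep = np.asarray(rep)
    for e in envs:
        reps = sorted(set(rep[env == e]))
        for r in reps[1:]:
            cols.append(((env == e) & (rep == r)).astype(float))
    if not cols:
        return np.empty((len(env), 0))
    return np.column_stack(cols)


def combine_across_env(pheno: PhenotypeTable, entry_effect: str = "fixed",
                       traits: Optional[Sequence[str]] = None) -> EntryMeans:
    """Stage-1 across-environment analysis.

    Runs the per-environment fixed-entry fits (whose residual mean squares
    are pooled with df weights), then the across-environment model with
    environment fixed and entry-by-environment random.  Entries missing in
    some environments are retained through the mixed model rather than
    dropped; design completeness for the diallel is enforced separately.
    """
    envs = pheno.environments()
    if len(envs) < 2:
        raise ValueError("across-environment analysis needs >= 2 environments")
    traits = list(traits or pheno.traits())
    data = pheno.clean
    data = data[data["value"].notna()]

    per_env_fits = {env: fit_env_model(pheno, env, "fixed", traits)
                    for env in envs}
    per_env_entries = [set(per_env_fits[e][traits[0]].entry_values.index)
                       for e in envs]
    if not set.union(*per_env_entries) or not set.intersection(*per_env_entries):
        raise ValueError("no overlapping entries across environments")

    pooled_ms, pooled_df = {}, {}
    for trait in traits:
        num = sum(per_env_fits[e][trait].resid_var * per_env_fits[e][trait].resid_df
                  for e in envs)
        den = sum(per_env_fits[e][trait].resid_df for e in envs)
        pooled_ms[trait] = num / den if den > 0 else 0.0
        pooled_df[trait] = den

    across_cols, varcomps = {}, {}
    for trait in traits:
        sub = data[data["trait"] == trait]
        n = len(sub)
        env_v = sub["environment"].astype(str).tolist()
        rep_v = sub["replicate"].astype(str).tolist()
        ent_v = sub["entry"].tolist()
        Xcols = [np.ones((n, 1))]
        env_d, _ = dummies(env_v, drop_first=True)
        if env_d.shape[1]:
            Xcols.append(env_d)
        Xcols.append(_nested_rep_dummies(env_v, rep_v))
        entries = sorted(set(ent_v))
        ge_labels = [f"{e}:{v}" for e, v in zip(ent_v, env_v)]
        ge_d, _ = dummies(ge_labels)
        Z_list, z_names = [ge_d], ["entry_env"]
        if entry_effect == "fixed":
            ent_d, _ = dummies(ent_v, drop_first=True)
            Xcols.append(ent_d)
        else:
            ent_full, _ = dummies(ent_v)
            Z_list.insert(0, ent_full)
            z_names.insert(0, "entry")
        X = np.hstack(Xcols)
        fit = fit_mixed(sub["value"].to_numpy(), X, Z_list)
        if entry_effect == "fixed":
            n_ent = len(entries) - 1
            base = X[:, :X.shape[1] - n_ent].mean(axis=0) @ fit.beta[:X.shape[1] - n_ent]
            coef = np.concatenate([[0.0], fit.beta[X.shape[1] - n_ent:]])
            values = base + coef
        else:
            base = X.mean(axis=0) @ fit.beta
            values = base + fit.u[z_names.index("entry")]
        across_cols[trait] = pd.Series(values, index=entries)
        vc = dict(zip(z_names, fit.var_u))
        vc["residual"] = fit.var_e
        varcomps[trait] = vc

    per_env = {
        env: pd.DataFrame({t: per_env_fits[env][t].entry_values for t in traits})
        for env in envs}
    n_reps = int(data.groupby(["environment", "trait"])["replicate"].nunique().max())
    return EntryMeans(per_env=per_env, across=pd.DataFrame(across_cols),
                      pooled_error_ms=pooled_ms, pooled_error_df=pooled_df,
                      n_reps=n_reps, n_envs=len(envs),
                      trait_meta=dict(pheno.trait_meta),
                      across_varcomp=varcomps, entry_effect=entry_effect)


# ---------------------------------------------------------------------------
# hand-off to the diallel stage

def cross_mean_tables(em: EntryMeans, design: DiallelDesign
                      ) -> dict[str, pd.DataFrame]:
    """Per-environment cross-mean tables (checks dropped, crosses as tuples)."""
    out = {}
    for env, mat in em.per_env.items():
        labels = [cross_label(c) for c in design.crosses]
        missing = [l for l in labels if l not in mat.index]
        if missing:
            raise ValueError(
                f"environment {env!r} lacks entries {missing[:3]}...; use "
                "max_complete_subset to restrict the design")
        sub = mat.loc[labels]
        sub.index = pd.Index(design.crosses, tupleize_cols=False)
        out[env] = sub
    return out
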