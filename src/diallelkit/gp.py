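"""Genomic and GCA-based prediction of untested single-cross hybrids.

Marker workflow: quality-filter the parental SNP panel (missingness, then
monomorphic markers, then minor-allele frequency), impute remaining missing
calls with the observed allele frequency, and build the realized genomic
relationship matrix

    G = W W' / (2 sum_m p_m (1 - p_m)),   W = dosage - 2 p

(VanRaden's first method).  Hybrid-specific (SCA) effects have the
Kronecker-structured covariance Cov(h_ij, h_kl) proportional to products of
parental relationships; because a half-diallel has a single parent pool and
unordered crosses, the symmetrized form

    H[(i,j),(k,l)] = (G_ik G_jl + G_il G_jk) / 2

is used, which is positive semi-definite whenever G is and reduces to the
two-pool Kronecker product when parent roles are distinct.

The prediction model is the hybrid GBLUP

    y = mu + Z g + Z_h h + e,   g ~ N(0, sigma_g^2 G),  h ~ N(0, sigma_H^2 H)

where Z sums the two parental incidences (single pool: one GCA vector tied
across parent roles).  Variance components are estimated by EM-REML on the
mixed-model equations or by a Gibbs sampler with scaled-inverse-chi-square
priors.  Two validation schemes are provided: leave-one-hybrid-out
GCA prediction (refit the Method 4 GCA effects without the focal cross and
predict it as mean + g_i + g_j) and seeded k-fold cross-validation of the
marker model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import Cross, DiallelDesign, cross_id
from .mixedlm import fit_mixed
from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)

PSD_TOL = 1e-8


# ---------------------------------------------------------------------------
# kinships

@dataclass
class KinshipMatrix:
    """Symmetric realized-relationship matrix with labelled rows/columns."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def is_psd(self, tol: float = PSD_TOL) -> bool:
        scale = max(1.0, float(np.abs(self.values).max()))
        return self.min_eigenvalue() >= -tol * scale

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# marker QC

def filter_markers(geno: GenotypeMatrix, max_missing: float = 0.15,
                   maf_min: float = 0.05) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Marker quality control, applied in a fixed auditable order.

    1. drop markers with missing-call fraction strictly above ``max_missing``;
    2. drop monomorphic markers (allele frequency 0 or 1 among observed calls,
       which allele-frequency imputation cannot rescue);
    3. drop markers with minor allele frequency strictly below ``maf_min``
       (a marker at exactly ``maf_min`` is retained).

    Returns the filtered panel and a ledger of marker counts after each step.
    """
    ledger = {"input": geno.n_markers}
    miss = geno.missing_fraction
    keep = miss <= max_missing
    ledger["after_missing_filter"] = int(keep.sum())

    calls = geno.calls[:, keep]
    markers = [m for m, k in zip(geno.markers, keep) if k]
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    calls, markers = calls[:, poly], [m for m, k in zip(markers, poly) if k]
    ledger["after_monomorphic_filter"] = int(poly.sum())

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= maf_min
    calls, markers = calls[:, keep_maf], [m for m, k in zip(markers, keep_maf) if k]
    ledger["after_maf_filter"] = int(keep_maf.sum())

    if not markers:
        raise ValueError("marker QC removed every marker")
    for step, count in ledger.items():
        logger.info("marker QC %s: %d markers", step, count)
    return GenotypeMatrix(parents=list(geno.parents), markers=markers,
                          calls=calls), ledger


def impute_allele_freq(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean dosage ``2 p-hat``.

    Non-missing calls are untouched, so the per-marker mean dosage (hence the
    allele frequency) is unchanged by imputation.
    """
    calls = geno.calls
    if not np.isnan(calls).any():
        return GenotypeMatrix(parents=list(geno.parents),
                              markers=list(geno.markers), calls=calls.copy(),
                              imputed=geno.imputed)
    if np.isnan(calls).all(axis=0).any():
        raise ValueError("some markers have no observed calls")
    with np.errstate(invalid="ignore"):
        mean_dosage = np.nanmean(calls, axis=0)
    out = np.where(np.isnan(calls), mean_dosage, calls)
    return GenotypeMatrix(parents=list(geno.parents),
                          markers=list(geno.markers), calls=out, imputed=True)


def vanraden_G(geno: GenotypeMatrix) -> KinshipMatrix:
    """Realized genomic relationship matrix from centred SNP dosages."""
    calls = geno.calls
    if np.isnan(calls).any():
        raise ValueError("impute missing calls before computing G")
    p = calls.mean(axis=0) / 2.0
    denom = 2.0 * float((p * (1.0 - p)).sum())
    if denom <= 0:
        raise ValueError("all markers are monomorphic; G undefined")
    W = calls - 2.0 * p
    G = W @ W.T / denom
    return KinshipMatrix(labels=list(geno.parents), values=G)


def hybrid_H(G: KinshipMatrix, crosses: Sequence[Cross]) -> KinshipMatrix:
    """Hybrid (SCA) covariance restricted to the given unordered crosses.

    Crosses whose parents are not all genotyped are excluded with a warning,
    mirroring the situation where only part of the parent set has marker
    data.
    """
    idx = {lab: i for i, lab in enumerate(G.labels)}
    kept = []
    for c in crosses:
        c = cross_id(*c)
        if c[0] in idx and c[1] in idx:
            kept.append(c)
        else:
            warnings.warn(f"cross {c} references an ungenotyped parent; "
                          "excluded from the hybrid covariance", stacklevel=2)
    if not kept:
        raise ValueError("no crosses with fully genotyped parents")
    M = G.values
    n = len(kept)
    H = np.empty((n, n))
    for a, (i, j) in enumerate(kept):
        ii, jj = idx[i], idx[j]
        for b, (k, l) in enumerate(kept[:a + 1]):
            kk, ll = idx[k], idx[l]
            H[a, b] = H[b, a] = 0.5 * (M[ii, kk] * M[jj, ll]
                                       + M[ii, ll] * M[jj, kk])
    return KinshipMatrix(labels=kept, values=H)


# ---------------------------------------------------------------------------
# GBLUP

@dataclass
class GBLUPModel:
    """Fitted single-pool hybrid GBLUP."""

    mu: float
    gca: pd.Series                  # BLUP of parental GCA
    sca: pd.Series                  # BLUP of hybrid SCA, indexed by cross
    var_g: float
    var_h: float
    var_e: float
    crosses: list[Cross]
    method: str
    converged: bool
    n_iter: int
    fitted: pd.Series = None

    def predict(self, crosses: Sequence[Cross]) -> pd.Series:
        vals = []
        sca = self.sca
        for c in crosses:
            c = cross_id(*c)
            s = float(sca.get(c, 0.0))
            vals.append(self.mu + self.gca[c[0]] + self.gca[c[1]] + s)
        return pd.Series(vals, index=pd.Index([cross_id(*c) for c in crosses],
                                              tupleize_cols=False))


def _factor(K: np.ndarray) -> np.ndarray:
    """PSD square root K = L L' via eigendecomposition with clipped spectrum."""
    w, V = np.linalg.eigh(K)
    scale = max(float(w[-1]), 1.0)
    if w[0] < -PSD_TOL * scale:
        raise ValueError("matrix is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _reml_direct(y: np.ndarray, X: np.ndarray, Ks: Sequence[np.ndarray]
                 ) -> tuple[float, list[float], bool, int]:
    """Profiled REML over the variance ratios gamma_k = sigma_k^2 / sigma_e^2.

    With V = sigma_e^2 (I + sum_k gamma_k K_k) the residual variance profiles
    out analytically; the remaining low-dimensional surface is maximised by
    L-BFGS-B on log(gamma).  This handles boundary components (a ratio
    drifting to zero) far more gracefully than EM, whose steps become
    vanishingly small near the boundary.
    """
    from scipy import optimize

    n = len(y)
    p = X.shape[1]
    eye = np.eye(n)

    def negloglik(log_gamma: np.ndarray) -> float:
        gam = np.exp(log_gamma)
        Vbar = eye + sum(g * K for g, K in zip(gam, Ks))
        try:
            L = np.linalg.cholesky(Vbar)
        except np.linalg.LinAlgError:
            return 1e30
        logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
        Vi_y = np.linalg.solve(Vbar, y)
        Vi_X = np.linalg.solve(Vbar, X)
        XtViX = X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return 1e30
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
        if ypy <= 0:
            return 1e30
        return (n - p) * np.log(ypy / (n - p)) + logdet_v + logdet_x

    x0 = np.zeros(len(Ks))
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B",
                            bounds=[(-14.0, 14.0)] * len(Ks))
    if not res.success:
        # line-search hiccups near a flat ridge are common; polish with a
        # derivative-free pass from the best point found so far
        polish = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                                   options={"xatol": 1e-6, "fatol": 1e-8,
                                            "maxiter": 2000})
        if polish.fun <= res.fun:
            res = polish
    if not np.isfinite(res.fun) or res.fun >= 1e30:
        raise RuntimeError(f"REML optimisation diverged: {res.message}")
    gam = np.exp(np.clip(res.x, -14.0, 14.0))
    Vbar = eye + sum(g * K for g, K in zip(gam, Ks))
    Vi_y = np.linalg.solve(Vbar, y)
    Vi_X = np.linalg.solve(Vbar, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    ypy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    var_e = ypy / (n - p)
    var_u = [float(g * var_e) if g > np.exp(-13.0) else 0.0 for g in gam]
    return float(var_e), var_u, True, int(res.nit)


def _gibbs(y, X, Zs, q, seed, n_iter, burn_in, thin, prior_df=5.0):
    """Gibbs sampler for the iid-parametrized model (flat prior on beta)."""
    rng = np.random.default_rng(seed)
    n = len(y)
    p = X.shape[1]
    W = np.hstack([X] + list(Zs))
    WtW = W.T @ W
    Wty = W.T @ y
    vy = float(np.var(y, ddof=1))
    nu = prior_df
    # prior scales split the phenotypic variance equally across terms
    n_terms = len(Zs) + 1
    S0 = vy / n_terms * (nu - 2.0) / nu if nu > 2 else vy / n_terms

    var_u = [vy / n_terms] * len(Zs)
    var_e = vy / n_terms
    theta = np.zeros(W.shape[1])
    keep_var = []
    keep_theta = []
    for it in range(n_iter):
        D = np.zeros(W.shape[1])
        off = p
        for k, qk in enumerate(q):
            D[off:off + qk] = var_e / var_u[k]
            off += qk
        C = WtW + np.diag(D)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            C = C + np.eye(len(D)) * 1e-8 * np.trace(C) / len(D)
            L = np.linalg.cholesky(C)
        mean = np.linalg.solve(L.T, np.linalg.solve(L, Wty))
        z = rng.standard_normal(len(D))
        theta = mean + np.sqrt(var_e) * np.linalg.solve(L.T, z)
        off = p
        for k, qk in enumerate(q):
            a = theta[off:off + qk]
            var_u[k] = (S0 * nu + float(a @ a)) / rng.chisquare(nu + qk)
            off += qk
        e = y - W @ theta
        var_e = (S0 * nu + float(e @ e)) / rng.chisquare(nu + n)
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_var.append([var_e] + list(var_u))
            keep_theta.append(theta.copy())
    vars_post = np.mean(keep_var, axis=0)
    theta_post = np.mean(keep_theta, axis=0)
    return theta_post, float(vars_post[0]), list(vars_post[1:]), len(keep_var)


def fit_gblup(y: Union[pd.Series, np.ndarray],
              crosses: Sequence[Cross],
              G: KinshipMatrix,
              method: str = "reml",
              seed: int = 0,
              *,
              H: Optional[KinshipMatrix] = None,
              fix_vars: Optional[tuple[float, float, float]] = None,
              n_iter: int = 10_000,
              burn_in: int = 1_000,
              thin: int = 5) -> GBLUPModel:
    """Fit the single-pool hybrid GBLUP ``y = mu + Z g + Z_h h + e``.

    ``fix_vars`` = (var_e, var_g, var_h) skips estimation and solves the
    mixed-model equations at the given components (the GLS/BLUP solution).
    ``method='gibbs'`` runs a seeded Gibbs sampler (scaled-inverse-chi-square
    priors with 5 df, scales splitting the phenotypic variance equally);
    posterior means are reported.
    """
    crosses = [cross_id(*c) for c in crosses]
    y = np.asarray(y, dtype=float)
    if len(y) != len(crosses):
        raise ValueError("y and crosses length mismatch")
    if len(crosses) < 10:
        raise ValueError("need at least 10 hybrids to fit the model")
    if not G.is_psd():
        raise ValueError("G is not positive semi-definite")
    parents = list(G.labels)
    pidx = {p: i for i, p in enumerate(parents)}
    for c in crosses:
        if c[0] not in pidx or c[1] not in pidx:
            raise ValueError(f"cross {c} references an ungenotyped parent")

    n = len(y)
    Z = np.zeros((n, len(parents)))
    for r, (a, b) in enumerate(crosses):
        Z[r, pidx[a]] += 1.0
        Z[r, pidx[b]] += 1.0
    if H is None:
        H = hybrid_H(G, crosses)
    if H.labels != crosses:
        Hmat = H.to_frame().loc[crosses, crosses].to_numpy()
    else:
        Hmat = H.values

    Lg = _factor(G.values)
    Lh = _factor(Hmat)
    Zg = Z @ Lg
    X = np.ones((n, 1))
    q = [Lg.shape[1], Lh.shape[1]]

    if method == "reml" or fix_vars is not None:
        if fix_vars is not None:
            var_e, var_g, var_h = (float(v) for v in fix_vars)
            converged, n_used = True, 0
            used_method = "fixed"
        else:
            if float(np.var(y, ddof=1)) <= 1e-14:
                var_e, var_g, var_h = 0.0, 0.0, 0.0
                converged, n_used, used_method = True, 0, "reml"
            else:
                Kg_full = Z @ G.values @ Z.T
                var_e, (var_g, var_h), converged, n_used = _reml_direct(
                    y, X, [Kg_full, Hmat])
                if not converged:
                    raise RuntimeError(
                        f"REML did not converge after {n_used} iterations "
                        f"(var_e={var_e:.4g}, var_g={var_g:.4g}, "
                        f"var_h={var_h:.4g})")
                used_method = "reml"
        fit = fit_mixed(y, X, [Zg, Lh],
                        fix_vars=(max(var_e, 1e-12),
                                  [max(var_g, 1e-12), max(var_h, 1e-12)]))
        mu = float(fit.beta[0])
        g = Lg @ fit.u[0]
        h = Lh @ fit.u[1]
    elif method == "gibbs":
        theta, var_e, var_us, n_kept = _gibbs(
            y, X, [Zg, Lh], q, seed, n_iter, burn_in, thin)
        mu = float(theta[0])
        a_g = theta[1:1 + q[0]]
        a_h = theta[1 + q[0]:]
        g = Lg @ a_g
        h = Lh @ a_h
        var_g, var_h = var_us
        converged = True
        n_used = n_kept
        used_method = "gibbs"
    else:
        raise ValueError(f"unknown method {method!r}")

    gca = pd.Series(g, index=parents)
    sca = pd.Series(h, index=pd.Index(crosses, tupleize_cols=False))
    fitted = pd.Series(mu + Z @ g + h,
                       index=pd.Index(crosses, tupleize_cols=False))
    return GBLUPModel(mu=mu, gca=gca, sca=sca, var_g=float(var_g),
                      var_h=float(var_h), var_e=float(var_e),
                      crosses=crosses, method=used_method,
                      converged=converged, n_iter=n_used, fitted=fitted)


# ---------------------------------------------------------------------------
# validation schemes

@dataclass
class PredictionResult:
    """Out-of-sample prediction summary for one validation scheme."""

    scheme: str
    correlations: dict[str, float]
    predictions: pd.DataFrame        # crosses x traits, out-of-sample
    observed: pd.DataFrame
    folds: Optional[pd.Series] = None
    per_fold: Optional[dict[str, list[float]]] = None
    seed: Optional[int] = None


def _as_trait_frame(cross_means, crosses) -> pd.DataFrame:
    if isinstance(cross_means, pd.DataFrame):
        df = cross_means
    elif isinstance(cross_means, pd.Series):
        df = cross_means.to_frame(cross_means.name or "value")
    else:
        df = pd.Series(cross_means).to_frame("value")
    idx = pd.Index([cross_id(*c) for c in crosses], tupleize_cols=False)
    return df.loc[idx]


def _gca_ls(y: np.ndarray, Z: np.ndarray) -> tuple[float, np.ndarray]:
    """Least squares for y = m + Z g under the constraint sum(g) = 0 (KKT)."""
    n, p = Z.shape
    A = np.zeros((p + 2, p + 2))
    rhs = np.zeros(p + 2)
    A[0, 0] = n
    A[0, 1:p + 1] = Z.sum(axis=0)
    A[1:p + 1, 0] = Z.sum(axis=0)
    A[1:p + 1, 1:p + 1] = Z.T @ Z
    A[1:p + 1, p + 1] = 1.0
    A[p + 1, 1:p + 1] = 1.0
    rhs[0] = y.sum()
    rhs[1:p + 1] = Z.T @ y
    sol = np.linalg.solve(A, rhs)
    return float(sol[0]), sol[1:p + 1]


def loo_gca_prediction(cross_means, design: DiallelDesign) -> PredictionResult:
    """Leave-one-hybrid-out GCA prediction, r(GCA, F1 performance).

    For each cross (i, j) the GCA effects are re-estimated by constrained
    least squares from all remaining crosses; the held-out hybrid is
    predicted as the refit mean plus g_i + g_j.  Reports the Pearson
    correlation between predictions and observations per trait.
    """
    if design.n_parents < 5:
        raise ValueError("leave-one-hybrid-out needs at least 5 parents")
    crosses = list(design.crosses)
    df = _as_trait_frame(cross_means, crosses)
    pidx = design.parent_index()
    nc = len(crosses)
    Z = np.zeros((nc, design.n_parents))
    for r, (a, b) in enumerate(crosses):
        Z[r, pidx[a]] = Z[r, pidx[b]] = 1.0

    preds = {}
    for trait in df.columns:
        y = df[trait].to_numpy()
        if np.isnan(y).any():
            raise ValueError(f"missing cross means for trait {trait!r}")
        out = np.empty(nc)
        for k in range(nc):
            mask = np.ones(nc, dtype=bool)
            mask[k] = False
            mu, g = _gca_ls(y[mask], Z[mask])
            a, b = crosses[k]
            out[k] = mu + g[pidx[a]] + g[pidx[b]]
        preds[trait] = out
    pred_df = pd.DataFrame(preds, index=df.index)
    cors = {t: float(stats.pearsonr(pred_df[t], df[t])[0]) for t in df.columns}
    return PredictionResult(scheme="loo-gca", correlations=cors,
                            predictions=pred_df, observed=df)


def cv_kfold(cross_means, crosses: Sequence[Cross], G: KinshipMatrix,
             k: int = 5, seed: int = 0, method: str = "reml",
             **fit_kwargs) -> PredictionResult:
    """Seeded k-fold cross-validation of the marker-based hybrid model.

    Hybrids are shuffled with the given seed and split into k folds of sizes
    differing by at most one.  Each fold is predicted from a model fitted on
    the remaining hybrids; G and H are built from all parents (the test
    hybrids' phenotypes are masked, their relationships are not).  Reports
    out-of-fold predictions pooled across folds, the pooled Pearson r per
    trait and the per-fold r values.
    """
    crosses = [cross_id(*c) for c in crosses]
    nc = len(crosses)
    if k < 2 or k > nc:
        raise ValueError("k must be between 2 and the number of hybrids")
    df = _as_trait_frame(cross_means, crosses)
    rng = np.random.default_rng(seed)
    order = rng.permutation(nc)
    fold_of = np.empty(nc, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        if len(chunk) == 0:
            raise ValueError("empty fold; reduce k")
        fold_of[chunk] = f

    H = hybrid_H(G, crosses)
    preds = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
    per_fold: dict[str, list[float]] = {t: [] for t in df.columns}
    for f in range(k):
        test = fold_of == f
        train_idx = [c for c, t in zip(crosses, test) if not t]
        test_idx = [c for c, t in zip(crosses, test) if t]
        for trait in df.columns:
            y_train = df.loc[train_idx, trait]
            model = fit_gblup(y_train, train_idx, G, method=method,
                              seed=seed + f, H=None, **fit_kwargs)
            # BLUP of test-hybrid SCA given the training SCA solutions
            Htr = H.to_frame()
            h_test = (Htr.loc[test_idx, train_idx].to_numpy()
                      @ np.linalg.pinv(Htr.loc[train_idx, train_idx].to_numpy())
                      @ model.sca.loc[train_idx].to_numpy())
            base = model.predict(test_idx) \
                + pd.Series(h_test, index=pd.Index(test_idx, tupleize_cols=False))
            preds.loc[test_idx, trait] = base.to_numpy()
            obs = df.loc[test_idx, trait]
            if len(test_idx) >= 3 and obs.std() > 0 and base.std() > 0:
                per_fold[trait].append(
                    float(stats.pearsonr(base.to_numpy(), obs.to_numpy())[0]))
    cors = {t: float(stats.pearsonr(preds[t], df[t])[0]) for t in df.columns}
    return PredictionResult(
        scheme="kfold-marker", correlations=cors, predictions=preds,
        observed=df,
        folds=pd.Series(fold_of, index=df.index), per_fold=per_fold, seed=seed)
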