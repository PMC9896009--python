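"""Synthetic half-diallel trials and parental SNP panels with known truth.

The generator emulates a multi-environment maize half-diallel evaluated in an
alpha-lattice layout with two replicates: each plot value is built from the
additive model

    Y_ii'k = mu + E_k + g_i + g_i' + s_ii' + (gE)_ik + (gE)_i'k + (sE)_ii'k
             + rep + block + e

with every random term drawn at a user-chosen variance, so each downstream
stage (entry means, combining-ability decomposition, genomic prediction) can
be tested against a known ground truth.  Ordinal 1-9 ratings (foliar damage,
ear damage, leaf diseases) are produced by thresholding the latent Gaussian
value at fixed equal-probability cut points.

Random-number streams are split per term (GCA, SCA, interactions, residual,
...) so changing one variance never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .design import Cross, DiallelDesign, cross_label
from .griffing import _effects_from_matrix
from .tables import PhenotypeTable, TraitMeta


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2) for the parents, NaN marking missing calls."""

    parents: list[str]
    markers: list[str]
    calls: np.ndarray  # parents x markers, float with NaN for missing
    imputed: bool = False  # allele-frequency imputation yields fractional dosages

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.parents), len(self.markers)):
            raise ValueError("calls shape does not match labels")
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent labels")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker labels")
        if self.imputed:
            ok = np.isfinite(self.calls) & (self.calls >= 0) & (self.calls <= 2)
        else:
            ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or missing")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing calls only."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.parents, columns=self.markers)


def simulate_founders(n_parents: int, n_markers: int,
                      maf_range: tuple[float, float] = (0.05, 0.5),
                      missing_rate: float = 0.0,
                      seed: int = 0) -> GenotypeMatrix:
    """Simulate a parental SNP panel at Hardy-Weinberg genotype frequencies.

    Per-marker minor-allele frequencies are drawn uniformly from
    ``maf_range`` before missingness; missing calls are then injected
    independently at ``missing_rate``.  Identical seeds give identical
    panels.
    """
    if n_parents < 4:
        raise ValueError("n_parents must be >= 4")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    ss = np.random.SeedSequence(seed)
    rng_freq, rng_geno, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))
    p = rng_freq.uniform(lo, hi, size=n_markers)
    calls = rng_geno.binomial(2, p, size=(n_parents, n_markers)).astype(float)
    if missing_rate > 0:
        mask = rng_miss.random(size=calls.shape) < missing_rate
        calls[mask] = np.nan
    width = max(2, len(str(n_parents)))
    parents = [f"P{i + 1:0{width}d}" for i in range(n_parents)]
    mwidth = max(5, len(str(n_markers)))
    markers = [f"M{i + 1:0{mwidth}d}" for i in range(n_markers)]
    return GenotypeMatrix(parents=parents, markers=markers, calls=calls)


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class SimTruth:
    """Known simulation truth for a single trait.

    ``true_gca`` sums to zero across parents and ``true_sca`` row-sums to
    zero over the partners of every parent, matching the constraints the
    estimators impose; variances are in squared trait units.
    """

    parent_ids: tuple[str, ...]
    grand_mean: float
    env_effects: dict[str, float]
    true_gca: dict[str, float]
    true_sca: dict[Cross, float]
    var_gca: float
    var_sca: float
    var_gca_e: float
    var_sca_e: float
    var_error: float
    marker_effects: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("var_gca", "var_sca", "var_gca_e", "var_sca_e", "var_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def hybrid_value(self, cross: Cross) -> float:
        """Noise-free across-environment expectation of a cross."""
        return (self.grand_mean + self.true_gca[cross[0]]
                + self.true_gca[cross[1]] + self.true_sca[cross])


def simulate_diallel_truth(geno: Union[GenotypeMatrix, Sequence[str]],
                           var_gca: float, var_sca: float,
                           *,
                           var_gca_e: float = 0.0,
                           var_sca_e: float = 0.0,
                           var_error: float = 1.0,
                           grand_mean: float = 0.0,
                           n_envs: int = 3,
                           env_sd: float = 1.0,
                           use_markers: bool = False,
                           seed: int = 0) -> SimTruth:
    """Draw GCA/SCA truth, optionally additive in marker dosage.

    With ``use_markers`` the parental GCA is a linear combination of
    allele-frequency-centred dosages, ``g_i = sum_m beta_m (x_im - 2 p_m)``,
    with the marker effects ``beta`` scaled so that the GCA variance equals
    ``var_gca`` in expectation; this makes GBLUP recovery well-posed.
    Otherwise GCA values are drawn independently.  SCA deviations are drawn
    per cross and projected onto the Method 4 constraint space (zero row
    sums), so ``var_sca = 0`` yields exactly zero SCA.
    """
    if var_gca < 0 or var_sca < 0:
        raise ValueError("variances must be nonnegative")
    if isinstance(geno, GenotypeMatrix):
        parents = tuple(geno.parents)
    else:
        parents = tuple(geno)
        if use_markers:
            raise ValueError("use_markers requires a GenotypeMatrix")
    p = len(parents)
    if p < 4:
        raise ValueError("need at least 4 parents")
    ss = np.random.SeedSequence(seed)
    rng_g, rng_s, rng_e, rng_b = (np.random.default_rng(s) for s in ss.spawn(4))

    marker_effects = None
    if use_markers:
        freqs = geno.allele_freqs
        dosages = np.where(np.isnan(geno.calls), 2.0 * freqs, geno.calls)
        centred = dosages - 2.0 * freqs
        beta = rng_b.standard_normal(geno.n_markers)
        # scale the combination so the realized GCA variance hits var_gca
        raw = centred @ beta
        v = float(raw.var(ddof=1))
        scale = np.sqrt(var_gca / v) if v > 0 else 0.0
        beta = beta * scale
        g = centred @ beta
        marker_effects = dict(zip(geno.markers, beta))
    else:
        g = rng_g.standard_normal(p) * np.sqrt(var_gca)
    g = g - g.mean()

    # SCA: iid draws projected onto the zero-row-sum constraint space
    raw = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    raw[iu] = rng_s.standard_normal(len(iu[0])) * np.sqrt(var_sca)
    raw = raw + raw.T
    if var_sca > 0:
        _, S = _effects_from_matrix(raw)
    else:
        S = np.zeros((p, p))

    env_effects = {f"E{k + 1}": float(rng_e.standard_normal() * env_sd)
                   for k in range(n_envs)}
    design = DiallelDesign(parents=parents)
    true_sca = {c: float(S[design.parent_index()[c[0]],
                           design.parent_index()[c[1]]])
                for c in design.crosses}
    return SimTruth(
        parent_ids=parents, grand_mean=grand_mean, env_effects=env_effects,
        true_gca={pp: float(v) for pp, v in zip(parents, g)},
        true_sca=true_sca, var_gca=var_gca, var_sca=var_sca,
        var_gca_e=var_gca_e, var_sca_e=var_sca_e, var_error=var_error,
        marker_effects=marker_effects)


# ---------------------------------------------------------------------------
# ordinal scales

def ordinalize(latent: np.ndarray, thresholds: Sequence[float],
               n_categories: Optional[int] = None) -> np.ndarray:
    """Threshold a latent continuous value into ordinal scores 1..K.

    The score is ``1 + (number of thresholds below the latent value)``; the
    mapping is monotone, so rank order is preserved up to ties.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or len(thr) < 1:
        raise ValueError("thresholds must be a non-empty 1-d sequence")
    if (np.diff(thr) <= 0).any():
        raise ValueError("thresholds must be strictly ascending")
    if n_categories is not None and len(thr) != n_categories - 1:
        raise ValueError("need n_categories - 1 thresholds")
    latent = np.asarray(latent, dtype=float)
    return (np.searchsorted(thr, latent, side="left") + 1).astype(float)


def equal_probability_thresholds(n_categories: int, mean: float,
                                 sd: float) -> np.ndarray:
    """Gaussian cut points giving equal probability to each of K categories."""
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if sd <= 0:
        raise ValueError("sd must be positive")
    qs = np.arange(1, n_categories) / n_categories
    return stats.norm.ppf(qs, loc=mean, scale=sd)


# ---------------------------------------------------------------------------
# field trials

def simulate_trials(truth: SimTruth, design: DiallelDesign,
                    n_envs: int, n_reps: int,
                    *,
                    trait: str = "GY",
                    trait_meta: Optional[TraitMeta] = None,
                    var_rep: float = 0.05,
                    var_block: float = 0.0,
                    n_blocks: int = 1,
                    seed: int = 0) -> PhenotypeTable:
    """Simulate plot-level data for a complete half-diallel plus checks.

    Every cross appears exactly once per environment x replicate (design
    closure).  Incomplete blocks are modelled as a random effect nested in
    replicate with variance ``var_block`` (default 0, which keeps the
    balanced-case oracles exact).  Check entries receive their own genetic
    value drawn at the total hybrid genetic variance ``2 var_gca + var_sca``.
    Ordinal traits are thresholded at fixed equal-probability nine-category
    cut points of the latent marginal distribution.
    """
    if set(design.parents) != set(truth.parent_ids):
        raise ValueError("design parents do not match the truth")
    if n_envs < 1 or n_reps < 1:
        raise ValueError("n_envs and n_reps must be >= 1")
    envs = sorted(truth.env_effects)
    if n_envs > len(envs):
        raise ValueError(
            f"truth carries only {len(envs)} environment effects")
    envs = envs[:n_envs]
    crosses = design.crosses
    checks = design.checks
    entries = [cross_label(c) for c in crosses] + list(checks)
    n_entry = len(entries)

    ss = np.random.SeedSequence(seed)
    keys = ["rep", "block", "gxe", "sxe", "resid", "check"]
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))

    pidx = design.parent_index()
    g = np.array([truth.true_gca[p] for p in design.parents])
    genetic = np.array([g[pidx[a]] + g[pidx[b]] + truth.true_sca[(a, b)]
                        for a, b in crosses])
    check_gen = rngs["check"].standard_normal(len(checks)) * np.sqrt(
        2 * truth.var_gca + truth.var_sca)
    entry_gen = np.concatenate([genetic, check_gen])

    gxe = rngs["gxe"].standard_normal((len(design.parents), n_envs)) \
        * np.sqrt(truth.var_gca_e)
    sxe = rngs["sxe"].standard_normal((len(crosses), n_envs)) \
        * np.sqrt(truth.var_sca_e)
    check_gxe = rngs["gxe"].standard_normal((len(checks), n_envs)) \
        * np.sqrt(2 * truth.var_gca_e + truth.var_sca_e)
    entry_gxe = np.empty((n_entry, n_envs))
    for ci, (a, b) in enumerate(crosses):
        entry_gxe[ci] = gxe[pidx[a]] + gxe[pidx[b]] + sxe[ci]
    if checks:
        entry_gxe[len(crosses):] = check_gxe

    rep_eff = rngs["rep"].standard_normal((n_envs, n_reps)) * np.sqrt(var_rep)
    block_of_entry = np.arange(n_entry) % max(n_blocks, 1)
    block_eff = rngs["block"].standard_normal((n_envs, n_reps, max(n_blocks, 1))) \
        * np.sqrt(var_block)
    resid = rngs["resid"].standard_normal((n_entry, n_envs, n_reps)) \
        * np.sqrt(truth.var_error)

    rows = []
    for k, env in enumerate(envs):
        for r in range(n_reps):
            rep_label = f"R{r + 1}"
            for ei, entry in enumerate(entries):
                b = block_of_entry[ei]
                val = (truth.grand_mean + truth.env_effects[env]
                       + rep_eff[k, r] + block_eff[k, r, b]
                       + entry_gen[ei] + entry_gxe[ei, k]
                       + resid[ei, k, r])
                rows.append((env, rep_label, f"B{b + 1}", entry, trait, val))
    df = pd.DataFrame(rows, columns=["environment", "replicate", "block",
                                     "entry", "trait", "value"])

    meta = trait_meta or TraitMeta()
    if meta.is_ordinal:
        lo, hi = meta.bounds
        k_cat = int(hi - lo + 1)
        total_sd = np.sqrt(2 * truth.var_gca + truth.var_sca
                           + 2 * truth.var_gca_e + truth.var_sca_e
                           + truth.var_error + var_rep + var_block
                           + np.var(list(truth.env_effects.values())) + 1e-12)
        thr = equal_probability_thresholds(k_cat, truth.grand_mean, total_sd)
        df["value"] = ordinalize(df["value"].to_numpy(), thr) + (lo - 1)
    return PhenotypeTable(data=df, trait_meta={trait: meta})


# ---------------------------------------------------------------------------
# multi-trait convenience

@dataclass(frozen=True)
class TraitSpec:
    """Generator settings for one trait (units are trait units)."""

    mean: float
    var_gca: float
    var_sca: float
    var_gca_e: float = 0.0
    var_sca_e: float = 0.0
    var_error: float = 1.0
    env_sd: float = 1.0
    scale: str = "continuous"
    direction: str = "higher"
    use_markers: bool = False

    def meta(self) -> TraitMeta:
        return TraitMeta(scale=self.scale, direction=self.direction)


#: Default study conditions: grain yield (t/ha), days to anthesis (days),
#: plant height (cm) and ordinal 1-9 fall-armyworm foliar/ear damage scores,
#: with GCA variance dominating SCA (additive-leaning gene action) and
#: non-trivial GCAxE / SCAxE interaction variance.
DEFAULT_TRAITS: dict[str, TraitSpec] = {
    "GY": TraitSpec(mean=5.0, var_gca=0.5, var_sca=0.25, var_gca_e=0.1,
                    var_sca_e=0.1, var_error=1.0, env_sd=1.0,
                    use_markers=True),
    "AD": TraitSpec(mean=62.0, var_gca=2.0, var_sca=0.8, var_gca_e=0.3,
                    var_sca_e=0.3, var_error=4.0, env_sd=2.0),
    "PH": TraitSpec(mean=180.0, var_gca=40.0, var_sca=15.0, var_gca_e=8.0,
                    var_sca_e=8.0, var_error=100.0, env_sd=20.0),
    "FD3": TraitSpec(mean=0.0, var_gca=0.3, var_sca=0.12, var_gca_e=0.06,
                     var_sca_e=0.06, var_error=0.5, env_sd=0.4,
                     scale="ordinal", direction="lower"),
    "ED": TraitSpec(mean=0.0, var_gca=0.35, var_sca=0.12, var_gca_e=0.06,
                    var_sca_e=0.06, var_error=0.45, env_sd=0.3,
                    scale="ordinal", direction="lower"),
}


def simulate_experiment(design: DiallelDesign,
                        n_envs: int, n_reps: int,
                        trait_specs: Optional[Mapping[str, TraitSpec]] = None,
                        n_markers: int = 2000,
                        maf_range: tuple[float, float] = (0.05, 0.5),
                        missing_rate: float = 0.05,
                        var_rep: float = 0.05,
                        var_block: float = 0.0,
                        n_blocks: int = 1,
                        seed: int = 0
                        ) -> tuple[PhenotypeTable, dict[str, SimTruth],
                                   GenotypeMatrix]:
    """One-call generator for a complete experiment (all traits + markers)."""
    specs = dict(trait_specs or DEFAULT_TRAITS)
    ss = np.random.SeedSequence(seed)
    child = {name: s for name, s in zip(
        ["geno"] + sorted(specs), ss.spawn(1 + len(specs)))}
    geno = simulate_founders(design.n_parents, n_markers, maf_range,
                             missing_rate,
                             seed=int(child["geno"].generate_state(1)[0] % 2**31))
    geno.parents = list(design.parents)

    frames, truths, metas = [], {}, {}
    for name in sorted(specs):
        spec = specs[name]
        tseed = int(child[name].generate_state(2)[0] % 2**31)
        truth = simulate_diallel_truth(
            geno, spec.var_gca, spec.var_sca, var_gca_e=spec.var_gca_e,
            var_sca_e=spec.var_sca_e, var_error=spec.var_error,
            grand_mean=spec.mean, n_envs=n_envs, env_sd=spec.env_sd,
            use_markers=spec.use_markers, seed=tseed)
        tab = simulate_trials(truth, design, n_envs, n_reps, trait=name,
                              trait_meta=spec.meta(), var_rep=var_rep,
                              var_block=var_block, n_blocks=n_blocks,
                              seed=int(child[name].generate_state(2)[1] % 2**31))
        frames.append(tab.data)
        truths[name] = truth
        metas[name] = spec.meta()
    pheno = PhenotypeTable(data=pd.concat(frames, ignore_index=True),
                           trait_meta=metas)
    return pheno, truths, geno
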