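# Methods

`diallelkit` implements the quantitative-genetic analysis of a
multi-environment maize half-diallel: stage-1 entry means, Griffing Method 4
combining-ability decomposition, variance-ratio summaries (Baker's ratio,
entry-mean heritability), trait correlations and hybrid ranking, and two
hybrid-prediction schemes (parental GCA and genome-wide markers). This note
records the models, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Models

### Plot model and stage 1

Each management regime at each location/season is one *environment*. The
plot model within an environment is

    y = mean + replicate + block(replicate) + entry + error

with replicate fixed, incomplete block random (alpha-lattice layout), and
entry either fixed (BLUEs) or random (BLUPs). The across-environment model
adds a fixed environment effect, replicate nested in environment, and a
random entry-by-environment interaction. Variance components are estimated
by EM-REML on Henderson's mixed-model equations (relative-change tolerance
1e-8, at most 500 iterations); entry means are LS-means (fixed) or the fixed
baseline plus the BLUP (random). The plot-level residual mean squares of the
per-environment fixed-entry fits are pooled with df weights; this pooled
error MS, with the replicate and environment counts, feeds the
combining-ability F-tests on an entry-mean basis.

Outlier screening happens before fitting: within each environment x trait,
the residual from the additive two-way fit on entry and replicate means is
standardized, and values beyond ``z = 3.5`` residual SDs are flagged (the
flag is carried, rows are never deleted). The threshold is a convention for
"gross recording error", not a tuned constant; with only two replicates the
screen has limited power because a single spike leaks into the paired plot's
residual and inflates the pooled SD.

### Griffing Method 4 (half-diallel of F1s, fixed effects)

On the complete table of cross means, GCA and SCA effects are the
closed-form constrained least-squares solutions

    g_i  = [p Y_i. - 2 Y..] / [p (p-2)]
    s_ij = Y_ij - (Y_i. + Y_j.)/(p-2) + 2 Y.. / [(p-1)(p-2)]

which reconstruct the data exactly and satisfy `sum g = 0` and per-parent
SCA row sums of zero. The combined ANOVA partitions hybrids into GCA
(df `p-1`) and SCA (df `p(p-3)/2`), and the hybrid-by-environment
interaction into GCAxE and SCAxE, all computed as quadratic forms of the
per-environment and across-environment effects, so the sums of squares are
additive by construction. F-tests follow the conventional entry-mean wiring:
hybrids and environments against HxE, GCA and SCA against their own
environment interactions, and the interaction terms against the pooled plot
error divided by the replicate count.

Incomplete cross sets are handled by `max_complete_subset`, which greedily
removes the parent with the most missing cells (ties to the
lexicographically smallest label) until the induced half-diallel is
complete; the procedure is deterministic and mirrors the common practice of
restricting a diallel analysis to fully realized parents.

### Variance components, Baker's ratio, heritability

The default variance-component estimator is the quadratic mean of the
effects, `sum(g^2)/(p-1)` and `sum(s^2)/[p(p-3)/2]`, minus the sampling
variance of the effects estimated from the corresponding environment
interaction mean squares (`MS_GCAxE/[K(p-2)]` and `MS_SCAxE/K`). Without
that correction the SCA component absorbs roughly the full entry-mean error
variance and Baker's ratio is biased downward by ~0.1 under realistic error
levels; with it, the estimator is unbiased in the balanced case and is then
algebraically identical to the expected-mean-square estimator, which is also
available (`method="ems"`). Negative estimates are truncated at zero and
flagged. When no ANOVA/error information is supplied, the raw quadratic
means are returned.

Baker's ratio `2 var_GCA / (2 var_GCA + var_SCA)` summarizes the relative
weight of additive gene action: near 1, hybrid performance is predictable
from parental GCA alone. Entry-mean heritability is

    H^2 = var_g / (var_g + var_ge/nE + var_e/(nE nR))

with `var_g = (MS_H - MS_HxE)/K` and `var_ge = MS_HxE - MS_err/nR` read off
the combined ANOVA (each truncated at zero), clamped to [0, 1].

### Genomic prediction

Marker QC runs in a fixed, logged order: markers with more than 15% missing
calls are dropped, then monomorphic markers, then markers with minor allele
frequency strictly below 0.05 (a marker exactly at the threshold is kept).
Remaining missing calls are imputed with the marker mean dosage `2 p-hat`,
which leaves allele frequencies unchanged. The genomic relationship matrix
is VanRaden's `G = WW'/(2 sum p(1-p))` on allele-frequency-centred 0/1/2
dosages.

The hybrid model is a single-pool GBLUP

    y = mu + Z g + Z_h h + e,   g ~ N(0, var_g G),  h ~ N(0, var_H H)

where `Z` sums the two parental incidences. Because the half-diallel has
one parent pool and unordered crosses, the two-pool Kronecker covariance is
symmetrized: `H[(i,j),(k,l)] = (G_ik G_jl + G_il G_jk)/2`, which is PSD
whenever `G` is and reduces to the plain product when parent roles are
distinct. Correlated effects are reduced to iid form through eigen square
roots (`K = LL'`, spectrum clipped at zero below `1e-10` of the largest
eigenvalue).

Variance components for this model are estimated by direct REML: the
likelihood is profiled over the variance ratios `gamma_k = var_k/var_e` and
maximised by L-BFGS-B on `log gamma` (with a Nelder-Mead polish if the line
search terminates abnormally). EM-REML was deliberately not used here: with
one record per hybrid the saturated SCA term and the residual are separated
only by H's off-diagonal structure, the likelihood has a long flat ridge,
and EM's steps shrink geometrically near the boundary (a component pinned at
zero still moves after thousands of iterations). The direct optimiser
converges in tens of evaluations. Effect BLUPs are then solved from the
mixed-model equations at the estimates. A consequence of the same weak
identifiability is that only the combination `var_e + var_H * mean(diag H)`
is well determined, not the split; REML tends to put boundary mass at
`var_H = 0` while the Gibbs sampler's prior keeps it interior, and the two
agree on `var_g` and on the identified combination.

The Gibbs sampler (`method="gibbs"`) uses scaled-inverse-chi-square priors
with 5 df and scales splitting the phenotypic variance equally across the
three terms, a flat prior on the mean, and a joint Gaussian update of all
location effects; defaults are 10,000 iterations, 1,000 burn-in, thinning 5,
and a mandatory seed. Posterior means are reported.

Two validation schemes:

- **Leave-one-hybrid-out GCA prediction** — for each cross, GCA effects are
  re-estimated by sum-to-zero constrained least squares from the remaining
  crosses and the held-out hybrid is predicted as the refit mean plus
  `g_i + g_j`; the reported statistic is Pearson r between predictions and
  observations. Under a pure-noise null this r is *negatively* biased (the
  refit mean excludes the focal observation), which the permutation-null
  test accounts for.
- **k-fold marker CV** — hybrids are shuffled with an explicit seed into k
  folds differing in size by at most one; each fold's phenotypes are masked
  and predicted from the model fitted on the rest (relationships, but not
  phenotypes, of the test hybrids are used). Out-of-fold predictions are
  pooled for the reported r; per-fold r values are kept alongside. With
  `k = n` the scheme degenerates to leave-one-hybrid-out. Pooled
  out-of-fold correlation is the headline number because within-sample fit
  of a saturated hybrid model is close to 1 by construction and says little
  about new hybrids; the model object also exposes `fitted` for the
  within-sample variant.

### Reporting

Trait correlations are pairwise-complete Pearson r on across-environment
BLUPs, with exact t-based critical values at each pair's n (at n = 160 these
are 0.155 and 0.203 at the 5% and 1% levels). Rankings sort on a focal
trait respecting its direction (yield descending, damage scores ascending),
break ties by entry label for byte-identical reruns, and summarize the top-k
hybrids against all hybrids and the checks; the percent advantage is
`100 (best_hybrid / best_check - 1)`, displayed rounded to integers.

## Synthetic-data generator

The generator is the test bed for every stage. Plot values follow

    Y = mu + E_k + rep + block + g_i + g_j + s_ij + (gE)_ik + (gE)_jk
        + (sE)_ijk + e

with each term drawn at a user-set variance from its own named random
stream, so changing one variance never perturbs the other draws and a seed
fully determines the output. GCA draws are centred; SCA draws are projected
onto the Method 4 constraint space (so `var_sca = 0` gives exactly zero
SCA). In marker mode, GCA is a linear combination of centred dosages with
effects rescaled so the realized GCA variance matches the target, making
GBLUP recovery well-posed. Parental SNP panels are simulated at
Hardy-Weinberg genotype frequencies with uniform MAF and independent
missingness. Check entries receive an independent genetic value at the
total hybrid genetic variance `2 var_gca + var_sca`.

Default trait settings (`DEFAULT_TRAITS`) emulate a tropical maize trial:
grain yield around 5 t/ha with GCA variance 0.5, SCA 0.25 (Baker's ratio
0.8, additive-leaning), GCAxE/SCAxE 0.1 each and plot error 1.0; days to
anthesis ~62 d; plant height ~180 cm; and ordinal 1-9 foliar/ear damage
scores generated by thresholding the latent Gaussian at fixed
equal-probability nine-category cut points (the published material reports
only 1-9 scales, not score distributions, so equal-probability cuts are the
neutral choice). Replicate variance defaults to 0.05; incomplete-block
variance defaults to 0 (the design is named but no block variance is
reported), which keeps balanced-case oracles exact — set `var_block > 0`
and `n_blocks > 1` to exercise the lattice adjustment.

What the generator does **not** emulate: genetic correlations between
traits (traits are drawn independently, so simulated trait correlations are
near zero and only exercise the correlation machinery, not published trait
relationships); linkage disequilibrium between markers and any genetic map;
spatial field trend beyond replicate/block effects; non-Gaussian error;
selection or non-random missingness of crosses. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those departures.

## Problem sizes used in tests and the acceptance run

Monte-Carlo suites use the design sizes of the emulated study where the
check is about the study's own conditions (p = 15, 3 environments x 2
replicates for Baker-ratio recovery; p = 8, 1,000 replicates for F(SCA)
calibration; 105 hybrids for GBLUP recovery over 100 replicates) and small
designs (p = 5..10) for algebraic oracles where size is irrelevant. The
acceptance script simulates one full 15-parent experiment (3 environments,
2 replicates, 2,000 markers with 5% missingness, 5 checks) and reports the
pipeline's own estimates alongside the analytically recomputable published
quantities.

## Numerical choices and edge cases

- EM-REML variance floors at `1e-10` of the phenotypic variance; components
  landing on the floor are reported as exactly 0.
- A constant response short-circuits all fits to zero variances.
- Kinship PSD checks use an eigenvalue tolerance of `1e-8` relative to the
  largest entry.
- Degenerate inputs raise informative errors rather than proceeding: missing
  cross means point to `max_complete_subset`; an all-missing marker, an
  all-monomorphic panel, fewer than 4 parents for variance components,
  fewer than 5 for leave-one-out, fewer than 10 hybrids for GBLUP.
- Ties in rankings are broken by entry label; fold assignment uses
  `numpy` permutation under the supplied seed; no global random state is
  touched anywhere.

## Known limitations

- The stage-1 across-environment model omits a random block term (blocks
  are per-environment); with the default block variance of 0 this is exact.
- Ordinal 1-9 traits are analysed on their numeric scores (no link
  function), as is standard for these ratings; with very skewed score
  distributions the Gaussian machinery is approximate.
- The SCA/residual variance split in the hybrid GBLUP is weakly identified
  with one record per hybrid (see above); interpret `var_H` jointly with
  `var_e`.
- `percent_advantage` is meaningful for ratio-scale, higher-better traits
  (yield); it is not applied to damage scores.
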