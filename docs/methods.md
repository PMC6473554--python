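# Methods

## Model

Each node r of an n-node system is a univariate dynamic linear regression
on the contemporaneous values of its parent set Pa(r): the design row is
`(1, y_t(p1), ..., y_t(pk))` — an intercept is always included, and a
parentless node regresses on the intercept alone.  Coefficients follow a
Gaussian random walk and the observation precision φ(r) = 1/V(r) is unknown;
with the normal–gamma initial prior the analysis is conjugate and filtering
reduces to closed-form recurrences.  The one-step forecast of y_t(r) is
Student-t with n_{t-1} degrees of freedom, location F_t'm_{t-1} and squared
scale q_t = F_t'(C_{t-1}/δ)F_t + S_{t-1}, where S_t = d_t/n_t is the running
variance estimate.  The state innovation covariance is never specified
directly: a single discount factor δ inflates the prior covariance each
step (R_t = C_{t-1}/δ), the standard device in dynamic-regression practice;
δ = 1 recovers a static-coefficient Bayesian regression, and the smoother
gain is then the constant δ, so retrospective moments follow a two-line
backward recursion (rescaled by S_T/S_t so all variances refer to the final
variance estimate).

The score of a parent set is the log predictive likelihood (LPL): the sum
over t of the one-step forecast log densities, maximised over a discount
grid per (subject, node, parent set).  Two prequential identities anchor the
implementation and are asserted in the tests: at δ = 1 the LPL equals the
closed-form batch conjugate marginal likelihood exactly, and the LPL of a
network is exactly the sum of its n local scores, so log Bayes factors are
LPL differences.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `c0_scale` | 3.0 | prior coefficient variance (×S_0), weakly informative on unit-scale data |
| `n0`, `d0` | 0.001 | precision prior Gamma(n0/2, d0/2); S_0 = 1 |
| `delta_grid` | 0.80–1.00 (6 points) | discounts searched per parent set; score = grid maximum |
| `burn_in` | 0 | forecast terms skipped from the LPL (identical across compared models) |
| `standardize` | on | per-column mean-0 / sd-1 before scoring |
| `max_parents` | n−1 for n ≤ 12, else 4 | parent-set cap; hard node cap 20 for the exact search |
| IS threshold | 1/2 (strict) | fraction of individual networks an edge must exceed |
| `min_cluster_size` | 3 | smallest subgroup the tree cut may emit |
| `split_factor` | 2.0 | deep-split ratio of the adaptive tree cut |
| λ grid | 0.1, 0.7, 10, 100, 1000 | penalty sweep; exp(λ) is the edge-status prior odds |
| Z̄ threshold | 2 | absolute standardized strength flagged significant |

Whether series are standardized before fitting is a genuine modelling
choice that applied reports rarely state; the default is on, because the priors above are calibrated for unit-scale data, and the
toggle is exposed in the config.  The discount grid is shared across parent
sets rather than fixed per node — the score stays purely predictive and no
per-node tuning parameter leaks into model comparison.

## Structure search

Parent sets are bitmasks; per-(subject, node) score tables over all sets up
to `max_parents` are the expensive step and are cached and summed for every
group method.  The acyclic optimum is found by exact dynamic programming:
for each node a subset-lattice sweep yields the best parent set within any
allowed ancestor set, then a sinkless-vertex recursion over the 2^n subsets
assembles the globally optimal DAG — the same optimum an integer-programming
formulation attains, with no external solver.  Ties are broken toward
smaller parent sets, then smaller bitmask, applied identically in the
per-node (DGM) search and through the DP, so identical inputs always return
identical networks.  Tie-breaking matters more here than is usual in
score-based structure learning, for the reason given under *Limitations*.

## Group estimators and clustering

VTS averages the raw series pointwise across subjects and standardizes the
average (the average of already-standardized series would shrink
heterogeneous signals asymmetrically); CS sums score tables entrywise; IS
includes a directed edge iff it appears in strictly more than the threshold
fraction of individual networks.  The pairwise logBF separation
d(i,j) = c_ij(m_I) − c_ij(m_G) uses the same search variant for both terms;
negative values can only arise from floating-point rounding and are clamped
to zero (and logged).  Agglomerative clustering (average linkage by
default, the usual companion of the dynamic tree cut; complete and single
are available) is cut
by a hybrid adaptive rule: branches split where the joining height exceeds
a static 99%-of-range cut *or* where both sub-branches hold at least
`min_cluster_size` subjects and the joining height exceeds `split_factor`
times the heights inside them (the deep-split stage; a single static cut
cannot resolve nested separation scales).  Members of dissolved small
clusters are reassigned to the nearest surviving cluster when close enough
(PAM-like stage) and otherwise become singleton subgroups, mirroring the
treatment of outlying subjects as their own subgroup.  Classical
(Torgerson) MDS — double-centred eigendecomposition — provides the
low-dimensional diagnostic, with variance explained measured on the
positive eigenvalues.

The connectivity-strength formulas are implemented as the standardized mean
Z̄ = θ̄/√(σ̄²/(T·S_g)) and the Welch-type standardized difference
D̄ = (θ̄_g − θ̄_l)/√(σ̄²_g/(T·S_g) + σ̄²_l/(T·S_l)) — the standard readings
of a standardized mean and a two-sample standardized difference; θ̄ and σ̄²
average the
smoothed coefficient mean and variance over time and subgroup members (all
members, not only those whose individual network has the edge).  Edge
prevalence within a subgroup is tested one-sided (greater) against a
binomial null of p0 = 0.5 (the null and its direction are design choices)
with Benjamini–Hochberg correction across all
n(n−1) ordered pairs.

## IEMN / MEMN

IEMN estimates each level independently (individual searches; subgroup and
group searches on summed tables).  MEMN couples levels through
p(M_i(r)|M̄_g(r)) ∝ exp(−λ·SHD): the individual posterior marginalises over
the subgroup centre with a uniform prior over the configured parent-set
space, and the
subgroup/group posteriors multiply the members' penalty-weighted evidence.
All sums of exp(LPL) terms run in log space via log-sum-exp; the penalty
prior is normalised explicitly over the space (closed form
(n−1)·log(1+e^{−λ}) for the full power set, direct summation when
`max_parents` truncates it).  Acyclicity, when requested, is imposed on the
argmax over the penalised per-node tables, not inside the marginal sums.
At λ = 0 the penalty is flat, so the individual posterior argmax is the
likelihood argmax; the implementation feeds the raw score tables to the
search in that case, which keeps exact score ties exact and makes the λ = 0
networks identical to IEMN's (the generic log-sum-exp path perturbs ties at
the 1e−13 level).  λ can be chosen by maximising the summed individual
posteriors, the group posterior, or by leave-one-subject-out
cross-validation (held-out LPL under the predicted group structure, priors
refit); ties go to the smallest λ.  Predicted (leave-one-out) networks
transfer structure only — priors are refit on the held-out subject.

## Synthetic generator

`simulate_group` draws, per subgroup, one true DAG and one set of true
coefficients shared by its subjects; within each time point values are
generated in topological order, so the contemporaneous structural equations
are well defined.  Subject seeds derive from the master seed and the pair
(subgroup key, member index) — reordering subgroups never changes a
subject's data, and output is bitwise reproducible.  The presets emulate a
three-subgroup resting-state study: `full_scale_spec` (3 × 10 subjects,
n = 12, T = 1158) and `desk_scale_spec` (3 × 6, n = 8, T = 400).  Preset
DAGs are mutations of a shared base DAG (common topological order, mean
in-degree 2, in-degree capped at 3, pairwise SHD ≥ 4): real subgroup
networks share most of their edges while remaining structurally distinct,
and an edge-disjoint design would make the ">2/3 popular edges" reference
graph empty.  Preset coefficients have magnitude uniform in [0.4, 0.8] with
random sign and follow a slow random walk (innovation sd 0.02 per step);
`CoefficientProcess("constant")` is available and is the default for the
low-level `simulate_subject`.

What the generator does *not* emulate: hemodynamic convolution, physiological
and scanner noise, temporal autocorrelation of the BOLD signal, spatially
correlated region definitions, or between-subject variation in connection
strength within a subgroup.  Passing tests therefore demonstrate correct
recovery under the model's own assumptions (linear contemporaneous effects,
Gaussian noise, known region set), not robustness to fMRI preprocessing
artefacts.

## Numerical choices

* The per-node filter loop is JIT-compiled (numba) with an equivalent pure
  Python fallback; a test asserts both produce identical output.
* Non-finite inputs and non-positive forecast variances raise immediately;
  constant columns fail standardization with the region named.
* Smoothed variances are floored at the smallest positive float.
* Separations are clamped at −1e−9; larger negatives raise.
* Scores must be finite to enter a table; posterior tables are normalised
  per node before λ-selection so criteria are comparable across λ.

## Limitations

* **Score equivalence under constant coefficients.**  On standardized data
  with δ = 1 the local score depends on the data only through symmetric
  second-moment statistics, so Markov-equivalent structures (e.g. a single
  edge and its reversal) receive *exactly* equal scores and orientation
  inside an equivalence class is decided by the tie-break rule, not the
  data.  Directional recovery of contemporaneous networks therefore
  requires genuinely time-varying connection strengths (which the discount
  grid then detects); this is why the study presets default to the
  random-walk coefficient process.
* **λ and group-network density.**  As λ → ∞ the MEMN group posterior
  tends to the summed-score (CS) argmax, which on sharp synthetic data is a
  relatively dense consensus; the group level therefore tends to densify
  (or stay flat) along the λ sweep in this implementation, while individual
  networks densify toward the consensus.  A monotone *decrease* of group
  density in λ is not a property of the posterior as defined here.
* The exact DAG search is feasible to n ≈ 20 but the order DP is pure
  Python; practical study sizes are n ≤ 12–14 with `max_parents ≤ 4`.
* The DGM variant reports, but does not model, directed cycles; cyclic
  semantics beyond the per-node regressions are out of scope, as are
  lagged (Granger-style) effects and non-Gaussian observation models.
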