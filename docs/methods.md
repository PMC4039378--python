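# Methods

## Model

### Enzyme concentrations from transcripts

At balanced exponential growth, with per-transcript translation rates
unaffected by the environmental shift and protein loss dominated by
dilution through cell division, the steady-state enzyme level of gene *i*
in condition *j* is

    E_ij = α · m_ij · T(μ_j) / μ_j

where `m_ij` is the transcript signal as a fraction of total mRNA, `T(μ)`
the total mRNA per unit biomass, `μ_j` the growth rate, and `α` an
arbitrary constant. `T(μ) = a + b·μ` is affine; the defaults `a = 0.4,
b = 0.8 h` are normalized so T(0.75 h⁻¹) = 1 and are placeholders in the
sense that only the a/b ratio matters after the centered-log transform —
any analysis reported from this package should state the coefficients
used, and they are user-overridable everywhere (`TotalMrnaModel`). mRNA
degradation is deliberately ignored (dilution-only balance). Error
propagation is first-order: the relative SD of the signal is preserved in
the enzyme level; growth-rate SD can be folded in quadrature behind a flag
(off by default, since transcript error dominates in practice).

### Regulation coefficients

Virtually any enzyme kinetics factorizes as J = E · f(M), with the
metabolic state M entering only through f. On centered log₂ data across
conditions, the share of the log flux change carried by the enzyme is the
slope ρ_h of log₂E against log₂J, with ρ_m = 1 − ρ_h the metabolic share.
The fit orientation (enzyme on y, flux on x) is chosen so that ρ_h < 1
reads "enzyme changed less than flux". Centering both axes removes α, the
units constant β, and forces the fit through the origin.

At a two-arm branch point the same machinery is applied to
x = log₂(J_a/J_b), y = log₂(E_a/E_b), giving ρ_hr; ratio SDs combine in
quadrature on the log scale (our choice; nothing forces another). For arms
catalysed by two isozymes of unknown relative activity, an optional scan
refits over enzyme combinations (1−w)·E₁ + w·E₂, w ∈ {0, 0.05, …, 1},
reporting the best-R² weight. Multi-gene arms otherwise use the summed
level.

The substrate's explicit contribution uses the power law ΔJ = ΔE·ΔS^λ
(the S-system form). λ is the through-origin least-squares slope of
log J − log E on log S; the combined predictor log E + λ·log S is then
regressed on log J to give ρ_es, and δ = ρ_es − ρ_h (computed on identical
conditions) is the substrate's added explanatory value.

### Branch-point kinetics

The mechanistic simulator solves, for one substrate pool fed at fixed
J_in and drained by two irreversible Michaelis–Menten enzymes, the unique
steady state Σᵢ Vmaxᵢ·S/(Kᵢ+S) = J_in (feasible iff J_in < ΣVmax). The
root is bracketed by S_max = max(K₁,K₂)·Vtot/(Vtot−J_in) — a guaranteed
enclosure since v(S) ≥ Vtot·S/(maxK+S) — and solved with
`scipy.optimize.brentq` at near machine precision; the defining-equation
residual is the contract (< 1e−8·J_in in tests). The sensitivity scan
perturbs E₁/E₂ by a fold (default 2, split symmetrically), re-solves S at
fixed J_in, and reports Δlog(J₁/J₂)/Δlog(E₁/E₂).

A point worth making explicit: at fixed J_in the steady-state fractional
saturation is set by the **load** J_in/Vmax_tot, not by K_m alone (raising
both K_m simply raises S proportionally). "Unsaturated regime" therefore
means low load; the validation grid pins J_in/Vmax_tot = 1e−8 and varies
K_m and Vmax asymmetries, where the one-for-one law holds to ~1e−8. The
breakdown regime (one arm with 10⁴-fold lower affinity compensated by
10⁴-fold higher Vmax) deviates from slope 1 by >0.1 once the load on the
weak arm is appreciable (J_in = 2·Vmax₂ in the validation point).

## Estimation and inference

- **Weighted Theil-Sen.** The slope is the weighted median of all pairwise
  slopes (y_j−y_i)/(x_j−x_i) with weights (x_j−x_i)²; pairs with equal x
  are excluded. The weighted median is the *lower* median: the smallest
  value whose cumulative weight reaches half the total (deterministic tie
  rule). The vectorized implementation is checked exactly against a
  brute-force loop reference on random instances.
- **Resampling.** N = 2000 draws (configurable). Each draw samples a
  condition subset without replacement of size max(min_subset,
  round(f·n)) with f = 0.8, min_subset = 4 (the subset size is our
  choice; it keeps ≥4 of 8 points while perturbing composition), then
  perturbs every retained log₂ value with Gaussian noise of SD =
  relative measurement SD / ln 2 (first-order delta method; log-space
  injection is our choice). Reported ρ is the distribution median, the CI
  its 2.5/97.5 percentiles, and the P-value for ρ > 1 the fraction of
  draws with slope ≥ 1. Degenerate draws (no informative pair) are
  redrawn, capped at 10·N attempts. Everything is deterministic given the
  seed; pipeline runs derive per-task seeds from the base seed and the
  stable task order.
- **Goodness of fit.** Through-origin R² = 1 − Σr²/Σy² on the unperturbed
  centered data at the reported slope (may be negative; undefined and
  reported missing when y has no variation), plus the mean |residual| in
  log₂ units.
- **Classification.** `full_hierarchical`: mean |residual| < 0.4 log₂
  units and 1 inside the 95% CI. `partial`: good fit, CI strictly below
  1, ρ > 0. `metabolic`: |ρ| < 0.2. `outlier_driven`: otherwise-incoherent
  fit whose point estimate moves by > 0.3 on dropping one condition.
  `incoherent`: the rest. The CI-based criterion governs the
  transcriptional call; the one-sided P-value is reported alongside.
- **λ in resampling.** λ is refit inside every draw by default so its
  uncertainty propagates into the ρ_es interval (fixed-λ mode behind a
  flag). When the substrate series is exactly constant, λ is
  unidentifiable (Σ log²S = 0); the fit falls back to the plain ρ_h fit
  with λ = 0, consuming the identical RNG stream — so ρ_es ≡ ρ_h bit-for-
  bit in that limit, which the tests assert.

## Pairing and filtering

Reactions enter the ρ_h analysis when |flux| exceeds 0.1 mmol gcdw⁻¹ h⁻¹
in at least 3 conditions; within a kept reaction only above-cutoff
conditions are used. Reversible reactions whose flux changes sign are
split into per-direction tasks (each re-checked against the minimum);
fits use flux magnitudes, direction is metadata. A condition lacking a
positive enzyme measurement drops from the task, not the task from the
analysis. Branch series additionally require both arms above cutoff in at
least 5 joint conditions, with a config exclusion list for splits with
unreliable flux estimates. Conditions below cutoff but non-zero are
excluded from tasks (our resolution of an underdetermined corner).

## Synthetic data generator

The generator emulates the study conditions the analysis is designed for:
8 conditions with growth rates 0.22–0.75 h⁻¹; per-reaction centered log₂
flux profiles with SD 1.5 log₂ units (up to ~20-fold condition-to-
condition variation); enzyme profiles log₂E = ρ·log₂J, so the metabolic
term is exactly (1−ρ)·log₂J and the decomposition holds without extra
residual (an optional `residual_log2_sd` adds incoherent scatter);
substrate profiles log₂S = (log₂J − log₂E)/λ; transcripts by inverting
the dilution model; on/off genes with configurable induction folds
(defaults 10 and 100) and zero off-condition flux; branch series computed
by the mechanistic kinetic model. Multiplicative lognormal measurement
noise (factor exp(cv·z)) at relative SDs of 10% (flux), 15% (transcript)
and 10% (metabolite) by default; SD columns carry value·cv. All
randomness flows from one seed through fixed per-table, per-reaction
substreams, so datasets are byte-reproducible and adding a table does not
shift existing streams. The generator shares no slope-estimation code
with the fitters.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: correlated measurement errors between
tables, flux non-identifiability structure from the stoichiometric
network (collinearity is annotation here), condition-specific metabolic
states that violate the constant-ρ assumption, transcript compositional
effects, and biological replicate structure beyond the stated SDs.

## Validation studies and problem sizes

The bundled studies (also run by `scripts/acceptance.py`) use: 10,000
random instances (n ≤ 8) for estimator agreement; 200 replicate datasets
per true ρ_h ∈ {0, 0.3, 0.7, 1.0} at 5% CV and N = 2000 for recovery
(observed |bias| < 0.01 and coverage ≥ 98% — comfortably inside the ±0.1
and ≥85% targets); a 27-point unsaturated grid plus one breakdown point
for the branch law; and single 8-condition series for the ρ_es limits.
These sizes give stable summary statistics in seconds on one CPU.

## Known limitations

- ρ_m is only ever inferred as 1 − ρ_h; f(M) itself is not modelled.
- The constant-ρ assumption across conditions is a modelling choice; the
  outlier flag detects single deviating conditions, not drifts.
- No multiple-testing correction across reactions is applied (by design;
  the per-reaction coefficients are the object of interest).
- The branch model is irreversible, non-cooperative and ignores product
  inhibition; branch points with more than two arms are out of scope.
- Total-mRNA coefficients must come from organism-specific data for
  absolute interpretation of growth-scaling slopes at the protein level;
  with the default model only the qualitative mRNA-vs-protein contrast is
  meaningful.
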