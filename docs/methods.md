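# Methods

`sdnmap` implements a longitudinal synchronized-degeneration-network (SDN)
analysis: from serial volumetric change maps to annual atrophy-rate maps,
mass-univariate group statistics with cluster-extent familywise-error
control, epicenter seeds, seed-based SDN maps in controls, spatial
similarity with smoothness-matched permutation nulls, goodness-of-fit
network preference, and partial rank correlation with cognitive decline.
This note records the model, the numerical choices, and what the synthetic
cohort does and does not establish.

## Rate maps

Each subject contributes 2–3 serial maps on a Jacobian-determinant-like
scale (1 = no change) in a common space. The per-voxel annual change rate
is the OLS slope of map value on acquisition time (finite difference for
two time points). Rate maps are then smoothed with an isotropic Gaussian
kernel, default 8 mm FWHM, using zero padding and no mask renormalization;
masks enter only at the statistics stage. The analysis mask keeps voxels
whose mean tissue probability across subjects strictly exceeds 0.2 (the
direction at exact equality is a convention; it is documented and
configurable).

## Voxel-wise statistics

All group models are plain OLS fitted per voxel (`MassUnivariateGLM`):

* four-level ANCOVA (HC/MCIs/MCIp/AD) with age, sex, education years and
  total intracranial volume as nuisance covariates. Groups use cell-means
  coding (one indicator per group, no global intercept) so contrasts such
  as `MCIs-MCIp` are direct group-mean differences. Covariates are
  mean-centered; contrast t-maps are invariant to affine rescaling of
  covariates.
* one-sample t-tests per group of the mean rate against zero, evaluated at
  the covariate means (the intercept of a regression on centered
  covariates).
* t→z conversion via the exact CDF composition `z = Φ⁻¹(F_t(t; df))`,
  computed with survival functions for far-tail precision. Voxels with
  (numerically) zero residual variance carry a placeholder statistic and
  are clamped to |z| = 38 with a log warning; "numerically zero" means
  residual variance below 1e-24 times the mean squared signal, the scale
  of float64 roundoff after a perfect fit.

## Cluster-extent inference

Residual smoothness is estimated per axis with the classical
first-difference Gaussian-field estimator,
`FWHM = d·sqrt(−2 ln 2 / ln(1 − varΔ/(2 var)))`, averaged over subjects'
residual maps, combined as a geometric mean. The formula equals the true
FWHM for Gaussian autocorrelation; on a discrete lattice it cannot resolve
smoothness below one voxel, so estimates are floored at the voxel size
(the log argument 0.25 is exactly the 1-voxel point, making the floor
continuous).

The critical cluster extent is Monte-Carlo: Gaussian fields at the
estimated smoothness on the mask grid, standardized within the mask,
thresholded two-sided at the voxel p (default 0.005), largest cluster
recorded under 18-connectivity (6/26 available); the minimum extent is the
smallest k with P(max cluster ≥ k) ≤ α (default 0.05). Simulated noise is
Gaussian because thresholds are applied to z-converted maps. Calibration
(fraction of pure-noise datasets with any surviving cluster in
[0.02, 0.10] at nominal 0.05) is asserted in the acceptance suite.

## Epicenters, SDNs, network masks

Epicenters are the peak-|statistic| voxels of surviving clusters in the
progression contrast (faster atrophy in MCI progressors than in stable
MCI; one-sided, since the hypothesis is directional). Ties resolve to the
smallest flat scan-order index. A 6-mm closed-ball sphere around the peak
(center-to-center voxel distances) defines the seed; on a 2-mm grid a
6-mm sphere holds 123 voxels.

The SDN is mapped in controls only: each control's mean rate inside the
seed is the regressor of interest in a voxel-wise GLM with the same
nuisance covariates; the seed-coupling t is z-converted. Binarized network
masks use the same cluster-FWE criterion, positive coupling only
(synchronized degeneration is positive covariance; a two-sided flag
exists). Fixed-size alternatives rank in-mask voxels by z and keep the top
1–10% (ceil of the voxel count; ties at the cut break by scan order, which
makes the ladder of masks nested).

## Similarity, GOF, cognition

Spatial similarity is the Pearson correlation of unthresholded in-mask
voxel values. Its null replaces the SDN side with Gaussian fields smoothed
to the SDN map's estimated residual smoothness and standardized within the
mask; p is two-sided on |r| with the add-one rule (never exactly zero).
GOF of a network mask against a target z-map is mean z inside minus mean z
outside (within the mask); group one-sample z-maps are sign-flipped so
atrophy is positive before GOF and similarity.

Cognitive decline: per-subject, per-test OLS slopes of score on time;
association with the per-subject mean SDN rate by partial Spearman
correlation — rank-transform all variables, residualize ranked x and y on
ranked covariates by OLS, Pearson on residuals, p from the t approximation
with df = n − 2 − k. (The other common construction — Pearson partial of
ranks via the recursion formula — is equivalent here.) Six domain tests
form the Bonferroni family (threshold 0.05/6 ≈ 0.008); the MMSE is treated
as a separate global test at uncorrected 0.05.

## Synthetic cohort: the stated world

The generator emulates registered longitudinal data directly (no
acquisition, registration or segmentation). Per subject i and network k:

    f_{k,i} ~ Normal(μ_{k,g(i)}, σ_f²),   σ_f = 0.004/yr
    r_{v,i} = β₀ + Σ_k λ_{k,v} f_{k,i} + Σ_c γ_c (cov_{c,i} − ref_c)
    map_t   = 1 + r_v·t + ε_t,            ε: Gaussian, sd 0.0075, FWHM 4 mm

Trajectories are linear so true slopes are exact. Loadings are Gaussian
profiles (σ = 2.5 voxels) truncated at radius 5 voxels; the truncated
support is the declared true network. The default preset (32³ grid at
2 mm, brain = 13.5-voxel ball, group sizes 33/25/12/23, 2 time points for
17/93 of subjects, annual spacing) plants:

* a **progressive** network at (11,16,16): latent means −0.002 / −0.006 /
  −0.026 / −0.032 per year for HC/MCIs/MCIp/AD — the sharp
  progressor/stable gap is the phenomenon the method targets, and peak
  network rates of ~3%/yr sit at the upper end of rates reported for
  medial temporal structures in converters;
* a **stable decoy** at (22,16,16): −0.010/yr in every group, no cognitive
  coupling.

Cognitive slopes are `a + b·(mean true rate over the progressive network)
+ noise`; baseline scores follow per-group means/sds typical of such
cohorts. For coupled tests the slope-noise sd is calibrated so that the
*measured* partial Spearman correlation at n = 93 is ≈0.4 (the magnitude
the analysis is meant to reproduce). The calibration is Monte-Carlo:
replicate cohorts with the stated group counts and group-structured
covariates, partial-Spearman measured exactly as in the analysis, noise
solved by bisection with a fixed internal seed. A closed-form
bivariate-normal conversion is wrong here for two reasons discovered
during design: the network rate is a four-component normal mixture, and
education/age differ by group, so rank-partialling them removes genuine
signal (~0.05 of correlation at this n).

Three preset choices came from identifiability analysis rather than taste:
(i) epicenters keep ≥4 voxels of clearance from the brain edge, because
zero-padded smoothing otherwise attenuates the near-edge flank of the
signal and deterministically displaces the contrast peak inward by 2–3
voxels; (ii) the loading σ is 2.5 voxels because with a single latent
factor the contrast t equals λΔμ/√(λ²σ_f²+σ_n²), which plateaus over the
network interior when map noise is small — a sharper profile keeps the
peak curved and the epicenter identifiable; (iii) map noise 0.0075 trades
off SDN recovery (smaller noise recovers weaker loadings) against that
same plateau effect.

What a green recovery test establishes: the pipeline finds the planted
epicenter to ~1 voxel, recovers the network with Dice ~0.7, orders GOF
with planted severity, and detects the planted cognitive association at
the tuned effect size — under linear trajectories, Gaussian smooth noise,
a single latent factor per network, and no registration error,
inter-scanner drift, temporal autocorrelation or partial-volume effects.
Real data violate all of these to some degree; the tests validate the
estimator chain, not the biology.

## Known limitations

* Smoothness estimation assumes Gaussian autocorrelation; heavy-tailed or
  anisotropic-beyond-axes structure biases the Monte-Carlo extent.
* The generator's noise is white across time points (the slope model's
  assumption); serial correlation in real data inflates rate variance.
* One-sample z-maps depend on group df, so GOF comparisons across groups
  of very different size partly reflect sample size — visible in the
  synthetic world as compression of the n=12 group's z values.
* Cluster-FWE control is exact only for the simulated smoothness; it is
  re-estimated from residuals per analysis, not propagated with
  uncertainty.
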