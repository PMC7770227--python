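# sdnmap

Longitudinal synchronized-degeneration-network (SDN) mapping from serial
volumetric change maps.

Neurodegenerative atrophy does not spread uniformly: network-degeneration
accounts hold that disease starts in vulnerable *epicenters* and
progresses along the large-scale structural networks they anchor. Given
serial MRI-derived volume-change maps (Jacobian-determinant-like, already
registered to a common space) for a cohort of healthy controls, stable and
progressing MCI patients, and dementia patients, `sdnmap` provides the
full analysis chain to test that account longitudinally:

1. **Rate maps** — per-voxel annual change rate \(\hat\beta_v\) by OLS of
   map value on scan time, smoothed (8 mm FWHM), masked at mean tissue
   probability > 0.2.
2. **Group statistics** — voxel-wise four-level ANCOVA (nuisance: age,
   sex, education, TIV) and per-group one-sample t-tests; exact t→z.
3. **Cluster-FWE inference** — residual smoothness by the first-difference
   estimator, Monte-Carlo critical cluster extent at voxel p < 0.005,
   cluster α < 0.05.
4. **Epicenters and SDNs** — 6-mm sphere seeds at surviving-cluster peaks
   of the progression contrast; per-voxel coupling of each control's seed
   rate with every voxel's rate (GLM) defines the SDN z-map; binarized at
   the same cluster-FWE criterion or as fixed-size top-percent masks.
5. **Similarity and network preference** — Pearson spatial correlation of
   unthresholded maps against a null of noise maps matched to the SDN's
   smoothness (permutation p, add-one rule); goodness of fit
   GOF = mean z inside − mean z outside the network.
6. **Clinical association** — partial Spearman correlation (ranks
   residualized on ranked covariates) between mean SDN atrophy rate and
   per-subject cognitive slopes, Bonferroni over six domain tests
   (p < 0.05/6 ≈ 0.008), MMSE as a separate global test.

Because real serial MRI of this kind is rarely shareable, the package
includes a first-class synthetic cohort generator (`sdnmap.synthetic`)
with planted epicenters, network loadings, group-graded atrophy rates and
cognitive coupling, so every stage has a recoverable ground truth. See
`docs/methods.md` for the generative model and its calibration.

## Worked example

Run the whole pipeline on the default synthetic cohort (93 subjects,
groups 33/25/12/23, 32³ grid at 2 mm):

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (abridged):

```
subjects: 93, mask voxels: 11992
residual smoothness (mm): [8.95, 8.87, 8.88]
cluster extent threshold: 65 voxels
epicenters (voxel indices): [[11, 16, 17]]
  sdn group  r_observed   p_perm
sdn00  MCIs    0.185970 0.058941
sdn00  MCIp    0.328711 0.000999
sdn00    AD    0.368794 0.000999
  sdn group      gof
sdn00  MCIs 2.029143
sdn00  MCIp 2.482773
sdn00    AD 4.181317
cognition, sdn00:
 test_name       rho        p  alpha_threshold  significant
      MMSE  0.224189 0.034682         0.050000         True
     CVVLT  0.360013 0.000530         0.008333         True
CFT_recall  0.378414 0.000256         0.008333         True
       VFT  0.326014 0.001822         0.008333         True
     TMT_B  0.101691 0.343000         0.008333        False
```

Reading this: the progression contrast finds one surviving cluster whose
peak (11,16,17) lies one voxel from the planted epicenter (11,16,16). The
SDN seeded there correlates spatially with each patient group's
degeneration map, more strongly (and with smaller permutation p) in the
more advanced groups, and its GOF rises monotonically MCIs → MCIp → AD —
the network "prefers" the advanced-stage atrophy pattern. Its mean atrophy
rate predicts decline in the coupled cognitive tests (rank correlations
≈0.33–0.38, significant after Bonferroni) but not in the uncoupled ones
(TMT-B, CFT copy), and the MMSE clears only its uncorrected threshold —
the planted structure, recovered end to end.

The same stages are available as a CLI for real data
(`sdnmap simulate|rates|glm|cluster-sim|sdn|compare|cognition|run-all`;
NIfTI maps, TSV tables, JSON reports) and as a library
(`sdnmap.run_pipeline`, or the per-module functions shown in the tests).

## What `scripts/acceptance.py` does

It executes the complete pipeline — simulate the default cohort with the
given seed, fit rate maps, run the ANCOVA and cluster simulation, map the
SDN, compute permutation similarity, GOF and the cognition table — prints
the summary above, and writes its (empty) results object to `--out`. The
quantitative acceptance checks (oracle equivalence, error-rate
calibration, smoothness recovery, planted-structure recovery, association
power, determinism) live in `tests/test_acceptance.py`.
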