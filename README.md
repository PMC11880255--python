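# robot-erp

EEG analysis of implicit robot-performance evaluation: when an observer
watches a robot perform an action and silently judges it as optimal or
suboptimal, the judgment leaves spatiotemporal traces in the evoked EEG.
This package implements the full analysis chain for such studies — of
interest to passive brain–computer-interface (BCI) researchers who want
brain-derived labels for robot-learning systems — together with a
synthetic-study generator that reproduces the trial design and the three
condition-discriminative signatures, so the whole pipeline is testable
without access to restricted recordings.

The chain:

1. **Preprocessing** — detrend, zero-phase 4th-order Butterworth bandpass
   0.2–10 Hz, epoching −0.2…2.0 s around video onset, downsampling to
   250 Hz, per-epoch bad-channel spline interpolation, baseline
   correction, condition-count equalization.
2. **Current source density (CSD)** — reference-free spherical-spline
   surface Laplacian (Perrin construction, m = 4, 50 Legendre terms,
   λ = 10⁻⁵): `CSD(x) = −∇²_S v̂(x)`, positive = current source.
3. **Cluster-mass permutation statistics** — per-sample one-sample t of
   the subject-wise contrast (suboptimal − optimal), spatiotemporal
   clustering of same-sign supra-threshold samples, family-wise control
   by the sign-flip permutation distribution of the maximum |Σt|, with an
   exhaustive 2ⁿ enumeration oracle for small cohorts.
4. **Temporal decoding** — sliding per-timepoint LDA with analytic
   Ledoit-Wolf shrinkage, `w = Σ̂⁻¹(μ₁ − μ₀)`, repeated stratified 5×20
   cross-validation, ROC-AUC, 5,000-fold bootstrap CIs against a dummy
   baseline, Haufe activation patterns `a ∝ Σₓw` with contrast-CI masking.
5. **Single-trial interval decoding** — per analysis window, xDAWN
   spatial filtering, super-trial SPD covariances, tangent-space
   projection at the affine-invariant geometric mean, plain LDA; AUC per
   interval with bootstrap CIs.

`docs/methods.md` describes the models, defaults and limitations in
detail.

## Worked example

Run a reduced synthetic study from a YAML config and summarize it:

```sh
cat > study.yaml <<'YAML'
seed: 7
study: {n_subjects: 3, n_blocks: 3, trials_per_block_optimal: 26,
        trials_per_block_suboptimal: 14}
cluster: {n_permutations: 200}
temporal: {n_repeats: 2, n_boot: 300}
single_trial: {n_repeats: 2, n_boot: 300}
YAML
robot-erp run --config study.yaml --out-dir results/
robot-erp report results/
```

The run takes about half a minute; the report's temporal-decoding section
prints:

```
## Temporal decoding

Peak AUC 0.722 at 1580 ms; dummy upper CI 0.512; 42/220 timepoints significant.
```

Reading: even at this deliberately tiny scale (3 subjects, 120 trials
each) per-timepoint decoding of the observer's judgment peaks late in the
video — around 1.6 s — which is the late-evaluation effect the analysis is
built to expose. The interval table below it hovers near chance at this
trial count: the single-trial Riemannian decoder needs the study-scale
trial budget (1,000 trials/subject), at which the late window reaches the
0.6–0.75 AUC regime (the acceptance checks run that configuration).
`results/` also contains the cluster report (`clusters.json`,
sign/mass/p per spatiotemporal cluster), the group decoding curve
(`decoding_curve.json`), masked activation patterns (`patterns.h5`),
per-subject CSD epochs (HDF5), a rejection log and a manifest that makes
the run bit-reproducible.

The same stages are available as library functions
(`robot_erp.preprocessing`, `robot_erp.csd_transform`,
`robot_erp.cluster_stats`, `robot_erp.temporal_decoding`,
`robot_erp.riemann_single_trial`) and as further subcommands
(`robot-erp simulate`, `robot-erp montage`).

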