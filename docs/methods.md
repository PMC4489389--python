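# Methods

This note records the models, conventions and numerical choices behind
`restconn`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the known limitations.

## Synthetic cohort model

The generator (`restconn.synthetic`) emulates a two-group resting-state
study in signal space. Its defaults are the study conditions the package
is validated under:

| parameter | default | meaning |
|---|---|---|
| n_patients / n_controls | 23 / 20 | group sizes |
| n_regions / n_timepoints | 90 / 230 | parcellation size; retained volumes |
| tr_seconds | 2.0 | sampling interval (s) |
| n_modules | 6 | covariance blocks (contiguous; last absorbs remainder) |
| within_r_control / within_r_patient | 0.6 / 0.3 | target within-module correlation |
| between_r | 0.05 | baseline between-module correlation |
| coupling_sd | 0.08 | SD of the per-subject latent coupling |
| noise_sd | 0.2 | additive white-noise scale (unit-variance signal) |
| cognition_slope / cognition_sd | 57 / 5 | cognitive-score coupling and noise |

Per subject, a latent coupling c is drawn from
Normal(group target, coupling_sd) truncated to (between_r, 0.95); this
gives a continuous trait for correlation analyses rather than two point
masses. The block-constant correlation matrix at coupling c is projected
to the nearest positive-definite correlation matrix (eigenvalue clipping
at 1e-6, diagonal renormalised) because block-constant targets can become
indefinite after per-subject jitter. Gaussian series sampled from that
matrix get white noise added (attenuating realised correlations by
≈ 1/(1+noise_sd²) ≈ 0.96) and then pass through the *same* band-pass
filter as real data, so synthetic and ingested data share one
preprocessing path.

Cognitive scores are affine in the latent coupling:
`camcog_total = 59 + 57·c + N(0, 5)` and
`praxis = 4.1 + 0.2·57·c + N(0, 0.25·5)`. The anchors place the scores on
the scale of a CAMCOG-like battery (≈ 93 for controls at c = 0.6, ≈ 76
for patients at c = 0.3) and make cognition exactly affine in coupling
when `cognition_sd = 0`. Motion summaries are log-normal
(median 0.8, σ = 0.8 in log space, for translation in mm and rotation in
degrees), putting roughly 5 % of subjects beyond each 3.0 exclusion bound
so the QC path is exercised.

What the generator does **not** emulate: voxel space and spatial
preprocessing, haemodynamic response, physiological noise structure,
lesion/white-matter pathology, spatially realistic module layout, or
anti-correlated networks. Passing tests therefore demonstrate that the
pipeline recovers known ground truth from signals with modular
covariance — not that it would be unbiased on real BOLD data.

### Direction of the induced group effect

Reducing within-module coupling at fixed edge count reproduces the
canonical patient pattern for segregation metrics — lower Cp and E_loc,
longer Lp — but *raises* patient global efficiency: a less modular
correlation matrix thresholded to the same density yields a more
integrated graph. Disease cohorts in the literature typically show lower
patient E_glob as well, presumably because overall connectivity loss
accompanies the modular weakening; a "uniform attenuation" effect is not
part of this generator's design. Analyses of E_glob direction on synthetic
cohorts should keep this in mind.

## Preprocessing

Only the final, signal-space stages are implemented: discarding initial
volumes (default 10, for T1 equilibration), motion-based exclusion, and
temporal band-pass filtering. Image-space steps (slice timing,
realignment, normalisation, smoothing) are out of scope; the entry format
is extracted ROI time series.

- **Filter realisation.** The band (0.01–0.08 Hz) is standard; the filter
  family is not dictated by convention alone, so we chose an order-4
  Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero phase:
  any phase lag would shift cross-correlations, which are the quantity of
  interest. Edge transients matter on 230-point series, so reflective
  (even) padding of three settling lengths is used, and series shorter
  than that are rejected. Input and output are demeaned; a constant
  series maps to zero.
- **Idempotency.** Forward–backward filtering squares the magnitude
  response, so the −3 dB band edges lose another factor of two on a second
  pass. Within the passband interior (1.5·f_low to 0.9·f_high) a second
  pass changes RMS by under 5 %; over the full nominal band, including the
  edges, the change is ≈ 5.3 % for band-limited noise. This is inherent to
  any finite-order realisation, not a defect of this one.
- **Motion QC** uses strict inequalities ("exceeding 3.0 mm or 3°"): a
  subject exactly at a bound is kept.

## Network construction

Edges are the K = round(S·N(N−1)/2) largest **positive** correlations.
Negative correlations are never edges by default: binary
sparsity-thresholded resting-state analyses overwhelmingly follow this
convention, and the alternative (rank by |r|) is available as
`edge_sign="absolute"`. Rounding of K is half-away-from-zero; floor or
ceiling would change K by one and with it every realised sparsity.
Thresholding is rank-based, so a Fisher z-transform before thresholding
would be a no-op and is not applied. Ties at the K-th strongest value are
broken by ascending lexicographic (i, j) order, making edge sets
bit-reproducible. Families over the grid are built as prefixes of one
ranking and are therefore nested in S by construction.

## Graph metrics

Definitions are the standard Watts–Strogatz / Latora–Marchiori forms (see
README). Two conventions needed fixing:

- **Lp on fragmented graphs.** At the low end of the grid (S = 0.05),
  90-node networks can fragment. Lp is the mean distance over *reachable*
  pairs, with the unreachable-pair count reported alongside. The harmonic
  alternative (1/E_glob) is available via `lp_convention="harmonic"`, but
  as the default it would make Lp and E_glob redundant (they are tested as
  deliberately distinct quantities); observed and null networks always use
  the same convention, since mixing them would bias λ.
- **Degree < 2 nodes** get clustering 0 and local efficiency 0, and stay
  in the means (excluding them changes Cp at low sparsity; inclusion keeps
  the metric defined everywhere and is the common toolbox behaviour).

Distances are all-pairs BFS implemented as vectorised boolean wavefront
expansion; clustering from the diagonal of A³. The implementation is
validated on every metric against independent brute-force oracles
(neighbour-pair enumeration, Floyd–Warshall) to 1e-12 on random graphs,
and against hand-computed analytic fixtures.

## Null models and small-worldness

Nulls are Maslov–Sneppen double-edge swaps: 10·K *attempted* swaps per
null (attempts, not successes, are counted; swaps creating loops or
multi-edges are rejected), preserving the degree sequence exactly. The
ensemble default is 100 nulls; the pipeline driver and acceptance run use
20 nulls on an evenly spaced 8-value sparsity subset, which keeps runs in
minutes while leaving γ/λ estimates stable at this graph size (SD of the
ensemble mean shrinks as 1/√n_random and is already small at 20).
Ensemble RNG seeds derive from (base seed, subject, sparsity) via a hash,
so results are independent of processing order.

γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ. The literature's criterion
"γ > 1 with λ ≈ 1" names no cutoff, so classification uses an explicit
operationalisation — group-mean γ > 1 **and** group-mean λ ≤ 1.1 — with
both cutoffs configurable. On the default synthetic cohort this flags the
upper sparsity range (0.30–0.40 at the 1.1 cutoff): γ stays well above 1
everywhere, while λ only settles toward 1 as density grows. σ is reported
as a convenience index; it is sensitive to the λ denominator and is not
used for classification.

## Statistics

- **t-tests** are pooled-variance (Student) by default, two-tailed,
  df = n₁+n₂−2; Welch is an option. Pooled was chosen because it exactly
  reproduces the printed p-values of the motivating cohort table from
  their (mean, SD, n) triples (education 0.060, ADL 0.047, memory 0.003,
  immediate recall 0.036, Stroop color 0.001). `summary_ttest` computes
  the identical statistic directly from summary triples.
- **Sign convention**: patient minus control, so t > 0 means the metric is
  higher in patients.
- **2×2 association**: Pearson chi-square without continuity correction by
  default; Yates-corrected and Fisher's exact variants are provided, since
  printed categorical p-values in this literature are often ambiguous
  about which was used.
- **AUC** summaries use the trapezoid rule over a stated sub-range whose
  endpoints must lie on the grid (default 0.08–0.31 for the cognition
  analysis; full grid span for group comparison).
- **FDR** is Benjamini–Hochberg at q = 0.05, applied within each
  (metric × scope) family — per-sparsity curves, the AUC family, and each
  nodal metric's 90 regions separately. Nodal tests are reported at a
  typical sparsity S = 0.18.
- **Cognition correlation** is Pearson r between per-subject AUCs and
  scores, computed within the patient group in the pipeline driver
  (mirroring the cohort-study design of relating pathology burden to
  cognition among patients).

## Determinism

Every random stage derives from a single config seed (`numpy` Generator /
SeedSequence); reruns with the same config produce byte-identical TSV
outputs, which the test suite checks by hashing. Run logs record package
version, config hash, seed and per-stage record counts (no timestamps, to
keep reruns comparable).

## Problem sizes used in validation

The recovery experiments use the full design size (23+20 subjects,
90 regions, 230 timepoints, 36-value grid, 20 replicates). Pipeline-level
determinism and IO tests use scaled cohorts (6–12 subjects, 24–30 regions)
with small null ensembles; these sizes exercise every code path and are
the package's chosen balance between coverage and turnaround. Null-model
reference checks (Erdős–Rényi self-normalisation, Watts–Strogatz
small-worldness) use N = 90 graphs with 100 nulls.

## Known limitations

- Positive-only thresholding discards potentially meaningful
  anti-correlations (configurable but untested against ground truth with
  negative coupling).
- The finite-mean Lp convention makes Lp non-comparable across graphs with
  very different fragmentation; the unreachable-pair count should be
  inspected at low sparsity.
- No covariate adjustment (age, education), no weighted or directed
  metrics, no lattice-referenced small-world index, no imaging-space
  preprocessing.
- The synthetic cohort's cognition coupling is linear by construction;
  recovery tests cannot speak to nonlinear brain–behaviour relationships.
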