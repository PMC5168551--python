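# Methods

## Pipeline overview

A stance-phase recording is an ordered sequence of same-shape non-negative
pressure grids sampled (by default) at 126 Hz. The pipeline is:

1. **COP extraction** — per frame, the pressure-weighted centroid
   (Xc, Yc) = (Σ Pᵢxᵢ, Σ Pᵢyᵢ) / Σ Pᵢ over sensor-cell centers. Frames with
   zero total pressure are skipped rather than failing the recording (they
   occur at stance onset/offset in thresholded data). The foot's bounding box
   is the union of cells active in *any* frame; a per-frame box would make the
   subsequent size normalization jitter frame-to-frame.
2. **Standard-foot mapping** — X′ = 30·X/L_X, Y′ = 20·Y/L_Y, with X the long
   (heel→toe) axis. This removes foot-size differences so COP lines from
   different subjects are commensurate. The 30 × 20 target frame follows the
   standard-foot convention of the sensor-array model; only the ratio matters
   downstream because features are max-normalized anyway.
3. **Key points** — k = 5 points at indices round(j·(T−1)/(k−1)), j = 0…4
   (half-up rounding), flattened to the 10-vector (C1x, C1y, …, C5x, C5y).
   How the five points should be placed is not specified by the source method
   beyond their count; time-equidistant points anchored at the first and last
   COP sample match the structure of the published feature tables (C1x small,
   C5x ≈ 1 after normalization) and are the simplest reproducible rule. The
   index rule is a small pluggable function (`key_point_indices`) should an
   arc-length or anatomical-event rule be preferred.
4. **Normalization** — each feature column is divided by its maximum over the
   analysis set (combined, left-only or right-only, mirroring the published
   per-experiment normalization). The maxima are stored in the model set and
   re-applied to query samples; queries may legitimately exceed 1 and are
   flagged in the log, not clipped.

## Fuzzy C-means

Objective J = Σᵢ Σⱼ uᵢⱼᵐ ‖xⱼ − vᵢ‖², columns of U constrained to sum to 1.
Defaults follow the published experiment settings: m = 2, ε = 1e−5 on the
max-abs membership change, at most 100 iterations; c = 4 for combined-side
data, c = 2 per side.

Numerical choices:

- **Membership exponent.** The update uses the standard Bezdek exponent
  2/(m−1) on the distance ratios. (A published rendering of this formula with
  2/(m−2) is undefined at its own setting m = 2 and is treated as a typo.)
- **Zero distances.** A sample coinciding with one or more centers gets its
  full membership split equally among the coinciding centers.
- **Degenerate clusters.** A cluster whose membership mass vanishes is
  re-seeded at the sample farthest from any surviving center (logged).
- **Initialization.** U is drawn column-stochastic uniform at random from a
  seeded generator. Because the fixed point reached depends on the start, the
  driver restarts 10 times by default and keeps the lowest-objective run; on
  all three packaged tables this optimum is reproducible across seeds to
  ~1e−10 in J.
- **Hardening.** Labels are the per-sample argmax membership, ties broken
  toward the lowest cluster index so results are deterministic.

The objective trace (recorded as J(U_{k+1}, V_k) each iteration) is
non-increasing by construction of the alternating updates; the test suite
asserts this within 1e−9 on random instances.

A caveat established during development: the *printed* membership tables are
not a fixed point of these updates on the printed 2-decimal features — one
update step moves entries by up to 0.44, and iterating to convergence from
the printed memberships reaches the same optimum as multi-restart FCM, which
agrees with the printed hard partition on only about two thirds of samples
(68 % left side, 72 % right side, 51 % combined). The printed tables were
presumably produced from unrounded features. The packaged fixtures therefore
serve as *inputs* (features + reference labels) to the identification
experiments, and cluster-level replication is asserted only as a stable
optimum with partial agreement, never as numerical membership recovery.

## Kernel SVM

The binary machine solves the dual max Σαᵢ − ½ΣΣαᵢαⱼyᵢyⱼκ(xᵢ,xⱼ) subject to
0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0, by SMO: at each step the maximal KKT violator in the
"up" set is paired with the index giving the largest second-order objective
decrease, and the two coefficients are updated analytically. Kernels: linear,
polynomial (⟨x₁,x₂⟩ + R)^d, Gaussian exp(−‖x₁−x₂‖²/2σ²).

- **Soft margin.** The source formulation is hard-margin; real COP features
  are not separable, so a box bound C is added (default C = 1), with C = ∞
  requesting the hard-margin formulation. Numerically C = ∞ is rendered as a
  box of 1e6 — on inseparable data the literal hard-margin dual is unbounded.
- **Stopping rule.** The KKT violation is driven below 1e−8 *relative to the
  gradient scale*. Near-hard-margin fits push dual coefficients (hence
  gradients) to ~1e6, where an absolute 1e−8 sits below float64 resolution;
  on separable problems gradients are O(1) and the rule coincides with an
  absolute 1e−8. The inner loop is numba-compiled when numba is installed
  (pure-Python fallback otherwise); worst-case fits on the packaged tables
  take ~3e7 pair updates, hence the generous default iteration cap of 1e8.
- **Bias.** b is the mean of yₛ − Σαᵢyᵢκ(xᵢ,xₛ) over free support vectors
  (midpoint of the KKT bounds if none are free) — the KKT-consistent rule. A
  published closed form dividing by 2Σ_{yᵢ=1}αᵢ is dimensionally inconsistent
  and is not used.
- **Prediction.** sign of f(x); an exact 0 maps to +1 (documented tie rule).
- **Multiclass.** One-vs-one voting (the 4-model experiment needs a scheme
  the source never specifies); vote ties break by the largest summed decision
  magnitude in a class's favor, then by lowest class label. A pair whose
  training fails falls back to a constant majority-label vote (logged).

## Replication experiments

Ground truth for the three experiments is the printed `category` column of
the packaged tables (deterministic; an optional mode re-runs FCM first).
Protocols: experiment 1 trains on combined-table rows 1–80 and tests on
81–100 (4 classes); experiments 2–3 run adjacent-block 5-fold CV on the 50
per-side samples — each test block is 10 consecutive rows, blocks taken from
the *end* of the table first, matching the published fold listing (fold 1
trains 1–40/tests 41–50, …, fold 5 trains 11–50/tests 1–10).

The kernel and regularization behind the published accuracies are unreported,
so each runner sweeps a fixed documented grid — linear; polynomial R = 1,
d ∈ {2, 3}; Gaussian σ ∈ {0.5, 1, 2}; each at C ∈ {1, 10, ∞} — and the report
flags every configuration whose mean lands on the published value, plus the
best-matching configuration (smallest mean gap, then smallest per-fold L1
gap, then grid order) and its gap. Outcomes on the packaged tables: the
combined-table 50 % and the left-side mean 76 % with fold-5 100 % are
reproduced exactly by grid configurations; the right side's best attainable
mean is 64 % against a published 62 % — one extra misclassified sample over
the 50 CV test points — with fold-5 90 % reproduced. Accuracies are fractions
internally and percentages (0 decimals) in reports.

## Synthetic data generator

Each synthetic stance is an isotropic Gaussian pressure blob (σ = 2 cells)
translating along a COP path on a 20 × 40 sensor grid for 63 frames at
126 Hz (~0.5 s stance), modulated by a half-sine loading/unloading profile
peaking at 100 sensor units, with additive per-cell Gaussian noise truncated
at zero to respect pressure non-negativity. The path is a piecewise cubic
through 5 control points in the unit square — deliberately commensurate with
the 5-key-point feature design — placed in the grid with a 2σ margin; paths
that would push the blob off the grid raise a configuration error.

Two default families stand in for the study conditions: a gently curving
normal roll-off, and an "ACLD-like" path deviated by 0.15 normalized units
medio-laterally at mid-stance (the condition's characteristic COP
abnormality). Cohorts add per-recording control-point jitter (SD 0.02
normalized units) for within-family variability and use per-recording child
seeds so any cohort is reproducible from one seed. Default test conditions
are 30 recordings per family at noise SD 5 % of peak amplitude.

What the generator does *not* emulate: anatomical pressure structure (heel /
metatarsal / toe sub-regions), the double pressure peak of real vertical
force curves, sensor saturation and quantization, or between-subject foot
geometry differences. Passing end-to-end tests on this generator shows the
pipeline recovers known COP geometry and separates geometrically distinct
path families under noise — not that the feature set is clinically
discriminative.

## Known limitations

- The five key points are time-equidistant; stance events (heel strike,
  midstance, toe-off) are not detected.
- Hard-margin results on inseparable data depend mildly on the finite box
  rendering of C = ∞ (test points close to the decision surface can flip);
  the packaged-table accuracies are stable at the default 1e6.
- FCM finds a reproducible multi-restart optimum, but that optimum need not
  match a partition produced from differently rounded inputs (see the caveat
  above).
- Membership values of the published tables are treated as reference data,
  not as reproducible outputs.
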