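# Methods

This note documents the models, conventions and numerical choices behind
`wormrle`, in the order the pipeline runs.

## Step decomposition

**Resampling.** The raw track is interpolated linearly onto a regular grid
`t0 + i·Δt` (default Δt = 1 s), truncated at the last raw timestamp. Linear
interpolation (rather than nearest-sample picking) makes the stage robust
to jittered camera timestamps; samples already on the grid are reproduced
exactly.

**Turning events.** The scan keeps a *reference heading*, initialized from
the first two sampled points. At each sampled point i the heading of the
incoming segment (i−1 → i) is compared with the reference; if the absolute
circular difference exceeds Θ (default 40°, between the ±30° head-angle
wobble of straight crawling and genuine reorientations), point i becomes a
turning event and the reference resets to the heading of the segment
leaving i. Zero-displacement segments (below 10⁻¹² mm) inherit the nearest
defined heading, so pauses neither crash the angle math nor fabricate
turns.

Two conventions here were genuinely open and are isolated behind single
functions:

* *Reference heading* = the first post-event displacement. The main
  alternative (mean heading of the whole preceding step) is smoother but
  makes the scan O(n²) in pathological cases and blurs sharp corners; the
  first-displacement rule detects a 90° corner at the corner-adjacent
  sample, which is the behavior wanted for step segmentation.
* *Interior angle* with 180° = straight continuation and 0° = reversal.
  This is the only convention under which "shallow turn" (≥ 90°) includes
  straight movement and "sharp turn" (< 90°) includes reversals, matching
  the sharp/shallow vocabulary used throughout.

**Known property: Θ hysteresis.** Because the reference resets at each
event, the detector has memory: event sets for different Θ are not nested,
and the per-path event count is not strictly monotone in Θ (a larger Θ can
delay one event, re-anchor the reference differently and admit an extra
event later). Empirically the inversion is rare (≈1% of 40 s default-
parameter synthetic paths over a 20–150° grid) and the *mean* event count
decreases strictly with Θ; the tests assert exactly that (mean monotone,
per-path monotone in ≥ 95% of paths).

**Normalization** is min–max per feature, pooled over *all* animals of a
run — the step clustering is pooled, which requires a common scale. A
zero-range feature is mapped to 0 and flagged rather than producing NaNs.
The first step of each path has no angle; it is excluded from clustering
(its feature vector is incomplete) but kept in the table for bookkeeping.

## Symbolization

k-means (scikit-learn, Euclidean distance) on the normalized
length/angle/speed triples, k ∈ [2, 5], default 2. Determinism matters
more than the last fraction of inertia, so the fit uses a fixed seed,
10 restarts, tolerance 1e-6 and ≤ 300 iterations. Raw cluster labels are
arbitrary, so clusters are relabeled to symbols 1..k by ascending mean raw
angle; this makes symbol semantics invariant to initialization (symbol 1 =
sharpest cluster). Assignment ties go to the lowest symbol id. The
per-symbol raw feature ranges are reported so that the angle split around
90° can be inspected. A decision-tree re-validation of k is deliberately
out of scope; instead `angle_rule_agreement` scores how well the k = 2
symbols match the plain 90° threshold rule.

## Run-length encoding

Runs are maximal by construction (`decode ∘ encode = id`, property-tested
against a scan-based oracle). The bin scheme generalizes the printed
7-bin example — {1},{2},{3} then dyadic spans [4,8],[9,16],[17,32],[33,64],…
— continuing the doubling until the cohort maximum run is covered, with
the last bin truncated. Matrix variants:

* IMF/AMF carry raw run-length columns (individual vs cohort-wide range);
  they satisfy Σ j·P(i,j) = n_p and Σ P(i,j) = n_r exactly.
* BAMF uses the bin *index* as column value; BAAMF the average observed
  run length in the bin (per animal), with empty bins falling back to the
  bin midpoint so descriptor formulas stay defined (flagged in the
  output).
* IMFL/AMFL apply ln(1 + count) elementwise — log1p because zeros
  dominate these sparse matrices; n_r and n_p are carried over unchanged
  and descriptor formulas are evaluated on the transformed entries.

n_r is the **total number of runs** (the standard run-length texture
convention); RP = n_r/n_p then measures run homogeneity: 1 when every
step alternates symbol, → 0 for long uniform stretches.

## Descriptors and redundancy filter

The eleven descriptors (SRE…RP) are evaluated with the matrix's column
values as j and the symbol index as i. ALN and RLN square the marginal
sums ((Σ_j P)² and (Σ_i P)²), the standard nonuniformity definitions. A
vectorized and a brute-force double-loop evaluation agree to 1e-12
relative on ~1000 random strings (acceptance-tested).

The correlation filter is greedy in the fixed descriptor listing order:
keep a descriptor iff |Pearson r| < 0.9 against every already-kept one.
Greedy-with-fixed-order was chosen over exhaustive subset search because
it is deterministic and the kept set provably satisfies the pairwise
bound; zero-variance descriptors are dropped with a warning. The kept set
is data-dependent and is reported, not asserted.

## Animal-level clustering

Descriptors span orders of magnitude (LRHAE vs RP), so features are
min–max scaled over animals before k-means (same determinism settings).
Default k = 5, mirroring a five-group experimental design; the synthetic
two-phenotype studies use k = 2. Composition is reported as two exact
ratio families: share-of-cluster (columns sum to 1) and share-of-group
(rows sum to 1). Stability across seeds and matrix variants is quantified
by the mean pairwise adjusted Rand index — chance-corrected and invariant
to label permutation — and is *reported*, not asserted, since it is a
property of the data at hand.

## Synthetic paths

The simulator emulates the qualitative structure of single-worm crawling:
long roaming bouts of nearly straight movement (per-second Gaussian
heading jitter) interrupted by turning bouts of discrete reorientations
(uniform magnitude in ±[turn_min, turn_max], direction a fair coin,
reversals realized as turns near 180°). Regime switching is evaluated on a
1-second clock, aligned with Δt, so simulator statistics are directly
interpretable in step units. A reorientation is drawn on the second the
turn regime is entered *and* on every further second spent in it, the
exit check following the draw — so a turning bout of b seconds produces b
reorientations, and with both switch probabilities at 1 every second
reorients. Per-frame displacement is speed/frame_rate along the current
heading, speed ~ N(mean, sd) truncated at 0.

Defaults: 300 s at 30 Hz, speed 0.12 ± 0.03 mm/s — a realistic crawling
speed and recording length at desk scale. Two presets define the study
conditions for recovery experiments, calibrated once to produce
sharp-symbol fractions of ≈ 0.6 and ≈ 0.1:

| preset | p_roam→turn | p_turn→roam | jitter SD | turn range |
|---|---|---|---|---|
| sharp-turn-rich | 0.22 | 0.7 | 20° | 115–180° |
| shallow-turn-rich | 0.06 | 0.8 | 18° | 50–130° |

What the simulator does **not** emulate: body posture (omega turns, head
bends), spatially correlated speed modulation, food-patch geometry,
tracking noise and segmentation dropouts. Passing recovery tests
therefore show that the pipeline separates phenotypes that differ in
turn statistics; they do not show robustness to the imaging artifacts of
real video data.

`bimodal_step_tables` skips the trajectory level entirely and draws step
features directly (angles from two Gaussian modes at 20° and 160°,
SD 8°), providing a controlled fixture for the symbolization stage alone.

## Problem sizes and determinism

The test suite runs the simulation studies at desk scale: recovery uses
two 20-animal cohorts of 300 s tracks over 20 cohort seeds; the
angle-rule study uses 8 animals × 120 steps over 20 seeds; oracle
equivalence uses 1000 random strings of length ≤ 500. Every stochastic
component (simulator, k-means, hypothesis) is seeded; rerunning the
pipeline with an identical configuration reproduces byte-identical
artifact files, which the test suite asserts.

## Limitations

* The turning-event detector is hysteretic in Θ (see above).
* Descriptor semantics of "low/high angle" (LARE, HARE, …) are
  documented for the two-symbol alphabet; larger alphabets are supported
  structurally but the i² weighting then mixes ordinal distance with
  angle semantics.
* The correlation filter's kept set depends on the cohort; it is an
  output, not a stable signature.
* With heavily overlapping phenotypes the animal-level k-means grouping
  is unstable across seeds; use `stability_report` before interpreting
  cluster composition.
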