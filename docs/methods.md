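# Methods

This note documents the models behind `replipat`, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the package's known limitations. Everything quantitative stated here
is computed by the test suite or the example scripts.

## Coordinate model and geometry

All coordinates are continuous nanometres in image-local axes; no pixel
grid, membrane curvature, or platinum-shadowing geometry is modeled.
ROIs are simple polygons. Points exactly on a polygon edge count as inside
(closed region). For active zones (AZ) a particle also counts as belonging
to the region when it is *strictly* closer than the rim width (default
30 nm) to the demarcation border — the "outer rim" convention for synaptic
membranes, where the demarcation traces the intramembrane-particle
aggregate and labels sit slightly outside it.

The ROI "center" used by radial statistics is the area centroid (center of
gravity). The normalized radial position of an interior point is its
centroid distance divided by the centroid-to-boundary distance along the
ray through the point, computed by direct ray/edge intersection
(vectorized over points and edges; first crossing wins for non-convex
shapes, and values are clamped to 1). If the centroid of a strongly
concave ROI falls outside the polygon, the maximum boundary distance is
used as the normalizer and a warning is emitted; CPI itself refuses such
ROIs because the center–periphery reading would be meaningless. For any
star-shaped ROI, uniform points have E[CPI] exactly 0.5 (conditional on
the ray, the normalized radius has density 2u on [0, 1]), which is what
the Monte-Carlo null check asserts.

Particles admitted to an AZ only through the rim are assigned CPI = 1:
they are maximally peripheral by construction, and the assignment keeps
the rim population visible in the statistic rather than discarded.

## Distance statistics

NND and APD are plain Euclidean distances with **no edge correction**,
matching the field's convention for these replica analyses. The bias is
upward for ROIs whose scale approaches the mean NND; at the default test
geometry (100 µm² ROI at 100 particles/µm²) fewer than 2% of particles sit
within one expected NND of the border and the simulated CSR mean agrees
with 0.5/√D within Monte-Carlo error. Per-ROI analyses of small patches
(AZs of ~0.1 µm²) inherit the bias in both the observed and simulated
patterns, so paired real-vs-null comparisons remain valid.

Sample skewness is the adjusted Fisher–Pearson estimator (bias-corrected
third standardized moment).

## Random simulation

Hard-core placement uses sequential random rejection (RSA): candidates
uniform in the ROI, rejected when closer than 10 nm (default) to an
accepted point, with a 10⁴-attempt-per-point budget; an infeasible packing
raises an error naming the stalled density. Label displacement shifts each
point by a vector drawn area-uniformly from a 30-nm-diameter disk (radius
∝ √u), giving a mean shift of (2/3)·15 = 10 nm. Displaced points are not
clipped back into the ROI — real labels cross demarcation lines — and all
density comparisons re-count within the region. The hard core applies in
every use of the random null.

## Fitted simulation (Matérn cluster process)

The Matérn cluster process has Poisson parents (intensity κ), each
spawning a Poisson(µ) number of offspring uniform in a disk of radius *R*.
Simulation draws parents in the ROI buffered by *R* so border-straddling
clusters contribute, and clips offspring to the ROI.

Fitting is minimum contrast on Ripley's K with exponent ¼: the border-
corrected (minus-sampling) empirical K is compared with the closed-form
Matérn K on a 50-point grid, κ and *R* optimized (coarse grid then
Nelder–Mead in log space) with the intensity constraint κµ = n/area
imposed exactly. The contrast radii run up to min(ROI diameter/4, 8× the
pattern's mean NND): the cap keeps the fit on the cluster-scale part of K,
where the border-corrected estimator still has many reference points —
without it the noisy large-r tail dominates the contrast and radius
recovery degrades severely. Fits with µ ≤ 1.5 or *R* above half the ROI
diameter are flagged `degenerate` (no resolvable clustering; CSR input
lands here).

Goodness of fit uses the two-sample Kolmogorov–Smirnov test on both APD
and NND, with a subsampling bootstrap to avoid excessive power at large n:
when the simulated sample exceeds 100 values, 1000 subsamples of 100
values (drawn without replacement) are each tested against the observed
sample's empirical CDF and the p-values averaged; at or below 100 values a
single exact test is used. The bootstrap p-values use the asymptotic
Kolmogorov distribution with Stephens' small-sample correction, which
matches the exact test's null behavior (mean p ≈ 0.5) at these sizes while
being orders of magnitude faster. Inputs are sorted internally, so the
statistic is invariant to input order and reproducible given a seed.

A simulation is accepted iff p ≥ 0.1 for **both** APD and NND. The
acceptance loop resamples from a single fit (no re-fitting after
rejection), with a default budget of 100 attempts; on exhaustion an error
carries the best attempt and its p-values. The association driver
(`association_vs_fitted`) uses that best attempt rather than aborting the
replicate, flagging the row `sim_accepted=False`; with realistic labeled
patterns a few percent of replicates end there, almost always on the APD
criterion (the APD of a pattern with ~10 parent clusters is dominated by
the chance parent configuration).

## Cluster detection

DBSCAN uses minPts = 3 (a cluster is at least three particles) and
eps = median + 1.5·IQR of the pattern's same-channel NNDs, computed per
ROI by default (quartiles by linear interpolation, the "type 7"
convention). Input points are sorted by coordinates before clustering so
border-point assignment is deterministic. Ward-linkage clustering cuts the
dendrogram at a 50-nm cophenetic height; every particle is assigned
(singletons allowed). Cluster area is the convex hull of members;
collinear or sub-3-member groups get area 0, are flagged degenerate, and
are excluded from intracluster-density summaries while still counting
toward cluster density. PSD demarcation runs DBSCAN on the marker channel
and returns the hull of the member-richest non-degenerate cluster, ties
broken toward the larger hull.

**Limitation — eps on mixed patterns.** The NND-based eps rule adapts to
the *typical* spacing, which has two regimes on realistic membranes. When
a large share of particles is scattered or background (the default
synthetic soma: ~40% at 52 particles/µm² with 20/µm² background), the NND
distribution is bimodal, the IQR spans both modes, and eps inflates to
100–200 nm; chance aggregations of background points are then detected as
clusters (inflating cluster density ~40% above the generated truth) and
nearby true clusters can merge. When nearly all particles are clustered,
eps collapses toward the intra-cluster spacing and dense clusters can
fragment. Every *generated* cluster is still detected under the default
conditions (tested over 20 seeds), and the detected cluster count closes
the loop within 25% when background is low; but absolute cluster-geometry
summaries on mixed patterns should be read as properties of the
detector-plus-pattern, not of the generating process alone. This mirrors
how the rule behaves on real replica data.

## Calibration model

The leaflet convention: one phospholipid occupies ~0.65 nm², and 750,000
phospholipids are taken to build a 1 µm² half leaflet, so a species at
*m* mol% has theoretical density 750,000·*m*/100 molecules/µm². The two
constants are not mutually consistent (1 µm²/0.65 nm² ≈ 1.54×10⁶); the
750,000 figure is the operative convention that the 5 mol% → 37,500
worked example fixes, and both are configurable on `LeafletModel`.
Background subtraction (default 20 particles/µm²) applies in the general
calibration curve; the classic 850 /µm² → 2.3% worked example is
reproduced without subtraction, and both modes are explicit flags.
Efficiency regimes (≈17% at sparse target densities, 2–5% near probe
saturation) are chosen by the caller per context; the package does not
infer the regime.

The NND Gaussian mixture is a 2-component EM fit (unequal variances,
means initialized at the 25th/75th NND percentiles, 500 iterations max,
tolerance 10⁻⁶), components reported ascending by mean; fits whose means
collapse within one standard deviation are flagged degenerate.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume:
Matérn-clustered particles (cluster radius 17.5 nm ⇒ ~35-nm diameter,
~1000 nm² area; intracluster density ~0.009–0.014 nm⁻² by compartment
preset), a scattered CSR fraction (default 20% of the specific signal), a
CSR background (default 20 particles/µm²), per-compartment global
densities (soma/MS ~52, SmB ~49, SpB ~63, spine ~74 particles/µm²), and
the 30-nm label-displacement disk applied to *every* molecule position
(particle = molecule + antibody linkage, consistent with the null model).
The global density target is the measured total, so the specific signal is
the target minus background. Counts are Poisson around targets (a
`fixed_n` flag gives exact counts for deterministic tests). ROI shapes:
regular-polygon disks and 2:1 ellipses rescaled to the exact target area,
and smooth star-shaped "irregular" polygons from low-order Fourier radial
perturbations (guaranteed simple). Ground truth (cluster centers, per-
point membership, pre-displacement positions, realized counts) accompanies
every pattern.

What it does **not** emulate: platinum-shadow anisotropy, detection
misses/false positives beyond the uniform background, spatially varying
intensity within a compartment, membrane curvature projection, and the
animal/cell/image nesting of a real study (gen_study emits flat
per-ROI metadata only). Tests passing on generated scenes therefore
validate the estimators under the stated point-process model, not the
upstream imaging chain.

The second channel's association model places a coupled fraction of B
points at Gaussian offsets from A cluster centers (default scale 20 nm)
and the rest uniformly; both channels get label displacement. This is a
construction for power/specificity testing, not a mechanistic model of
protein–lipid interaction.

## Numerical choices

- RNG: every stochastic function takes an integer seed or a
  `numpy.random.Generator`; drivers thread one generator through
  replicates, so runs are reproducible end to end given one seed.
- Uniform sampling in polygons is rejection from the bounding box.
- KD-trees for NND; `pdist` for APD; hulls via Qhull with degenerate
  (collinear) inputs flagged rather than raised.
- Problem sizes in tests and examples are desk-scale by design: ROIs of
  1–8 µm², hundreds of particles, tens of Monte-Carlo seeds — large enough
  that each recovery criterion's tolerance is met with margin, small
  enough to iterate quickly.
- Ties in NND are broken arbitrarily (the value is equal either way);
  DBSCAN border-point ties are fixed by coordinate-sorted input order.

## Pipeline

`run_pipeline` validates the channel-role map before any computation, then
runs per target-channel ROI: density (rim-aware), NND mean and skewness,
mean CPI over in-ROI particles, DBSCAN cluster summaries, the random-null
mean-NND comparison, and the NND GMM (when ≥ 20 values). Any stage error
aborts with the stage name and ROI id. Output tables carry
image/ROI/channel/seed provenance on every row; an output directory is
never silently overwritten. Hierarchical statistics across ROIs (GLMM and
multiple-comparison machinery) are deliberately out of scope — the tables
are formatted to feed external tools.
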