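# Methods

## Scope and model

`saxsens` treats a flexible multidomain protein as an ensemble of rigid
conformers whose solution SAXS curve is the weight-averaged single-conformer
intensity. All inference is a posteriori: conformers are fixed (from
simulation, crystallography, or the synthetic generator) and only their
statistical weights are adjusted against one experimental curve. Errors are
assumed uncorrelated and Gaussian with known per-point σ(q); no error model
beyond that diagonal σ is used.

## Forward scattering

Single-conformer intensities come from the exact Debye double sum with the
i = j and q → 0 singularities replaced by their analytic limit 1, so
I(0) = (Σ f(0))². Three form-factor levels are provided:

- `unit` (f ≡ 1): every value has a closed-form oracle; default for bead
  models and tests.
- `residue`: one bead per residue at the residue centre of mass with a
  q-independent form factor equal to the residue electron count.
- `atomic`: 4-Gaussian Cromer–Mann factors, in vacuo.

There is no hydration-shell term and no excluded-volume contrast model; the
multiplicative scale c fitted to experiment absorbs contrast differences at
low q. This is a known systematic difference from hydration-aware
spherical-harmonics codes, so χ² values against real data are not
comparable bit-for-bit with those codes' output. Computed curves are
interpolated linearly in q onto the experimental grid, and extrapolation is
an error. The fitted constant offset (buffer-subtraction mismatch) is
optional and unconstrained in sign.

## Primary analysis

The Guinier fit is a weighted linear regression of ln I on q², iterated on
the number of low-q points until q_max·Rg ≤ 1.3 (configurable): start from
the lowest 20 usable points, shrink while the constraint is violated,
expand while it holds; the first non-positive intensity truncates the
usable range. A strictly positive slope is reported as "no Guinier region";
a flat curve legitimately yields Rg = 0. The dimensionless Kratky transform
(qRg)²·I/I₀ vs qRg is accompanied by the globular reference x²e^(−x²/3)
(peak at (√3, 3/e)) and the Debye random-coil reference 2/x²(e^(−x²)+x²−1).

The pair-distance distribution is computed from model coordinates (an
f(0)-weighted histogram of pair distances, unit area, 1 Å bins by default),
not by regularised inversion of experimental data. Its radius of gyration
uses the exact finite-N relation Rg² = ⟨r²⟩·(F² − Σf²)/(2F²), which reduces
to the textbook ⟨r²⟩/2 for many scatterers and gives exactly d/2 for a
two-point particle.

## Two-step clustering

Structural clustering runs HDBSCAN (scikit-learn implementation; the
dedicated `hdbscan` package is not a dependency) with min_cluster_size = 5
on per-frame vectors of pairwise Cα–Cα distances over the selected domains
— a roto-translationally invariant representation, so no frame alignment
is needed. Intra-domain pairs are included by default (they are
near-constant and harmless); a flag restricts to inter-domain pairs. Noise
frames (label −1) are discarded. Each cluster is represented by the member
minimising the summed pairwise feature-RMSD score; ties break to the lowest
index. Whether that score is an RMSD proper or a monotone transform of it
does not change the argmin; RMSD proper is used.

Profile clustering normalises curves to I(0) = 1, computes the pairwise
per-point χ²(i,j)/N_q under the experimental σ, agglomerates with Ward's
linkage and cuts at a flat threshold of 0.15. The normalisation behind the
published threshold is not documented anywhere authoritative, so threshold,
normalisation and linkage are all configurable. Each profile cluster is
represented by the member closest (in χ²) to the cluster mean — a
deterministic, oracle-checkable choice.

## Maximum-parsimony inference

The posterior over basis weights is exp(−χ²(w)) — no ½ factor — times a
uniform simplex prior, with the scale c re-estimated in closed form at
every χ² evaluation. Sampling is plain Metropolis with a symmetric
pairwise-transfer proposal: pick two components, move δ ~ U(−s, s) between
them, reject moves leaving [0, 1]. The step size s is adapted every 100
burn-in steps toward a 25–45% acceptance window and frozen afterwards, so
the post-burn-in chain satisfies detailed balance. Defaults are 51,000
steps with 1,000 discarded as burn-in. Reported weights are posterior means
(renormalised) with posterior standard deviations. States with ~0–1%
posterior weight are reported as-is, never pruned.

## Maximum-entropy inference

The objective is L = θ·S_KL + χ²/2. Published formulations differ in
constant factors inside the χ² term; any such factor is equivalent to
rescaling θ, so the ½ convention is fixed and documented. Optimisation runs
unconstrained in log-weight coordinates (w = softmax(a)) with the analytic
gradient and L-BFGS-B. The nuisance scale c is profiled out analytically at
every objective evaluation — by the envelope theorem the gradient with c at
its per-evaluation optimum is exact — which converges in one pass where a
literal alternation of weight steps and c re-estimation creeps along a
(c, w) valley; an outer loop (10 rounds maximum) re-checks L until its
relative change is below 1e−10 and flags non-convergence instead of
raising. The gradient is verified against finite differences in the tests.

The θ-scan (default 13 log-spaced values, 10⁻²…10⁶) walks from large θ to
small, warm-starting each fit. Elbow selection defaults to the
residual-plateau rule: the largest θ whose χ²_red is within 1% of the scan
minimum, i.e. the strongest regularisation that still achieves the best
attainable fit. A discrete maximum-curvature selector on the log–log
(S_KL, χ²_red) polyline is also provided; the two agree on sharp
single-corner curves, but the curvature rule is unstable on realistic scans
because the trace has a second corner where S_KL collapses toward the
prior-dominated branch. An explicit θ always overrides selection.
Significant conformers are those with w above the mean plus one population
standard deviation (strict inequality, so uniform weights yield none).

## Landscapes and errors

Free-energy surfaces are F = −kT·ln(h/h_max) on a weighted 2-D histogram
over two collective variables (default 40×40 bins over the observed range
padded 2%); the most populated bin defines F = 0 and empty bins are masked,
never assigned a value. Units are kT by default or kcal/mol at the given
temperature (300 K default, the usual simulation temperature). Difference
landscapes subtract initial from reweighted surfaces on bins occupied in
both. Weighted Rg statistics use total-weight (population) normalisation.
The Rg-threshold split assigns boundary frames to the compact side.

Block-averaging errors cut the series into blocks of doubling size and
report the maximum blocked SEM over sizes retaining at least 32 blocks.
The 32-block floor keeps each SEM estimate's own sampling noise near 13%,
so the max-over-sizes plateau read reflects correlation, not estimator
variance; with an 8-block floor the plateau read is biased high by tens of
percent even for white noise. This implies a minimum series length of 64.

## Synthetic data generator

The generator emulates the geometry that makes multidomain reweighting
non-trivial: three rigid quasi-uniform bead domains (30 beads, radius 8 Å)
whose centres sit at the ends of two 57 Å arms meeting at a hinge, with
8-bead straight linkers. Hinge angles span 21°–180°; the compact end gives
Rg ≈ 27 Å and the fully extended conformation ≈ 45 Å, bracketing the
25–45 Å range typical of an RBR-scale construct. Beads carry equal masses,
are labelled as Cα atoms with author-style residue numbers (domains mapped
onto 699–751 / 796–841 / 869–934), and default to unit form factors, so
structural metrics, clustering features and forward curves all have
analytic or brute-force oracles. Geometries whose tightest hinge would
overlap the terminal domains are rejected at validation.

Observations are I_obs = Σ wₖIₖ + ε with ε ~ N(0, σ(q)),
σ(q) = 1%·I(q) plus a floor of 0.5% of I(0) (no zero-σ points at high q),
on a 200-point grid to q = 0.35 Å⁻¹. By construction χ²_red of the
generating mixture against its own observation is ≈ 1, which the tests use
as a noise calibration.

Two recovery benchmarks define what "working" means here:

- *Two-state*: compact + extended conformer, truth (p, 1−p); both tracks
  must recover p.
- *Sparse metastable states*: real MD ensembles occupy a handful of basins,
  so 50 frames are drawn around 8 rigid states differing simultaneously in
  hinge angle (centres uniform in sin(α/2), which spaces the
  terminal-domain separation evenly), both arm lengths (40–65 Å) and twist,
  with small intra-state jitter; state draws are rejected until all state
  profiles are pairwise distinguishable (per-point χ² > 1 under the nominal
  noise). Truth populates 4 of the 8 states. On a smooth single-parameter
  continuum, by contrast, per-conformer weights are not identifiable from
  SAXS at all — neighbouring profiles differ by far less than the noise —
  and no inference method can correlate with a spike-sparse truth there;
  the basin structure is what makes the question well-posed, exactly as the
  basis-set construction presumes.

What passing these benchmarks does *not* show: real MD ensembles have
thousands of frames, imperfect forward models (hydration, flexibility
within states), and correlated experimental errors; recovery quality there
is bounded by those systematics, not by the inference machinery tested
here.

## Crystal-model metrics

The extended HOIP RBR reference model is assembled from PDB entries (not
redistributed): 5EDV chain B 699–867 plus 4LJP chain A 868–1071 grafted
after Kabsch superposition on the shared 860–867 backbone, with the
751–759 RING1 loop taken from 5EDV chain A. Centre-of-mass quantities are
mass-weighted over all atoms in the residue range (Zn included) — the
common trajectory-analysis default; a geometric-mean convention would shift
inter-domain distances by a few tenths of an Å, which is why the
acceptance tolerances on those distances are ±0.5 Å. Dmax is the maximum
inter-atomic distance of the coordinates, not a P(r) extrapolation. The
closed-arrangement D_IBR–RING2 is measured directly on the two crystal
fragments in their crystallographic frame; the 852–853 junction is not
rebuilt, and metrics that would require the rebuilt loop are out of scope.

## Numerical choices

- Simplex tolerance 1e−8 on weight sums; KL terms use the x·ln x → 0 limit
  and report infinite divergence (w > 0 where w⁰ = 0) as an error.
- L-BFGS-B: ftol 1e−14, gtol 1e−12, ≤ 2000 iterations per inner solve.
- Metropolis proposals that leave the simplex count as rejections
  (symmetric proposal, valid Metropolis on the constrained support).
- Ties in representative selection break to the lowest index; profile
  basis members are reported in ascending frame order.
- q-grid equality is checked to 1e−9 Å⁻¹; sinc is evaluated via `np.sinc`
  (exact limit at 0).
- All stochastic stages take explicit seeds and record them in their
  outputs; identical seeds give byte-identical results.

## Known limitations

- No hydration shell or excluded-volume contrast: absolute χ² against real
  curves differs systematically from CRYSOL-class forward models.
- Experimental P(r) (regularised inverse transform) is not implemented;
  P(r) here is model-based.
- The closed-model assembly stops at fragment superposition (no loop
  closure), so only metrics independent of the rebuilt junction are
  reported.
- HDBSCAN hyper-parameters other than min cluster size follow the
  scikit-learn defaults, which differ in detail across implementations and
  versions; the clustering partition on real trajectories is therefore
  implementation-sensitive at the margins.
- Weight uncertainty from MaxPars is the posterior spread under the stated
  likelihood only; forward-model systematics are not propagated.
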