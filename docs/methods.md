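# Methods

## Detection model and likelihood

`rollscr.scr` implements closed-population spatially explicit
capture–recapture for *proximity* detectors: a camera station can record a
given individual at most once per occasion (day), and repeat photographs of
the same individual at the same station on the same day are collapsed on
ingest. Detection of individual *i* at detector *k* on one occasion is
Bernoulli with the half-normal form `p_k(s) = g0·exp(−d_k(s)²/2σ²)`, where
*s* is the individual's latent activity centre and `d_k(s)` the Euclidean
detector–centre distance. Coordinates must be planar metres; the package
does no geographic reprojection.

Activity centres are integrated over a **habitat mask**: a regular grid of
cell centres tiling the trap bounding box expanded by a buffer on all sides.
The likelihood is the *full* (unconditional) form in which the number of
detected individuals is Poisson with rate `Λ = D·a·Σ_m p·(s_m)`:

    log L(D, g0, σ) = Σ_i log( D·a·Σ_m Pr(ω_i|s_m) ) − Λ

with `Pr(ω_i|s) = Π_k p_k(s)^{n_ik} (1−p_k(s))^{T−n_ik}` and
`p·(s) = 1 − Π_k (1−p_k(s))^T`. Because p is constant across occasions
within a session, the per-occasion binary histories collapse without loss to
binomial counts `n_ik`, making one likelihood evaluation O(n·K·M). The
additive `−log n!` constant is dropped; `ScrFit.loglik_convention` records
this. The conditional-likelihood / Horvitz–Thompson route is deliberately
not implemented: the full likelihood is the default of the standard software
for this analysis, and matching that default keeps session fits comparable.

### Parameterisation, optimisation, uncertainty

Estimation is on link scale — log D, logit g0, log σ — which keeps the
natural parameters in range and makes the objective smooth and
approximately quadratic near the optimum. Cold starts use cheap
method-of-moments values (σ₀ from half the mean per-individual maximum
recapture distance, floored at half the mean nearest-trap spacing; g0₀ from
detections per unit exposure discounted by the mean distance decay, clipped
to [0.001, 0.5]; D₀ = n / (a·Σ_m p·(s_m))) followed by Nelder–Mead
(objective tolerance 1e−8) and a BFGS polish. When a warm start is supplied
— in rolling batches, the previous window's optimum, whose data overlap the
current window in all but two days — the simplex stage is skipped and BFGS
runs directly from it; `batch_fit` falls back to the cold path if that
fails. Standard errors come from inverting a central-difference Hessian
(step 1e−4 on link scale); 95% intervals are `estimate ± 1.96·SE` on link
scale back-transformed to the natural scale (lognormal-style for D and σ,
logit-interval for g0). A fit is flagged converged when the objective is
finite and the numeric gradient's max component is below 0.1 (the objective
is O(10²–10³), so this is far above central-difference noise but tight
enough to exclude stalled optimisations). A non-positive-definite Hessian
yields NaN intervals plus a warning rather than an error.

Degenerate inputs are rejected before optimisation: no detections; fewer
than two individuals; no individual at ≥ 2 detectors (σ unidentifiable — a
session of single-station animals carries no spatial signal).

### Mask resolution defaults

Defaults are buffer 30 km and spacing 300 m, appropriate for σ ≈ 2.5–5 km
(buffer ≳ 4σ, spacing ≪ σ). Both are quadrature choices, not model
parameters: the suite checks that on a typical simulated session D̂ moves
< 1% when the buffer grows 15 → 30 km or the spacing halves 600 → 300 m.
On that basis the simulation studies in the test suite and the rolling
batches use coarser, faster masks (buffer 15 km with 1 km spacing for
single-session studies, 3 km spacing for the 50-replicate rolling-series
study) — accuracy there is governed by the invariance checks, and the
problem sizes were chosen as the smallest that leave those checks
comfortably satisfied.

## Rolling sessions

`make_windows(total_days, L, step=1)` enumerates every inclusive window
`(d, d+L−1)`; a 365-day record gives 276 90-day and 186 180-day sessions.
Each window is summarised (individuals, detections per sex — counted after
the daily dedup — and male spatial recaptures) and fitted independently with
one shared mask. Sessions whose fit is impossible propagate as missing
entries carrying the reason; the series never silently drops windows.

**Spatial recaptures** are defined as Σ over individuals of
(distinct detectors with a detection − 1), floored at zero. The quantity is
not given a formula in the field literature this package follows; this
definition counts the extra stations beyond each animal's first — the
information σ is actually estimated from — and at typical session sizes
(~14 males) yields totals of a few tens, consistent with reported values,
whereas (detections − individuals) would be an order of magnitude larger.
Alternative definitions could be added alongside.

No correction is applied for the overlap of consecutive windows: each
session estimate is taken at face value, matching how such rolling series
are reported. Correlation p-values on these series are therefore
anticonservative (see below).

## Synthetic data

`simulate_population` draws N ~ Poisson(D_true × region area) activity
centres uniformly on the region (trap bounding box + 15 km simulation
buffer by default — beyond ~4σ an individual is effectively undetectable,
so the finite region is not a real truncation), with i.i.d. Bernoulli
sexes. `simulate_detections` draws every individual×detector×day Bernoulli
independently under the half-normal law, with optional day-indexed
multipliers m_σ(t), m_g0(t). All draws use seed-derived independent
substreams, bit-for-bit reproducible.

`scenario_paper_like()` encodes the reference study conditions: a 4×5 grid
at 2 km spacing (20 stations, mean nearest-neighbour distance 2.0 km), 365
daily occasions, male density 2.0 per 100 km², g0 = 0.06/day, σ = 3.6 km.
The population is ~64% male (21 males to 12 females in a year of
monitoring), and D_true is scaled so the male component is exactly 0.02/km²
— the quantity the male-only fits estimate. The default modulated variant
uses m_σ(t) = 1 + A·sin(2πt/365) with A = 0.3, chosen once from the ±30%
spread of fitted σ around its annual mean in the reference study; there is
no canonical value, and A is exposed as a knob.

What the generator does **not** emulate: trail-mediated detection (real
stations sit on trails males patrol, so real g0 is behaviourally
heterogeneous and female g0 is much lower than male g0 — the generator uses
one g0 for both sexes, so simulated female detection counts run higher than
field values); territoriality or male–male avoidance (centres are uniform,
not inhibited); home-range drift (centres are fixed for the year); and
non-circular ranges. One consequence: a compact rectangular grid spans
~6×8 km, less than a real ~120 km² trail network, so the expected number of
males detected per 90-day session is ~11 rather than ~14. Passing tests
therefore demonstrate correctness of the estimator and the qualitative
session-length phenomena, not that the generator reproduces field counts.

GPS tracks are i.i.d. normal displacements about the centre, which makes
`18.86·σ_move²` the asymptotic ~95%-of-use area; a finite sample's 100% MCP
sits below it at small n and can overshoot it at large n (the hull absorbs
outliers), so tests assert order of magnitude and growth in n, not equality.

## Home ranges and the σ ↔ area transform

`mcp_area` returns the convex hull (via shapely) of a track's fixes with
area in km²; fewer than three non-collinear fixes give a flagged
degenerate zero-area range. `rolling_mcp` applies the same window rule as
the density sessions (span − L + 1 windows at step 1), aligned to the
track's first fix day. σ-equivalents use `σ = √(area/18.86)` and its exact
inverse `area = 18.86·σ²`, valid under a circular range with a single
centre and half-normal use. `max_station_distances` ranks individuals by
the largest pairwise distance among the *detectors* where they were
photographed (not animal positions), excluding single-station individuals;
ties share the smaller rank.

## Series statistics

On simulated rolling series from a constant population the fitted density
and σ are strongly negatively correlated (median r ≈ −0.9 across seeds):
between-session variation in σ̂ is estimation noise that trades off
directly against D̂ along the likelihood ridge. Under strong seasonal
modulation of the true σ the picture is noisier — the seasonal signal and
small per-window sample sizes dilute the trade-off and the correlation can
weaken or even change sign in some years — so the strong negative
association is a property of stable-ranging series, not a universal law.

`pearson` wraps the product-moment correlation with pairwise-complete
filtering (rolling series contain missing sessions); `fit_polynomial_r2`
fits degree-1 (linear) and degree-2 ("curvilinear") least squares and
reports R² = 1 − SS_res/SS_tot. "Precision" of a session is defined as the
width (upper − lower) of its 95% density CI on the per-100 km² scale — the
natural reading of a mean precision of ~2.4 lying between CI extremes of
~0.5 and ~5.3 around a ~2.0 mean; half-width and CV readings are not
supported. Because overlapping sessions are strongly dependent, reported
p-values understate uncertainty and should be read descriptively.

## Known limitations

- Half-normal detection only; no hazard-rate or other forms, no covariates
  on D, g0 or σ, no open-population or non-Euclidean variants.
- Wald intervals can undercover for very sparse sessions (few spatial
  recaptures); such sessions are often rejected as unidentifiable instead.
- The rolling series' sampling distribution is not corrected for window
  overlap anywhere in the package.
- File formats are this package's own minimal CSV dialects (`id,x,y`;
  `individual,sex,detector,day`; `animal,day,x,y`), not an interchange
  standard.
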