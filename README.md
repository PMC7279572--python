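# rollscr

Rolling-window spatially explicit capture–recapture (SCR) density estimation
for camera-trap surveys of low-density, wide-ranging animals.

Snapshot camera surveys of large carnivores typically run 60–90 days and are
fitted with closed-population SCR models. `rollscr` asks how stable such
estimates actually are: it takes a long (e.g. 365-day) record from a fixed
station grid, subsamples it into every contiguous 90- or 180-day session
(276 and 186 sessions respectively for a year), fits each session
independently with a from-scratch maximum-likelihood SCR estimator, and
summarises how the density series varies with ranging behaviour (σ), capture
probability (g0) and local demography. Fitted σ can additionally be
confronted with GPS-collar home ranges via 100% minimum convex polygons
(MCPs) and the circular home-range relation.

## The model

Each individual holds a latent activity centre *s*; a camera at distance *d*
detects it on any given day with half-normal probability

    p(d) = g0 · exp(−d² / 2σ²).

Centres are integrated over a discretized habitat mask (the trap bounding
box buffered by 30 km, grid spacing 300 m by default), and the number of
detected individuals *n* is Poisson, giving the full likelihood

    log L = Σᵢ log( D·a·Σₘ Pr(ωᵢ|sₘ) ) − D·a·Σₘ p·(sₘ)        (− log n! dropped)

with `Pr(ωᵢ|s) = Πₖ pₖ(s)^{n_ik} (1−pₖ(s))^{T−n_ik}`, `p·(s)` the
probability of at least one detection in the T-day session, and *a* the mask
cell area (km²). Estimation is on link scale (log D, logit g0, log σ) with
Wald 95% intervals back-transformed from a finite-difference Hessian.

Under a circular home range, range area and σ are linked by
`area = 18.86 σ²`, so telemetry MCPs convert to σ-equivalents via
`σ = √(area / 18.86)`.

## Worked example

Simulate a year-long 20-station survey (male density 2.0 per 100 km²,
g0 = 0.06, σ = 3.6 km), fit one 90-day session, then the whole rolling
series:

```sh
$ rollscr simulate --scenario paper-like --seed 7 --out-dir demo
simulated N=49 individuals, 1374 detections (0 duplicates collapsed) -> demo

$ rollscr fit --traps demo/traps.csv --captures demo/captures.csv \
      --window 1 90 --buffer 15000 --spacing 1000
n=14 individuals, T=90 occasions, K=20 detectors
D     = 2.45 per 100 km^2  (95% CI 1.38-4.34)
g0    = 0.0677  (95% CI 0.0549-0.0831)
sigma = 3.55 km  (95% CI 3.06-4.11)
logLik = -1269.5506  converged = True
```

The 90-day window detected 14 males; the density estimate (2.45/100 km²)
covers the simulated truth of 2.0, g0 and σ land close to their true values
(0.06, 3.6 km). Now the rolling analysis:

```sh
$ rollscr batch-fit --traps demo/traps.csv --captures demo/captures.csv \
      --length 90 --buffer 15000 --spacing 3000 --out demo/series90.csv
276 sessions (0 failed); mean D = 2.24 per 100 km^2, range 1.05-2.79 over 276 fits

$ rollscr analyze --series demo/series90.csv --pairs D:sigma,g0:det_male \
      --out demo/assoc.csv
precision (95% CI width, per 100 km^2): mean 2.73, range 1.15-3.31 over 276 sessions
2 associations -> demo/assoc.csv
```

Although the simulated population is constant, the 276 session estimates
range from 1.05 to 2.79 males per 100 km² — and the association table shows
why: density and σ move inversely (r = −0.90, linear R² = 0.81), i.e. the
between-session variation is driven by apparent ranging behaviour, not
abundance. `rollscr homerange --tracks demo/tracks.csv --rolling 90` adds
the MCP/σ comparison for the simulated collar tracks, and
`rollscr movement` ranks males by maximum between-station distance.

The same operations are available as library functions
(`rollscr.batch_fit`, `rollscr.fit_scr`, `rollscr.association_table`, …);
see `docs/methods.md` for the modelling details and design choices.

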