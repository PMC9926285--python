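# Methods

## Carrier flux law and its oracle

The transporter is modelled as a symmetric alternating-access uniporter:
one pool of `et` carriers cycles between outward- and inward-facing
conformations, substrate binds at rapid equilibrium with the same `Kd` on
both faces, the loaded carrier translocates at `k2` in either direction
and the empty carrier at `k4`. Grouping the four microstates into an
outward pool `Eo` (loaded fraction `θo = s_out/(Kd+s_out)`) and an inward
pool `Ei` (loaded fraction `θi`), the pools exchange at rates
`r_o = k2·θo + k4·(1−θo)` and `r_i = k2·θi + k4·(1−θi)`; solving
`r_o·Eo = r_i·Ei` with `Eo + Ei = et` and reporting the net loaded flux
`k2·(θo·Eo − θi·Ei)` gives the closed form used throughout:

    J = et·k2·k4·(θo − θi) / [k2·(θo + θi) + k4·(2 − θo − θi)].

`carrier_ode_flux` is an independent check of the same scheme: it
integrates `dEo/dt = −r_o·Eo + r_i·(et − Eo)` with an implicit stiff
solver (Radau, rtol 1e-12, atol 1e-13·et) until the residual satisfies
`|dEo/dt| < 1e-12·et·max(λ,1)` with `λ = r_o + r_i`. The tolerance is
deliberately far below the 1e-8 relative agreement asserted in tests:
with slow rate constants a looser stationarity residual would leave a
flux error of the same order as the bound being checked. Conservation of
the four-state sum is exact by construction of the reduction.

The Michaelis–Menten comparator is the canonical uncoupled alternative,
`J = et·(k2·θo − k4·θi)`: influx and efflux saturate independently with
the same four parameters, which is what makes internal concentration
track external concentration above threshold. The reference parameter set
is `k2 = k4 = 4`, `Kd = 10`, `et = 10` (arbitrary model units; no unit
conversion layer is provided).

## Homeostasis

Consumption is a constant demand `J_demand` (default 15), on the argument
that Pi assimilation is proportional to growth rate and growth rate is
constant across the conditions of interest. `solve_internal` finds the
unique root of `J(s_out, ·) = J_demand` in `[0, s_out]` by Brent's method
(relative tolerance 1e-12); uniqueness and bracket validity follow from
strict monotonicity of J in `s_in`. The balance point is stable because
the flux decreases in `s_in`. Starvation (`J(s_out, 0) < J_demand`) is an
explicit result value rather than an exception, because the regulon layer
consumes it as `s_in = 0`. `critical_external` root-finds
`J(·, 0) = J_demand` and reports unattainability when the demand meets or
exceeds the supremum `et·k2·k4/(k2+k4)` (carrier) or `et·k2` (MM).

`robustness_index` quantifies "internal level insensitive to external
level" as the fold-change of `s_in` between `lo·c` and `hi·c`, where `c`
is the model's own critical threshold; anchoring to `c` compares the two
flux laws over equivalent operating ranges. The defaults (2, 20) span a
10-fold external range and give 2.54 (carrier) vs 5.90 (MM) at the
reference parameters. The metric is this package's operationalization;
values near 1 mean robust homeostasis.

## Regulon model

State variables (per cell): high-affinity expression `e_H`, Spl2 level,
and the two reporter classes, all with first-order synthesis/dilution
`dx/dt = α·g(n) + β − δ·x`, with time in units of `1/δ` (δ = 1). Fast
layer, re-equilibrated every step: low-affinity activity
`a_L = 1/(1+(spl2/K_S)^m)`; internal phosphate from the two-carrier
balance `a_L·J_L(s_in) + e_H·J_H(s_in) = J_demand` (vectorised bisection,
60 halvings, starvation ↦ 0); nuclear Pho4
`n = n_mid·H(s_in; phi_plateau) + (1−n_mid)·H(s_in; phi_full)` with
`H(s; φ) = 1/(1+(s/φ)^8)` — a smoothed three-level step standing in for
the Pho80/Pho85 phospho-site logic, not a mechanistic kinase model.
Promoter drives are Hill functions of `n` with coefficient 8 and
midpoints `K_p = 0.15` (plateau class) and `K_d_prom = 0.75` (decoupled
class).

Default parameters (model units, `Kd_H = 1`): low-affinity
`(k2=4, k4=4, Kd=100, et=10)`, high-affinity shape `(4, 4, 1)` scaled by
`e_H` with maximum `α_H/δ = 10`, `J_demand = 15`, `α_S/δ = 10`,
`α_P/δ = 100` over a basal reporter level of 1, `K_S = 1`, `m = 2`,
`phi_plateau = 5`, `phi_full = 0.05`, `n_mid = 0.4`. These were chosen so
the low-affinity set point (`Kd_L/3 ≈ 33`) sits far above `phi_plateau`
(off state) while the high-affinity set point (`≈ Kd_H/3 = 0.33`) falls
between the two thresholds (plateau state). `K_d_prom = 0.75` keeps the
decoupled class below 2× basal at `n = n_mid` (at 0.7 the plateau-state
leak-through reaches 2.1× basal, blurring the class distinction the
parameter exists to encode). None of the regulon-level constants are
measured quantities; all are this package's design.

Integration is fixed-step forward Euler with `dt = 0.01/δ` (all
eigenvalues are −δ, so stability is unproblematic; negative levels abort
with advice to reduce `dt`). Sweeps settle each grid point for `12/δ`
plus a `1/δ` classification window — long enough for the slowest
transient in practice, the decoupled reporter's decay after the brief
full-activation excursion a cell passes through when entering the plateau
state — carrying the terminal state to the next point (path dependence is
the point). `classify_state` demands <1% relative drift of every
observable across the window (denominators floored at 1% of each
variable's natural scale) and labels by the window means: OFF at
`n < 0.1·n_mid` with both reporters below 10× basal, ON at
`n > 1 − 0.1·n_mid` with both induced, PLATEAU at `|n − n_mid| ≤ 0.1·n_mid`
with only the plateau reporter induced. Anything between definitions
raises rather than guesses; `MIXED` is reserved for population summaries.

The default sweep grid `(1, 2, 20, 40, 100, 600, 1500, 4000)` places
points inside the three regimes and away from two kinds of measure-zero
transition zones where the smoothed transfer function yields genuinely
intermediate stationary `n` that the classifier would (correctly) refuse:
the narrow bands where `s_in` crosses a threshold, and — for the
Spl2-disabled variant (`K_S = ∞`) — the range `s_out ≈ 170–400` where a
stable intermediate fixed point with `n ≈ K_p` exists because the
low-affinity flux can no longer be shut off.

The deterministic bistable window extends to arbitrarily high `s_out`
(commitment): once Spl2 is up, the high-affinity system pins `s_in`
regardless of medium richness. The experimentally finite bistable range
is reproduced only at the population level, by lognormal cell-to-cell
variability in the low-affinity capacity `et_L` (`population_sweep`,
default CV 0.3, mean-preserving): cells with larger `et_L` hold out in
the off state to higher `s_out`, giving intermediate activated fractions
over a broad band.

## Localization score

`score = P(pixel/median > t_q) − (1−q)`, with `t_q` the `q`-quantile
(default q = 0.995) of the pooled, median-normalized pre-starvation
reference. Per-frame median normalization makes the score exactly
invariant to intensity scaling, so expression drift cannot masquerade as
localization; the cost is saturation at the nuclear area fraction once
every nuclear pixel clears the threshold. Pixel inclusion uses the mask
when given; otherwise a two-stage Otsu cutoff (if the first split keeps
<15% of the frame it has isolated the bright nucleus, so the cutoff is
recomputed on the sub-threshold pixels). The maskless path assumes
well-exposed images with clear cell/background contrast. A minimum of
1000 included pixels is enforced for both reference and scored frames.
The statistic is behaviour-matched to the qualitative description of
histogram-tail analysis — zero under the null, increasing with nuclear
concentration — and its absolute scale is not meaningful beyond that.

## Synthetic data

`make_cell_image` renders an elliptical cell with a disk nucleus: all
cell pixels receive the projected cytosolic density `(1−f)·F/area_cell`,
nuclear pixels additionally `f·F/area_nucleus`, plus background `b`;
realized pixels are `Poisson(expected) + N(0, σ)` clipped at zero. The
additive projection reflects widefield imaging, where cytoplasm above and
below the nucleus contributes along the optical axis; at `f = 0` the cell
is uniform and the expected in-cell photon sum equals `F` for every `f`
(redistribution, not production). Defaults: 96×96 frame, cell semi-axes
(28, 22) px, nucleus radius 8 px (≈10% of the cell area), `b = 100`,
`σ = 2`, and `F = 2×10⁴`. The budget was fixed by scanning
F ∈ {5e3, 1e4, 2e4, 4e4} for the value keeping the score's response
strictly monotone over `f ∈ [0, 0.6]` with the widest margins — brighter
budgets saturate the tail statistic (every nuclear pixel already exceeds
`t_q` by `f ≈ 0.15`), dimmer ones bury small fractions in shot noise.
It also matches the dim, near-native expression levels the score is
designed for. What these fixtures do *not* emulate: photobleaching, cell
growth and division, textured backgrounds, segmentation errors, or 3-D
optics beyond the uniform projection — so passing tests demonstrate the
statistics' correctness on their stated model, not robustness to every
artifact of real microscopy.

Trace populations draw a state per cell from an (off, plateau, on)
mixture and lognormal intensities per timepoint (default component
medians 1, 30, 300; log-sd 0.4), making two-state mixtures cleanly
bimodal. `make_regulon_dataset` couples the regulon population sweep to
multiplicative lognormal measurement noise (CV 0.1). One global seed
expands to substreams via `default_rng([seed, index])`, so subsets are
independently reproducible.

## Known limitations

* The regulon layer is phenomenological: no intrinsic expression noise,
  no vacuolar storage dynamics, no transcriptional repression of the
  low-affinity transporters (only Spl2 inactivation), and thresholds in
  place of kinase biochemistry.
* The three-level Pho4 map is continuous; grid points landing inside its
  narrow transition bands are refused by the classifier by design.
* The localization score saturates at the nuclear area fraction and its
  absolute value depends on the chosen `q`; comparisons are meaningful
  within a reference, not across references.
* All quantities are in arbitrary model units; mapping to μM or minutes
  requires calibration outside this package's scope.
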