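# Methods

This note documents the model implemented by `cottonfibre`: its assumptions,
parameters, numerical choices, and the limits of what the synthetic-data
tests demonstrate.

## Physiological time

All development is clocked in physiological days: the daily increment is
E(T̄) = (T̄ − T_b)/(T_o − T_b) clamped to [0, 1], with T_b = 12 °C and
T_o = 25 °C (`thermal.ThermalParams`, config key `thermal`). T̄ is the
arithmetic mean of daily Tmin and Tmax; no sub-daily integration is
attempted. One parameter set serves the plant clock and every organ clock.
The clamp makes E continuous and piecewise-linear; accumulation is additive,
so reordering a fixed multiset of days leaves any accumulated age unchanged.

## Weather

Input weather is a gap-free daily series of (date, Tmin, Tmax) read from CSV
(`weather.read_weather`), or generated synthetically
(`weather.generate_weather`): the daily mean follows an annual sinusoid
`mean + amplitude·cos(2π(doy − peak_doy)/365.25)` peaking in late July
(day-of-year 205), with Tmin/Tmax offset by half the diurnal range and
perturbed by independent Gaussian noise. If noise inverts a pair the two
values are re-ordered, preserving the Tmin ≤ Tmax invariant. Generation is
bit-reproducible under a fixed seed.

Site presets are tuned so the noise-free April–October *active accumulated
temperature* — the sum of daily means on days with mean ≥ 12 °C, the
agro-climatological convention for "above 12 °C temperature sums" — matches
the published seasonal totals (Anyang 4561 °C·d, Huimin 4518, Yueyang 5245,
Aksu 4335). Tuning solves for the annual mean by bracketed root-finding
(`weather.tune_annual_mean`); the realised noisy sums land within a few
percent of target. Defaults: amplitude 14 °C, diurnal range 10 °C, noise sd
1.5 °C — plausible for continental-East-Asian cotton sites.

Film mulching is represented purely as an additive air-temperature increment
on Tmin and Tmax from sowing for a fixed number of calendar days (defaults
+2 °C for 60 days; both config keys). The magnitude and duration are
placeholders — the underlying soil-temperature physics is out of scope — and
the adjusted weather drives both the physiological clock and the quality
reduction factors, so mulch acts on fibre quality only through development
timing and early-season temperatures.

## Plant architecture

Phytomers appear on the main stem at a fixed plastochron once an emergence
lag (8 pd from sowing, config `emergence_lag`) has elapsed. The plastochron
is linear in log(density) between 3.0 pd (≤ 0.75 plants m⁻²) and 3.5 pd
(≥ 6 plants m⁻²), and mepiquat chloride adds 0.25 pd capped at 3.5 — a
monotone placeholder map (config keys) standing in for the upstream
calibrated density/MC response, chosen to respect the documented 3–3.5 pd
range.

Main-stem phytomers of rank ≥ 7 (`first_branch_rank`) each bear a fruiting
branch with up to 3 fruiting nodes (`nodes_per_branch`). A fruit's
cumulative phytomer number is CPN = branch rank + node rank, and every organ
appears when the plant clock reaches `emergence_lag + (CPN − 1)·plastochron`
— this implements the cohort property that organs of equal CPN appear
simultaneously and age together. Squaring coincides with node appearance by
default (`squaring_lag` = 0 pd); fruit age is counted from squaring, the
origin used in calibrating the fibre kinetics, so the lag only shifts
calendar timing.

Fruits progress square → flower (23 pd), flower → boll (3 pd later) and boll
→ open boll (73 pd = 23 + 50), all config keys; open boll is absorbing and
halts both ageing and fibre accumulation. Abscission is a daily Bernoulli
trial with a piecewise-constant age-dependent probability (default: 0.005/d
below 10 pd, 0.010/d to 23 pd, 0.020/d for young bolls to 33 pd, 0.002/d
after) — a placeholder shaped to peak for young bolls, clearly
non-authoritative. Each fruit draws from its own seeded stream keyed by
(seed, plant, branch, node), so a fruit's fate is identical across
management scenarios sharing a seed; this makes scenario contrasts
deterministic comparisons rather than noisy ones.

Topping (main stem or all branches) deactivates the affected apices and
removes the top two phytomers per axis (fewer if fewer exist); unset fruits
(squares, flowers) on removed phytomers are discarded with them, while set
bolls are kept. Repeat topping is a no-op. The conservation invariant —
initiated fruits = alive-by-stage + abscised + removed — is asserted daily
in tests.

## Fibre quality

Potential quality per index is logistic in fruit age,
Q_i(t) = Q_max,i/(1 + e^(−K_i(t − t_m,i))), with the calibrated constants
(length 30.47 mm / 0.28 d⁻¹ / 33.78 pd; strength 30.94 cN tex⁻¹ / 0.23 /
39.97; micronaire 4.648 / 0.22 / 47.03). The realised daily increment is the
potential increment along the fruit's own age trajectory multiplied by the
index's temperature factors: length uses the daily-mean quadratic
(−0.0038·T̄² + 0.1904·T̄ − 1.3694); strength the daily-mean linear
(0.0198·T̄ + 0.4657, 1 above 30 °C) times the diurnal-range linear
(−0.0216·TD + 1.136); micronaire the minimum-temperature linear
(0.0244·Tmin + 0.3874, 1 above 25 °C). Cold days thus act twice: they slow
the age clock (smaller potential increment) and shrink the increment through
the factors.

All factors are clamped to [0, 1]. The length quadratic slightly exceeds 1
(1.016) at its 25.05 °C vertex; clamping keeps the "potential" ceiling
meaningful, and the unclamped values remain available (`clamp=False`) for
diagnostics. Note that all four factors are simultaneously 1 only in a
narrow band (T̄ ≈ 27 °C with Tmin > 25.1 °C and TD ≤ 6.3 °C), so even a hot
mid-summer day typically realises slightly less than the potential length
increment. The increment scheme is additive in age: splitting a day into two
half-effect steps at the same temperatures yields the identical total, which
the tests assert.

Accumulation runs from squaring and halts at boll opening or season end,
whichever comes first — harvest-time drying is not modelled. Abscised fruits
stop accumulating and are excluded from every aggregate. A single parameter
set is used for all cultivars (the calibration pooled two cultivars that
showed no difference); per-cultivar sets can be loaded from the YAML
`quality` block. Micronaire's decline with CPN is emergent (late fruits are
cold-limited during their thickening window); no positional correction is
applied.

## Scenarios and aggregation

Region presets encode practice anchors: Xinjiang (sow Apr 10, main topping
Jul 20, branch topping Aug 5, 18 plants m⁻², film mulch), Yellow River
(Apr 25 / Jul 30 / Aug 15, 6 m⁻²), Yangtze (Apr 10 / Aug 10 / Aug 25,
6 m⁻²). A scenario cell perturbs these by day offsets from the standard
menus (sowing −20…+30, main topping −10…+15, branch topping 0…+30, mulch
on/off) and runs a stand of plants per year on synthetic site weather (or
user-supplied series). Aggregates — means and SDs per index, per-CPN
profiles with 2×SE bars, and frequency histograms (5-unit bins for length
and strength, 0.75 for micronaire, open-ended at both extremes so counts are
conserved) — are computed over retained fruits only: abscised fruits have no
harvestable fibre and removed fruits leave the plant. Sweeps are fully
deterministic under a fixed seed.

Default problem sizes (6 plants per cell-year, a handful of synthetic years)
were chosen because per-fruit quality is tightly determined by weather and
position — between-plant variation enters only through abscission — so small
stands already give stable means.

## Calibration and evaluation

`calibration.fit_logistic` fits (Q_max, K, t_m) by bounded nonlinear least
squares (`scipy.optimize.curve_fit`, bounds Q_max ∈ (0, 2·max(y)),
K ∈ (0, 2), t_m ∈ (0, 120)) from three deterministic starting points,
keeping the best-SSR solution; standard errors come from the Jacobian-based
covariance, and R² and RMSE are reported against the observations. Constant
or under-determined (< 3 point) series are rejected.

Model evaluation uses RMSE = sqrt(mean((Y−X)²)) and a relative error
RE = 100·sqrt(mean(((Y−X)/X)²)); the squared (root-mean-square) form of RE
is the package's chosen reading of the statistic as conventionally used in
crop-model evaluation, with a mean-absolute variant behind `form="mean_abs"`.

## What the synthetic tests do and do not show

The synthetic weather reproduces seasonal thermal totals, a realistic annual
cycle and day-to-day noise; it does not reproduce heat waves, cold snaps,
within-season autocorrelation, or the 1981–2010 station records, and the
abscission and plastochron maps are placeholder calibrations. Passing tests
therefore demonstrate the model's internal consistency (invariants,
conservation, determinism), its analytic anchors (logistic asymptotes and
inflection ages, factor optima and saturations), and the emergent
qualitative directions — declining quality at high CPN, earlier main-stem
topping never lowering retained-fruit mean quality on a cold-autumn site —
not quantitative agreement with any field survey. The directional topping
result is itself condition-dependent: it requires topping late enough that
the marginal (prevented) fruits would have developed into the autumn cold;
with very early topping the marginal fruits mature fully and the contrast
flattens to neutrality.

## Degenerate inputs and tie-breaks

Weather files with inverted extremes, gaps, duplicates or no rows are
rejected with row numbers. Days at or below the base temperature advance
nothing but the calendar. Organ-appearance thresholds are compared with ≥,
so an exact threshold crossing fires the same day; a fruit appearing mid-day
starts with the fractional age accrued past its threshold and its first-day
quality increment covers exactly that fraction. Topping an axis with fewer
than two phytomers removes what exists. Histogram values outside the bin
range are collected into the first/last bin so totals are conserved.
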