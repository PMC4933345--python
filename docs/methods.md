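# Methods

## Problem setting

After intracoronary (IC) injection into a perfused heart, each donor cell is
either mechanically entrapped in the coronary microvasculature or flushed out
with the coronary effluent. In an ex-vivo Langendorff preparation the aortic
valve stays closed, so all injectate enters the coronaries and all
non-retained cells appear in the collected effluent. This closure property is
what makes effluent counting a direct retention assay, and it is the
conservation law the whole package is built on: `retained + exited =
injected`, exactly, in every simulated run.

## Effluent arm

Per minute *m* (minute 1 = [0, 60 s) from injection start, so the 20-s
injection lies wholly inside it):

* effluent cell number `E_m` = aggregate(concentration reads) × collected
  volume. The aggregate is the arithmetic mean of the ≥3 replicate counter
  reads (a median option exists for robustness but is not the default).
* total loss `E = Σ_{m=1..W} E_m` over the analysis window `W` (default
  5 minutes; essentially all washout is complete by then, and the simulated
  exit-time distribution puts < 10⁻⁸ of exits beyond it).
* retention `R = (N − E)/N × 100` for dose `N`.

Degenerate/edge policies: a negative retained count (counting noise making
`E > N`) is clamped to 0% with a logged warning, and the raw unclamped value
is always kept on the result object. Red-blood-cell background subtraction is
off by default (cells are injected only once carryover is negligible) but
available as a constant-rate subtraction floored at zero. The first-minute
washout fraction `E_1/E × 100` is reported as NaN (flagged missing, not an
exception) when `E = 0`.

Allometric dose conversion scales a single-artery clinical dose by body-mass
ratio; per-artery values are reported at 2 significant figures and the
all-artery total at 1 (raw values retained), matching how such doses are
quoted in practice.

## Size stratification

Diameter distributions come from an automated counter as counts per 1-µm
subdivision; bins are half-open `[d, d+1)` labelled by their integer lower
edge, so "5–6 µm" is bin 5. Per-bin retention compares the pre-injection
histogram (scaled to the injected dose) with the pooled effluent histogram on
identical edges. Conventions that matter for reproducibility:

* **Median**: interpolated within the bin containing the 50th percentile
  (`lower + (N/2 − cum_below)/count_in_bin`); a single-bin histogram has its
  median at the bin midpoint. The mean is the count-weighted midpoint mean.
* **Low support**: bins with < 100 injected cells are flagged and excluded
  from monotonicity diagnostics (cells ≥ 10 µm are < 1% of the mononuclear
  population, so their per-bin rates are noisy).
* **Pooling**: effluent size distributions are pooled over the 5-minute
  window rather than resolved per minute.
* Bins with zero injected cells yield NaN (missing), not an error; pooled
  tail retention (`≥ cutoff`) is computed from summed counts, never by
  averaging per-bin percentages.

## Stereology

Sections are 7.5-µm cryosections at three transverse levels (base /
papillary-muscle / apex). The whole-heart estimate is

```
retained = mean areal density (cells/mm²) / 0.0075 (mm) × heart mass (mg)
```

with tissue density fixed at 1 mg ≡ 1 mm³ (configurable). Sections are
equally weighted within a heart by default; area weighting (pooled counts /
pooled area) is available since the two differ when examined areas differ.
The transmural analysis divides the wall into three equal-thickness layers
(epicardial / mid-myocardial / endocardial — no published boundary definition
exists, so equal thirds is the package's choice), averages densities per
layer first across levels within each heart and then across hearts, and
reports the endocardial:epicardial ratio. A zero epicardial density flags the
ratio as undefined (NaN) rather than raising.

## Entrapment simulator

The generator encodes the passive-entrapment interpretation: retention is a
per-cell Bernoulli event whose probability depends only on diameter.

**Size model.** `ln d ~ N(ln median, σ²)`. Defaults: BMMNC median 7.0 µm,
σ = 0.14 — this keeps the mean at 7.07 µm (mean ≈ median, as observed) and
the ≥10 µm tail at ~0.5% (< 1%, as observed). MSC median 11.5 µm with σ
solved from `mean = median·exp(σ²/2) = 12.2`, giving σ ≈ 0.344. A lognormal
is an assumption; the real mononuclear distribution is only described as
left-skewed unimodal, which the lognormal reproduces qualitatively.

**Entrapment.** `p(d) = p_max·logistic(k(d − d50))` with d50 = 8.5 µm and
k = 1 µm⁻¹ — the minimal monotone saturating form, centred just above the
capillary calibre range (~5–7 µm) so that retention is < 10% at 5–6 µm and
plateaus near 9 µm. `p_max` is the only calibrated scalar: since
`E[p(d)] = p_max·E[logistic]`, calibration is the exact division
`p_max = target/E[logistic]` with the expectation computed by quadrature
(`E[logistic]` ≈ 0.230 for BMMNC giving p_max ≈ 0.874; ≈ 0.787 for MSC giving
p_max ≈ 0.985). Targets are the observed group means (0.201, 0.775). A
per-bin lookup table can override the logistic for non-parametric curves;
such a table cannot be p_max-calibrated.

**Washout.** Exit time = U(0, 20 s) + Exp(τ = 15 s): uniform position in the
injection bolus plus a memoryless single-pass transit. Closed form for the
fraction exited by time t ≥ D: `1 − (τ/D)·e^(−t/τ)(e^(D/τ) − 1)`, which at
60 s gives 96.2% — comfortably above the observed >90% first-minute washout
and used as the analytic oracle for the Monte-Carlo runs. The effluent series
extends past the 5-minute window if any straggler exits later, so ground
truth and pipeline can be compared exactly.

**Flow.** Baseline coronary flow defaults to 12 ml/min (typical for a
constant-pressure-perfused ~200 g-rat heart; only graphical values are
published). BMMNC mode: constant baseline. MSC mode: an immediate fractional
obstruction `0.8 × retained fraction` decaying exponentially with time
constant 3 min; minute volumes are time-averages over the minute. With the
calibrated MSC retention (~0.78) this gives minute-1 flow ≈ 0.47× baseline
(< ½) and ≥ 95% recovery by minute 10, matching the qualitative observations;
the two constants are the package's choice, as no quantitative flow model is
published. The 3-ml injection vehicle is added to the minute-1 collected
volume; the obstruction check is made on the coronary component (vehicle
excluded).

**Measurement noise.** Mean-preserving multiplicative lognormal noise per
replicate concentration read, CV 5%, 3 reads — the counter protocol specifies
only "at least 3 measurements", so the CV is a realistic instrument-level
choice. Setting CV = 0 makes the pipeline recover ground truth to float
precision.

**Histology generator.** Expected areal density = retained/mass × thickness;
per-level layer counts are Poisson around density × layer area with layer
densities proportional to the transmural weights (default 1:2:3 epi:mid:endo,
scaled to preserve the whole-section mean, so the endo:epi expectation ratio
is exactly 3). The whole-section count is the sum of its layer counts, never
an independent draw. `exact=True` records expectations without sampling, for
noiseless cross-arm equality checks. Default examined area is 60 mm² per
level (a plausible rat left-ventricular cross-section; measured areas are not
published).

**Markers.** Optionally, categorical surface-marker labels are assigned
independently of diameter (multinomial pre-injection, multivariate
hypergeometric subset for the effluent), so pre vs effluent marker fractions
are equal in expectation — the mechanism's "no biochemical selection"
signature. Off by default.

## What the simulator does and does not emulate

It reproduces: lognormal-like size distributions, size-dependent first-pass
entrapment, dose-invariant retention fractions, >90% first-minute washout,
triplicate counter noise, MSC flow obstruction with recovery, and
Poisson-sampled transmural section counts. It does **not** model: explicit
vascular-network geometry, cell deformability, cell-clump mechanics (MSC
clumping affects flow only, never retention probability — retention events
are independent given diameter), pulsatile flow, extravasation, or viability
dynamics. Tests passing against the simulator therefore validate the
*estimators* under the stated generative assumptions; they do not validate
those assumptions against new wet-lab data.

## Numerical choices and problem sizes

Quadrature for `E[p(d)]` uses adaptive integration over the central
1 − 2×10⁻¹² of the lognormal; a degenerate σ = 0 model short-circuits to
`p(median)`. Simulation is chunked at 2×10⁶ cells to bound memory; all
randomness flows through a single `numpy` Generator per run, seeded
explicitly (identical seed ⇒ bit-identical output). The test suite exercises
reduced doses (10⁴–2×10⁵ cells per heart) for speed; the acceptance pipeline
uses the study design itself — 8 hearts per arm at dose 10⁶, and the washout
analysis additionally at 8×10⁶ and 4×10⁷ — completing in well under a minute
on one CPU.

## Known limitations

* The logistic entrapment curve is identified only up to its calibrated
  mean; d50 and k are fixed by capillary-calibre reasoning, not fitted to
  per-bin data (published per-bin retention exists only graphically).
* Retention denominators use total injected cells; whether viable-only
  denominators were used originally is unstated (viability was > 94%, so the
  difference is ≤ ~6% relative).
* The stereology estimator assumes uniform sampling of the three levels and
  exact tissue density; section-level area variation is supported but the
  generator draws equal areas.
* SEM is reported as SD/√n across hearts; with n = 8 hearts the 3-SE
  acceptance bands are dominated by counter noise, not Bernoulli sampling.
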