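# icretention

Quantitative analysis of **initial donor-cell retention in the heart after
intracoronary (IC) injection**, built around an ex-vivo Langendorff-perfusion
design: every injected cell either lodges in the coronary microvasculature or
exits with the coronary effluent, so timed effluent cell counts measure
retention directly.

The package is for cell-therapy and perfusion-physiology researchers who need
to (a) reduce per-minute effluent counts to retention rates, (b) resolve
retention by cell diameter, (c) extrapolate whole-heart retention from thin
histology sections, and (d) validate all three estimators against a
mechanistic simulator of size-dependent microvascular entrapment with exact
ground truth.

## The model in brief

**Effluent arm.** For minute *m*, the effluent cell number is
`E_m = mean(concentration reads) × flow volume` (cells/min); the total loss is
`E = Σ_{m=1..5} E_m`, and the retention rate is

```
R (%) = (N_injected − E) / N_injected × 100
```

**Size stratification.** With pre-injection and effluent diameter histograms
on 1-µm bins, per-bin retention is `R_d = (I_d − E_d)/I_d × 100`, exposing the
size selectivity of entrapment.

**Stereology.** With labelled-cell areal densities `ρ` (cells/mm²) counted on
7.5-µm sections and tissue density 1 mg ≡ 1 mm³,

```
N_retained = ρ / 0.0075 × heart mass (mg),    R (%) = N_retained / N_injected × 100
```

**Simulator.** Diameters are lognormal (mononuclear cells, BMMNC: median
7.0 µm; mesenchymal stromal cells, MSC: median 11.5 µm, mean 12.2 µm). A cell
of diameter *d* is entrapped with probability
`p(d) = p_max / (1 + exp(−k·(d − d50)))` (d50 = 8.5 µm, k = 1 µm⁻¹), with
`p_max` calibrated analytically so that `E[p(d)]` matches the observed
group-mean retention (~20% BMMNC, ~78% MSC). Non-retained cells exit at
`U(0, 20 s) + Exp(τ = 15 s)`; counts per minute get triplicate lognormal
counter noise (CV 5%). MSC transiently obstruct coronary flow in proportion to
the retained fraction.

## Worked example

```python
from icretention.io import RunConfig
from icretention.report import run_report

doc = run_report(RunConfig(cell_type="BMMNC", dose=1_000_000, n_hearts=8, seed=1))
print(f"retention {doc['retention_pct_mean']:.1f} ± {doc['retention_pct_sem']:.1f}% (SEM)")
print(f"first-minute washout {doc['first_minute_pct_mean']:.1f}%")
print(f"histology estimate {doc['histology']['retention_pct_mean']:.1f}%")
print(f"endo:epi density ratio {doc['histology']['endo_epi_ratio']:.2f}")
```

prints (seed 1):

```
retention 19.7 ± 0.9% (SEM)
first-minute washout 96.2%
histology estimate 19.9%
endo:epi density ratio 3.28
```

That is: of 10⁶ injected mononuclear cells only ~20% remain in the heart at
5 minutes; ~96% of the cells that leave do so within the first minute; the
histology arm independently recovers the same retention; and retained cells
concentrate ~3× toward the endocardium.

The same pipeline runs from the shell:

```bash
icretention simulate --cell-type MSC --dose 1e6 --n-hearts 8 --seed 42 --out rundir/
icretention retention --effluent rundir/effluent.csv --window 5 --out report.csv
icretention histology --counts rundir/histology.csv --out histology.json
icretention report --cell-type BMMNC --dose 1e6 --n-hearts 8 --seed 1 --out summary.json
```

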