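# qams-hplc

Single-marker multi-component quantification (QAMS — *quantitative analysis
of multi-components by single marker*) for HPLC-DAD assays, built and
validated end-to-end on synthetic chromatograms with known ground truth.

Multi-component quality control of herbal preparations normally needs one
reference standard per analyte — expensive and sometimes impossible to
source. QAMS sidesteps that: a single cheap internal reference (here
**gallic acid**) is calibrated externally, and every other analyte
(matrine, oxymatrine, catechin, rutin, ferulic acid — the actives of a
Danggui Kushen-type preparation) is quantified through a pre-established
**relative correction factor**

```
f_s/k = (W_k · A_s) / (W_s · A_k)
```

(`s` reference, `k` analyte; `W` concentration, `A` peak area), measured by
the *multipoint* design — the same mixed standard injected at 3, 5, 10, 15
and 20 µL, so the injection volume cancels in the ratio. In a sample run
the analyte peaks are located without their own standards via the
**relative retention time** `Rt_R = t_Rk / t_Rs`, and contents follow from

```
W_k = f_s/k · W_s · A_k / A_s ,
```

compared against the conventional external-standard (ES) route through the
signed relative error `RE% = (ES − QAMS)/ES × 100`.

The package is aimed at analytical-method developers who want the whole
workflow — peak detection/integration, calibration with LOD/LOQ (S/N = 3
and 10), RCFs, relative-retention localization, and the validation battery
(precision, stability, repeatability, recovery, RCF robustness,
localization-method comparison) — as tested, composable functions.

## Layout

* `src/qams_hplc/` — the library: `chromsim` (EMG chromatogram generator),
  `peaks`, `calibration`, `qams`, `validation`, `study` (the end-to-end
  synthetic study), `tables` (published reference tables as fixtures),
  `cli`.
* `analysis/01…06_*.py` — numbered narrative drivers (simulate → detect →
  calibrate → RCF → quantify/compare → validate) writing tables under
  `results/`.
* `scripts/acceptance.py` — recomputes the headline numbers from scratch.

A `qams-hplc` console script exposes the same stages
(`simulate | peaks | calibrate | rcf | quantify | validate | compare | all`).

## Worked example

```
$ python analysis/04_relative_correction_factors.py --seed 1
     analyte  mean_recomputed  mean_printed  rsd_recomputed  rsd_printed
     matrine             3.80          3.80            1.17         1.17
  oxymatrine             3.03          3.03            1.65         1.65
    catechin             0.39          0.39            1.42         1.42
       rutin             2.31          2.31            0.66         0.66
ferulic_acid             2.38          2.38            0.91         0.91
published per-injection values reproduce the printed summary: YES

synthetic multipoint RCFs (injection volume cancels):
injection_volume_uL  matrine  oxymatrine  catechin  rutin  ferulic_acid
                  3     3.97        3.21      0.74   2.59          2.60
                  5     3.97        3.21      0.73   2.58          2.60
                 10     3.96        3.21      0.74   2.62          2.60
                 15     3.97        3.21      0.73   2.62          2.60
                 20     3.96        3.21      0.73   2.62          2.60
               Mean     3.97        3.21      0.73   2.61          2.60
               RSD%     0.03        0.03      0.28   0.74          0.03
```

The first table recomputes the published multipoint RCF summary from its
per-injection values — mean and (n−1) RSD agree with the printed rows at
2 d.p. for all five analytes. The second shows the same procedure on the
synthetic detector: RCFs are stable across a near-sevenfold change in
injection volume (RSD ≤ 0.74%), which is exactly the property the
multipoint design relies on. (Synthetic RCF levels differ from the
published ones because the simulated detector's response factors are
anchored to the published calibration slopes, not to the RCF table.)

Quantifying the five synthetic batches both ways
(`python analysis/05_content_comparison.py --seed 1`) ends with:

```
synthetic |RE%| between methods never exceeds 0.46 (agreement of the two routes)
published RE sweep: 25/25 cells reproduce at 2 d.p. (signs included)
```

— the single-marker route agrees with external calibration to well under
1% on simulation, and every published RE cell recomputes from its printed
ES/QAMS pair.

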