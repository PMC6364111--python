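# Methods

## The quantification model

One analyte — gallic acid — is the internal reference `s`, externally
calibrated on its own serial-dilution curve. Every other analyte `k` is
quantified through a relative correction factor

    f_s/k = (W_k · A_s) / (W_s · A_k)

established on standard solutions, where `W` is concentration (µg·mL⁻¹)
and `A` an integrated peak area (response·seconds). Because both areas in
the ratio scale identically with injection volume and detector gain, `f`
is estimated by the *multipoint* design: the same mixed standard injected
at 3, 5, 10, 15 and 20 µL, per-injection factors averaged, dispersion
reported as the sample (n−1) RSD. In a sample run the reference's
concentration comes from its calibration line (`X = (A − b)/a`), and each
analyte's from

    W_k = f_s/k · W_s · A_k / A_s .

Solid-sample contents are mass fractions, `(W · V_extract)/(m_sample·10⁶)
× 100` %, with a 5 g sample extracted into 10 mL. The two routes (ES =
each analyte on its own curve; QAMS = single marker) are compared through
the signed relative error `(ES − QAMS)/ES × 100`, reported at 2 d.p. with
half-up rounding (all reported 2 d.p. statistics use half-up rounding;
banker's rounding changes some tie cells).

Peaks of analytes that have no standard are identified by relative
retention `Rt_R = t_Rk / t_Rs` against the reference peak, matched
greedily by relative deviation within a 5% tolerance window, each peak
used at most once, ties broken to the earlier-eluting peak. The 5% default
leaves an ample margin over the sub-2% Rt_R dispersion observed across
simulated condition changes while staying far below the smallest
between-analyte Rt_R gap (~0.2 in relative terms). Unmatched targets are
reported absent, not as errors — that is precisely the negative-control
behaviour the specificity test relies on.

## The synthetic study

No raw chromatograms are published for assays of this kind, so the package
carries its own generator and the default study is fully synthetic with
known ground truth.

**Peak shape.** Exponentially modified Gaussian (the standard model for
tailing LC peaks), per-analyte width σ and tail constant τ in minutes;
τ = 0 degenerates to a Gaussian. The profile is re-centred so its *mode*
sits at the configured retention time, keeping apex bookkeeping honest for
tailed peaks. True area is `concentration × injection volume × response
factor` by construction, which is what makes parameter-recovery tests
exact.

**Detector.** Four channels (210/225/256/320 nm); each analyte responds on
its assigned channel (matrine/oxymatrine/catechin at 210, gallic acid at
225, rutin at 256, ferulic acid at 320). Response factors are anchored to
the published calibration slopes divided by the 5 µL calibration injection
volume, so simulated areas live on the published scale. Baseline drift
0.01 response·min⁻¹, i.i.d. Gaussian noise (s.d. 0.02 response units —
set so the smallest peaks sit in the printed LOD/LOQ neighbourhood),
retention jitter s.d. 0.01 min per run. Randomness is keyed by
`(seed, channel)`, so each channel is independently reproducible.

**Concentrations.** The printed stock labels and the printed linear ranges
disagree with each other; this package adopts the *range-consistent*
assignment — each analyte's stock is the value that makes the 0.1–3 mL
into 5 mL dilution scheme span that analyte's own published linear range
(matrine 1191.8, gallic acid 44.4, oxymatrine 11552.6, catechin 5.7,
rutin 17.3, ferulic acid 548.2 µg·mL⁻¹; the ferulic value is implied by
its range). Under this labelling every batch content in the published
comparison table also falls inside its analyte's linear range, which the
as-printed labelling does not achieve; the fixture table records both
labelings. The working mixed standard is a 0.5 mL / 5 mL dilution of the
stocks. Ground-truth batch compositions are the published ES mass
fractions, converted to extract concentrations via the 5 g / 10 mL scheme
— the synthetic study therefore operates in the assay's real
concentration regime.

**Elution program.** Retention times are free design parameters (the
published gradient table is not linked to retention anywhere): gallic acid
6.8 min, matrine 8.2, oxymatrine 11.4, catechin 15.6, rutin 27.5, ferulic
acid 33.9 on a 53-min run sampled at 5 Hz, with widths growing with
retention (σ 0.05→0.13 min, τ ≈ 0.3σ). These choices give plate numbers
well above 3000 and resolutions far beyond 1.5, matching the system-
suitability regime the method requires.

## Peak processing

Detection uses `scipy.signal.find_peaks` with a prominence floor of
`min_snr × noise` (noise = n−1 s.d. of the linearly detrended first
0.5 min, a peak-free window; detrending makes the estimate drift-immune).
A peak's height criterion is applied against its *local chord baseline* —
prominence alone can be inflated by distant minima over a 53-min trace.
Integration bounds are derived from the measured half-height width
(apex −2.1/+2.9 × w½ ≈ ±5σ with extra room for the tail), clipped at the
valley between neighbouring apexes; the baseline is a straight chord whose
endpoint levels are averaged over ≤0.1 min just outside the bounds
(single-sample endpoints would inject `noise × span` worth of area error
into small broad peaks). Areas are converted to response·seconds; negative
net areas are clipped to zero with a warning. Plate numbers use the
half-height (5.54) formula; resolution converts half-height to base widths
by the Gaussian factor 1.699. Overlapping-peak deconvolution is out of
scope — the study's peaks are baseline-resolved by design.

## Calibration and limits

Unweighted OLS of area on concentration (≥3 distinct levels), `r` the
Pearson correlation. LOD/LOQ follow the S/N = 3 / S/N = 10 convention:
`3·noise/(height per unit concentration)` and `10·noise/(…)`, the height
factor measured on the lowest standard, so LOQ/LOD = 10/3 identically.
Out-of-range ES predictions warn but are returned — sample contents
legitimately sit near range edges.

## Validation battery and its condition model

Precision/stability/repeatability are six-replicate RSDs (thresholds
default to 2%); stability supports an optional linear degradation term
(default 0 — the published solution was stable over 24 h). Recovery spikes
each analyte at ~100% of the batch's own content (the printed spike
amounts are internally inconsistent, so the study uses a self-consistent
design); with no loss mechanism in the generator, mean recovery is ~100%
by construction, and the test verifies the pipeline does not *introduce*
bias. RCF robustness varies one axis at a time — two instruments, three
columns, three flow rates, three temperatures. Condition changes act on
retention (scale for flow/temperature/column, offset for instrument) and
on response as a **common-mode gain shift (1% s.d.) plus a small
per-analyte differential term (0.2% s.d.)**: gain, injection-volume and
lamp effects move all channels together and cancel in the RCF ratio, which
is the premise of the whole design. Per-condition RCFs use the same
multipoint multi-volume procedure as the primary estimate. The default
pass threshold (2.27%) mirrors the dispersion a validated assay of this
kind achieves. The same condition grid feeds the localization comparison:
per-analyte RSD of `t_Rk − t_Rs` versus `t_Rk / t_Rs` across conditions —
flow-rate changes rescale the clock (ratio immune, difference not), and
instrument offsets do the reverse; under the mixed drift the ratio method
wins for every analyte, which is why it is the default locator.

## What the synthetic study does and does not show

Passing tests demonstrate internal consistency: the algebra of the
single-marker route, volume cancellation, localization robustness, and
that the processing chain recovers known truth within ~0.5% under
realistic noise. The generator does *not* model detector saturation,
gradient-dependent baseline structure, co-eluting matrix interferents,
cross-channel spectral overlap, or extraction losses — so agreement here
does not by itself establish accuracy on real extracts; it establishes
that the computational method is sound and that any bench discrepancy is
chemistry, not arithmetic.

## Problem sizes and numerics

The default study uses 6 calibration levels, 5 injection volumes, 5
batches, 6 validation replicates and an 11-condition robustness grid —
roughly 300 simulated 53-min traces (15 901 samples each); the full
pipeline runs in a few seconds on one CPU, and Monte-Carlo style tests use
10–50 seeds. Degenerate inputs fail loudly: zero/negative concentrations,
areas or times raise with the offending symbol named; a flat trace yields
zero peaks (not an error); a constant-concentration series is rejected as
rank-deficient; a noiseless window makes S/N undefined and raises. Child
seeds for every stage derive from the master seed via SHA-256 (31-bit),
so stages are individually reproducible and mutually independent.
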