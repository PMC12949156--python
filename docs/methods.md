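# Methods

This note documents the models, estimators, and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
design decisions taken where the procedure was genuinely open.

## Stimuli

All levels are overall RMS levels in dB SPL re 20 µPa; `scale_to_spl` rescales
a synthesized waveform so its RMS pressure equals 20 µPa·10^(level/20), and
every synthesizer applies it last, so SAM and RAM stimuli at the same nominal
level carry identical energy (the sparse RAM envelope then has the higher
peak pressure). Default synthesis rate is 100 kHz, covering carriers up to
32 kHz with margin.

**SAM** envelopes are `1 + depth·sin(2π·fm·t)`. **RAM** envelopes are zero
for `1 − duty_cycle` of each modulation period and full-scale for
`duty_cycle` of it (default 0.25), with raised-cosine tapers at each on/off
edge. The taper span is defined as `edge_fraction` (default 0.025) of the
*full modulation period* and sits inside the on-portion; the original
rectangular-envelope stimulus literature specifies a "2.5% Tukey window"
without stating the span's base, so this convention is a documented choice —
it leaves the above-half-maximum fraction at `duty_cycle − edge_fraction`
(0.225 by default). **Tone pips** use cosine-squared rise/fall ramps
(default 0.5 ms) around a steady state (4 ms for the default 5 ms pip).

For SAM/RAM, `fm · duration` must be an integer so the modulation frequency
and its harmonics land exactly on DFT bins of the analysis epoch; this is
enforced at spec construction.

Interleaved trains present every frequency × level pair once per cycle with
frequencies rotating fastest (ascending within a level step, levels ascending
across steps). The effective rate per frequency is `overall_rate /
n_frequencies` (81/s over 7 frequencies → 11.6/s); the exact ordering within
the contract (consecutive stimuli differ in frequency) does not affect any
downstream metric.

## EFR estimation

Trials (equal counts per stimulus polarity) are resampled by a **balanced
bootstrap**: each of 100 draws samples `draw_size/2` trials with replacement
from each polarity (default 64 + 64 from a 128-trial set), averages the
waveforms, and computes the single-sided DFT amplitude spectrum of the
average. Multiplicities are drawn multinomially, which is equivalent to
independent sampling with replacement and lets the draw averages be formed as
one matrix product. Polarity balance cancels components that invert with
stimulus polarity (stimulus artifact, cochlear microphonic).

Numerical conventions: the full epoch is analysed with no window
(rectangular), so on-bin components are exact and the bin spacing for the
500 ms epoch is 2 Hz; amplitudes are single-sided spectral amplitudes in µV
(a sinusoid of amplitude A yields A at its bin) and the dB reference is 1 µV.
The SNR metrics are reference-free, so comparisons between measures are
unaffected by the amplitude convention. The noise floor around each harmonic
is the arithmetic mean of the 4th–7th bins on either side (exactly 8 bins).
The estimate of record for every amplitude quantity is the mean over draws;
per-draw distributions are retained for dispersion.

Metrics on the across-draw mean amplitudes f₀..f₄ and noise floors n₀..n₄:
`f0 = 20·log10(f₀)`, `f0_4 = 20·log10(Σfᵢ)`, `f0_snr = 20·log10(f₀/n₀)`,
`f0_4_snr = 20·log10(Σ fᵢ/nᵢ)`, and the power-sum variant
`f0_4_power = 10·log10(Σfᵢ²)`. SNR metrics raise on a zero noise floor
(degenerate noiseless input) rather than returning infinity.

**PLV.** The phase-locking value has no universally fixed estimator in this
setting; this package computes, for each bootstrap draw, the magnitude of the
multiplicity-weighted mean unit phasor of the *sampled trials'* f₀ phases,
and reports the mean over draws. Identical trials give 1; phase-incoherent
noise gives ≈ 1/√n_trials. An across-draw alternative (|mean phasor| of the
draw-average phase) was rejected as the primary definition because bootstrap
draws share the underlying trials: their average phases remain coherent even
for pure noise, biasing that statistic toward ~0.6 rather than toward 0. The
across-draw form is retained as a fallback for spectra built without
per-trial phases.

## ABR and DPOAE summaries

Averaged ABR traces are band-passed 300–3000 Hz with a zero-phase
(forward-backward) 2nd-order Butterworth cascade. Wave 1 is the first
prominent positive peak in the search window; its amplitude is
peak-to-following-trough by default (baseline-to-peak available). The
threshold criterion — the lowest level whose amplitude exceeds `k × noise`
(default k = 3) with all higher levels also exceeding it — is a deliberately
simple stand-in for published threshold algorithms, used for synthetic
validation and the all-levels slope; it is not a re-implementation of those
tools. Growth slopes are OLS slopes of amplitude against level over the top
two levels (75, 80 dB SPL), top four (65–80), or all collected levels; the
all-levels variant includes sub-threshold levels by default (a flag restricts
to supra-threshold levels, since published descriptions are ambiguous on
this point).

DPOAE thresholds are the L2 of the lowest upward crossing of 0 dB SPL on the
input–output function, linearly interpolated in dB–dB coordinates (a "step"
read-out is available for sensitivity checks); an I/O function that never
reaches 0 dB SPL yields "not reached", which propagates into modelling as a
missing covariate handled by complete-case filtering. Emission levels at
L2 = 40 and 55 dB SPL are read directly. L1 = L2 + 10 dB and f2/f1 = 1.2 are
carried as provenance.

## Correlation screening

Pearson r with two-sided Fisher-transform intervals
`tanh(atanh r ± z·(n−3)^(−1/2))`, at the Bonferroni-corrected confidence
level `(1 − (1 − c/100)/n_comparisons)·100` (z from the standard-normal
quantile at the corrected level). Significance is "the corrected interval
excludes zero"; no p-values are reported. Pairs with fewer than four complete
observations are reported as missing rather than failing the screen; |r| = 1
is flagged degenerate.

## Prediction models and cross-validation

Models are OLS fits of synapses/IHC on evoked-measure columns, an optional
DPOAE covariate, and an optional female-sex indicator, pooling 16 and 32 kHz
rows with no frequency term. Predictors are used on their native scales
(prediction is scale-invariant for OLS). Each model is fit on its own
complete-case rows; rank deficiency raises an error naming the collinear
columns. The intercept-only model predicts the sample mean and anchors the
error scale; DPOAE-only models anchor what OHC collinearity alone achieves.

Cross-validation first sets aside all rows of the acute-noise group as an
independent test set, then partitions the remaining **ears** (not rows) into
10 folds, shuffling ears before each of 10 repeats; both rows of an ear stay
in one fold, so training and validation are independent at the ear level.
Fold sizes differ by at most one ear. Each trained fold model is scored by
RMSE on its validation fold and on the full acute-noise set; means and SEMs
pool all repeats × folds. Pooling ignores between-repeat correlation and so
understates the SEM slightly — the same convention the summary statistics
are defined with. Folds are not stratified by group (ears are shuffled
uniformly). Identical seeds give identical partitions and bit-identical
results; paired fold assignments are detected when computing ΔRMSE against a
reference model family matched on DPOAE adjustment, in which case the SEM of
the difference is computed pairwise.

## AICc ranking

AICc = 2k − 2·loglik + 2k(k+1)/(n−k−1), with the Gaussian maximum-likelihood
log-likelihood (σ̂² = SSR/n) and k counting the intercept, every slope, and
the residual-variance parameter — the standard Gaussian-AICc convention; the
source procedure does not state its parameter-counting convention, so
absolute AICc values may differ from published tables by a constant per
model-size class, while ΔAICc comparisons within this package are internally
consistent. Because AICc is only comparable on identical observations, every
row incomplete in *any* column used by *any* grid model is dropped first;
rankings are computed for all ears and separately excluding the acute-noise
group. Tiers follow the conventional reading: ΔAICc ≤ 2 comparable, 2–10
ambiguous, > 10 a clear preference.

## Synthetic cohort generator

The generator encodes the *statistical structure* the analysis assumes — it
is not a biophysical cochlear model. Defaults define the study conditions:

- **Groups**: young 17, acute noise 13, aged 14, aged + noise 13 ears
  (57 total; sexes fixed at 32 F / 25 M with zero effect by default).
- **Ground truth**: baseline synapses/IHC 15.0 at 16 kHz and 12.5 at 32 kHz
  (the synaptogram peaks mid-cochlea at ~15/IHC and declines basally); mean
  fractional loss by group × frequency — acute 2%/50% (focal), aged 30%/35%,
  aged + noise 45%/50% (broad) — with per-ear lognormal spread (CV 0.18).
- **OHC loss**: per-group means (SD) 3 (2), 12 (6), 22 (8), 32 (9) dB, plus
  5 dB extra at 32 kHz for non-young groups; truncated at 0. Because OHC
  loss is group-correlated with synapse loss, DPOAE covariates are
  predictive of synapses without measuring them (the collinearity the
  correlation screens exhibit).
- **Linear link**: expected evoked amplitude = gain × synapse drive ×
  10^((−s·OHC + nuisance)/20), with per-measure gain (µV per synapse/IHC),
  OHC sensitivity s (dB/dB): ABR 0.10, SAM 0.60/0.50 (110/1000 Hz), RAM
  0.35/0.20 — RAM below SAM encodes the premise that the sharp RAM envelope
  is less vulnerable to OHC dysfunction — and per-ear Gaussian nuisance
  factors (dB SD 1.2–2.5) representing electrode placement, arousal, and
  head geometry.
- **Tonotopic integration**: the synapse drive probed at frequency f is
  `ρ·syn(f) + (1−ρ)·mean_f' syn(f')` with place specificity ρ = 0.65 for ABR
  and 0.25 for the 70-dB-SPL EFRs. This is the mechanism by which focal
  32 kHz loss leaves EFR magnitudes near-normal (off-frequency regions carry
  the response) while ABR partially registers it — hence all models
  overpredict the acute ears' 32 kHz synapses and the ABR model degrades
  least on that test set.
- **EFR trials**: response components at the envelope harmonics f₀..f₄
  (relative weights 1, 0.06, 0.025, 0.01, 0.004 for SAM — energy
  concentrated at f₀ with small rectification harmonics — and 1, 0.72, 0.45,
  0.28, 0.15 for RAM), white trial noise (30 µV SD), and a 5 µV stimulus
  artifact at the carrier that inverts with polarity. 128 trials (64 per
  polarity, alternating) of 500 ms at 65536 Hz, placing 110 and 1000 Hz and
  the 16/32 kHz carriers exactly on 2-Hz bins.
- **ABR growth**: wave-1 amplitude is a logistic function of level with
  midpoint 20 dB SPL + OHC loss and width 12 dB, scaled by the synapse
  drive, plus 0.05 µV noise. A saturating-growth form is a generator choice;
  no specific functional form is claimed by the source procedure.
- **DPOAE I/O**: emission level = 0.6·(L2 − threshold) dB with threshold =
  25 dB SPL + OHC loss and 1 dB noise (linear-compressive in dB–dB
  coordinates; threshold recovery is exact in the noiseless limit).
- **Missingness**: 35% of ears lack the 1-kHz-modulated EFR measures at
  32 kHz, exercising complete-case filtering.

Two generation paths share this link structure. The **trial-level** path
synthesizes waveform matrices and runs the full bootstrap estimator; it is
the default for the pipeline and the acceptance script (≈2 minutes for the
default cohort's 456 trial sets on one core). The **measure-level** path
("fast") draws EFR measures directly from the matched sampling distribution
of the trial-level estimator: harmonic estimates are |a + ε| with complex
Gaussian ε of per-component SD σ·√(2/(N·n_trials)), and noise-floor
estimates are Rayleigh means at √2 times that scale (per-draw bins carry
twice the grand-average noise variance because resampling adds one unit of
sampling variance). A cross-mode test verifies the two paths agree within
estimation noise. The fast path slightly understates the upward Rice bias of
near-floor harmonics; at default signal levels this is negligible for f₀
metrics. Cohort-scale statistical checks (e.g. the ten-seed ordering tests)
use the fast path; per-ear and cross-mode tests exercise the trial path.

**What passing tests do and do not show.** The generator plants linear links,
Gaussian nuisance, and a two-point tonotopic map; real EFRs have
non-Gaussian noise, level-dependent growth, frequency-specific generators,
and continuous tonotopy. Tests on this cohort validate the *machinery*
(estimators, CV contracts, selection arithmetic) and the qualitative
orderings that follow from the encoded premises (RAM-1 kHz best for broad
loss; ABR best, but degraded, for focal loss; DPOAE adjustment helping SAM
most). They do not validate those premises against real ears, and the
absolute RMSE/ΔAICc values depend on generator settings, not on any real
dataset.

## Workflow

Pipeline stages communicate only through tidy CSVs in the run directory and
a JSON manifest carrying the seed and a configuration hash (the hash covers
the scientific configuration, not the output path or log level). Trial
matrices are regenerated deterministically from per-ear seeds inside the
EFR-extraction stage rather than persisted (a full cohort of float32 trial
matrices is ~7 GB); a JSON-header + float32 container is available for
saving individual trial sets. `--resume` skips stages whose outputs exist.
The default model grid is the 6 × 4 cross of evoked options (none, ABR-80,
SAM-110, SAM-1000, RAM-110, RAM-1000 at the f₀ metric) with OHC adjustments
(none, DPOAE threshold, DPOAE-40, DPOAE-55); EFR metric variants and
multi-measure models are available through `ModelSpec` directly.

## Known limitations

- The wave-1 picker and threshold rule are simple documented procedures, not
  re-implementations of the semi-automated tools used on real recordings.
- The SEM convention pools repeats × folds without between-repeat
  correction and therefore understates uncertainty.
- AICc parameter counting includes the residual variance; comparisons with
  tables produced under another convention require matching it.
- The generator's two-frequency tonotopy makes "off-frequency" integration a
  single mixing weight; it cannot represent lesion edges or graded spread.
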