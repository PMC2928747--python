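# Methods

This note records the models behind `songshare`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions that matter when interpreting results.

## Repertoires and the similarity coefficient

A repertoire is a **set of types**, not a multiset of tokens: the syllable
repertoire is the set of distinct syllable labels an individual produced
across its analysed songs, and the sequence repertoire pools the distinct
contiguous *n*-grams for every *n* from 3 to 10 into one set. Windows slide
with stride 1 and never cross song boundaries (songs are independent
recordings). Pooling all *n* into a single set — rather than averaging per-*n*
coefficients — yields one sharing value per pair, which is what the
category-level summaries need.

The similarity coefficient RS = Z/((X+Y)−Z) is algebraically the Jaccard
index |A∩B|/|A∪B|; the package computes it from the set sizes and asserts the
identity against direct set operations in its tests. RS of two empty
repertoires is 0/0 and is refused with an error rather than silently mapped
to 0 or 1. Exact matching is used for sequences; there is no fuzzy or
variant-tolerant matching.

Field practice samples a fixed duration of song per male before labelling
(the package's transcripts carry whole songs); the repertoire functions
operate on whatever transcripts they are given, so a sampling window is a
property of the input, not of the algorithm.

## Permutation tests

*Paired test.* The null swaps the two values within each pair independently,
equivalently sign-flips the differences; the statistic is the mean within-pair
difference. All 2ⁿ assignments are enumerated whenever 2ⁿ ≤ 2²⁰ (so every
realistic study size, e.g. 7 or 17 pairs, is exact); otherwise `n_perm`
random sign vectors are drawn. Default `n_perm` is 10,000.

*Permuted correlation.* Observed statistic is the Bravais–Pearson r;
the null permutes one vector against the other. For paired vectors of
distances/similarities this is the vector form of a Mantel test. Default
1,000 permutations; exhaustive over all n! orderings when n! ≤ 2²⁰ (n ≤ 9).

Conventions, fixed across both tests: two-tailed significance through the
absolute statistic (the nulls are symmetric; doubling a one-tailed p can
exceed 1); ties count as extreme (≥, conservative); Monte-Carlo p uses the
add-one correction (b+1)/(m+1) so p > 0; exhaustive p is b/m with the
identity permutation included. Extremeness comparisons use a relative 1e-12
tolerance so that algebraically tied statistics computed in floating point
still count as ties.

No multiple-testing correction is applied anywhere; the pairwise treatment
comparisons report raw permutation p-values.

## Propagation channel and degradation analysis

The channel applies, in the frequency domain, spherical spreading
(gain = reference_distance/distance) plus an excess attenuation of
`excess_attenuation` dB per 100 m of excess path per kHz, then adds white
Gaussian noise of RMS `noise_floor`. Defaults: reference distance 1.56 m
(the control-microphone distance of the emulated field design), excess
attenuation 1 dB/100 m/kHz (a mid-range value for open grassland at song
frequencies), noise floor 5·10⁻⁴ on the unit-amplitude scale — chosen once so
that the synthetic signal is clearly decodable at 12.5–100 m, marginal near
200 m and lost past ~400 m, the qualitative active-space structure of an
open-field transmission experiment. Reverberation, wind and temperature
gradients are not modelled; degradation is therefore smoother and more
monotone in distance than real terrain produces.

Analysis: recordings are band-passed 1.6–7 kHz (zero-phase Butterworth,
order 5 run forward–backward, > 40 dB one octave out of band; the song band
of the emulated species, and the published high-pass edge of 1600 Hz). The
envelope is the smoothed magnitude of the analytic signal decimated to
1 kHz; the spectrum is a Welch-averaged magnitude spectrum (nfft 1024);
spectrogram cross-correlation uses Hann-windowed magnitude spectrograms
(nfft 256, hop 128 — the hop is a package choice; the frame settings follow
standard spectrographic cross-correlation practice) and scans integer-frame
lags within ±`max_lag` (default 0.5 s). Envelopes are aligned at their
cross-correlation best lag before computing r; without alignment r would
measure recorder timing rather than degradation. Correlations are scale-free,
matching the field protocol of RMS-equalizing stimuli.

Per (height, distance) cell, r is averaged over exemplars (averaging the
measures, not the features). A cell is flagged unusable, with r = NaN, when
the median envelope dynamic range (95th vs 10th percentile of the smoothed
envelope, a proxy for signal-above-background) falls below 3 dB — stationary
noise scores ≈ 0–1 dB on this measure, song well above 10 dB.

## Playback-response analysis

PCA is an eigen-decomposition of the 4×4 correlation matrix of the
standardized measures, pooled across all rows (pooling is required for scores
comparable across treatments). Component signs are fixed so the
largest-|loading| measure loads positively. Kaiser retention is strict
(eigenvalue > 1), with a 10⁻⁹ epsilon so an eigenvalue equal to 1 up to
round-off is not retained. Variance shares are eigenvalue/4 × 100.

The omnibus treatment test is a REML mixed linear model
`score ~ group + treatment + order + treatment:order` with a random subject
intercept. Factors use sum-to-zero contrasts so each Wald test is marginal
(Type-III-like) despite the interaction term. Pairwise comparisons use the
package's paired permutation test on the within-subject score differences —
assumption-light and consistent with the statistics core — rather than a
parametric studentized-range procedure.

The distance model regresses scores of the neighbour rows on singer distance
with a random intercept per song treatment (REML). With only two treatment
groups the random-effect variance often sits on the boundary; when the mixed
fit returns a non-finite standard error (or fails outright, e.g. on
noiseless scores) the model collapses to the fixed-effects OLS fit, which is
the same slope estimator. A Shapiro–Wilk p on residuals is reported as the
normality diagnostic.

## Synthetic study conditions

Defaults plant the structure the analysis assumes, at the emulated study's
scale: 2 groups (the field study's two neighbourhoods), 7 individuals per
group (its song-analysis sample), shared pool g = 40, private pool p = 10
(within-group syllable RS = 40/60 ≈ 0.67, a high-sharing microdialect
neighbourhood), dialect sequence of 7 syllables (the worked field example),
3 songs of 60 syllables per male, group spacing 5.8 km and territory spacing
130 m (the published inter-group and adjacent-neighbour distances), playback
tables with 17 subjects × 3 treatments and durations inside the 180-s scoring
window, and latency loaded opposite to the three duration measures.

Two generator choices deserve explanation:

- **Pool sampling.** In the default `deterministic` mode the filler syllables
  of an individual's songs start from one full permutation of its pool, so
  every male expresses its entire repertoire and the within-group RS equals
  g/(g+2p) *exactly* — pure i.i.d. sampling would only approach this with
  high probability, and an analytic value is worth more for validation than
  marginal i.i.d. purity. The `random` mode (used by the end-to-end pipeline)
  drops the guarantee so expressed repertoires, and hence RS values, vary
  between pairs as they do in real data.
- **Dialect placement.** The dialect sequence is inserted verbatim once per
  song at a uniform random position; everything else is uniform over the
  individual's pool. Real songs have syntax (transition structure, repetition
  avoidance); none is modelled, so passing tests validate set/sequence
  counting and the statistics, not linguistic realism.

The audio generator produces linear FM chirps (2–6.5 kHz, 0.1 s, raised-
cosine envelope) with 20 ms gaps — spectrally confined to the 1.6–7 kHz
analysis band but far simpler than real syllables; it exists to exercise the
signal chain, not to fool a bioacoustician. The response generator is a
single-latent-factor model (treatment effect + subject intercept + unit
residual, measures = baseline + scale·loading·latent + noise, clipped to
[0, 180] s); real response measures need not be one-factor, so the PCA sign
and dominance checks validate the pipeline's algebra under the model, not the
dimensionality of real behaviour.

Territory maps place group centres 5.8 km apart on one parallel and members
on a jittered grid; distances use the haversine formula on a sphere of radius
6,371,000 m (the conventional mean Earth radius; the choice matters at the
10⁻³ relative level at most).

All generators are bit-reproducible given their seed; sub-seeds are derived
with `numpy.random.SeedSequence`-style composition `[seed, k]` so stages are
independent but jointly deterministic.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single-CPU run: 1,000 random pairs for the Jaccard identity, 200 random
transcripts for *n*-gram counting, 5,000 replicates for the type-I rates
(binomial SE ≈ 0.003 at α = 0.05), 20 channel seeds per distance for the
degradation profile, and 200–250 replicates for the power/α estimates
(binomial SE ≈ 0.014–0.015). These sizes make the 3-SE acceptance bands
meaningful without over-resolving quantities the bands do not need.

## Known limitations

- Syllable labels are taken as ground truth; there is no acoustic
  classification of syllables from audio (real studies label spectrograms).
- Sequence matching is exact; a single substituted syllable breaks sharing.
- The channel has no reverberation or directionality, and height is carried
  as metadata only (real transmission differs strongly between 0.1 m and 2 m
  microphones; the synthetic channel does not reproduce that).
- The mixed models inherit statsmodels' small-sample behaviour: Wald tests
  are asymptotic, not the finite-sample F tests some field software reports.
- The unusable-cell flag is a heuristic on envelope dynamic range; it is
  meant to catch all-noise cells, not to estimate active space.
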