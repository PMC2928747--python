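# songshare

Analysis toolkit for studies of **vocal group signatures and the dear-enemy
effect in territorial songbirds** — species (such as the skylark, *Alauda
arvensis*) in which the males of a neighbourhood share syllables and
multi-syllable sequences ("microdialects"), and in which a territory owner's
aggression toward a played-back song depends on whether that song carries the
local group signature.

It is written for behavioural ecologists and bioacousticians who have

- syllable-labelled song transcripts (who sang which syllable in which order),
- territory GPS coordinates,
- propagation re-recordings of a broadcast signal at increasing distances, and
- playback-response scores (movement/latency measures per subject × treatment),

and who want the full chain of computations such a study needs, plus a
synthetic-data generator that plants known ground truth for validating every
step.

## What it computes

**Repertoire similarity.** An individual's syllable repertoire is the set of
distinct syllable types it produces; its sequence repertoire is the set of
distinct contiguous syllable *n*-grams with *n* ∈ [3, 10]. Sharing between
males *x* and *y* is the repertoire-similarity coefficient

```
RS = Z / ((X + Y) − Z)
```

with *X*, *Y* the two repertoire sizes and *Z* the shared count — algebraically
the Jaccard index, ranging from 0 (nothing shared) to 1 (identical
repertoires).

**Permutation statistics.** Two-tailed exact paired permutation tests
(sign-flipping within-pair differences; exhaustive over all 2ⁿ assignments for
small *n*, Monte Carlo otherwise) and a permuted Pearson-correlation test
(the vector equivalent of a Mantel test) for RS-versus-distance questions —
the resampling tests appropriate when each individual enters several pairwise
comparisons.

**Transmission degradation.** Envelope, averaged-spectrum and spectrogram
cross-correlation of propagated re-recordings against a close-range control,
averaged over exemplars into a feature × microphone-height × distance table,
with cells flagged unusable when the signal is indistinguishable from
background noise. A parametric channel (spherical spreading + frequency-
dependent excess attenuation + additive noise) emulates open-field
propagation.

**Playback responses.** Correlation-matrix PCA of the four response measures
(movement duration near the loudspeaker, time near the loudspeaker, total
movement duration, latency to move) with Kaiser retention (eigenvalue > 1);
treatment effects on the composite scores via a mixed linear model
(group + treatment + order + treatment×order, random subject intercept) and
pairwise paired permutation tests; singer-distance effects via a REML mixed
model with a random intercept per treatment.

**Synthetic ground truth.** `songshare.songsynth` generates neighbourhoods
whose groups share a syllable pool of size *g* plus *p* private syllables per
male and carry a planted dialect sequence in every song (within-group syllable
RS is analytically *g*/(*g* + 2*p*)); territory maps on the sphere
(haversine distances); frequency-modulated song audio at 48 kHz; propagated
versions of it; and response tables driven by a latent aggression factor.

## Worked example

```python
from songshare import (NeighborhoodSpec, generate_neighborhood,
                       repertoires_from_transcripts, category_rs_table,
                       category_summary, paired_permutation_test)

spec = NeighborhoodSpec(n_groups=2, individuals_per_group=7, seed=1)
transcripts, territories = generate_neighborhood(spec)
syll = repertoires_from_transcripts(transcripts, "syllable")

partners = {f"g0i{i}": {"aN": f"g0i{(i+1) % 7}", "dN": f"g0i{(i+3) % 7}",
                        "S": f"g1i{i}"} for i in range(7)}
table = category_rs_table(sorted(partners), partners, syll)
print(category_summary(table).to_string(index=False))

wide = table.pivot(index="focal_id", columns="category", values="RS")
res = paired_permutation_test(wide[["aN", "S"]].to_numpy(), seed=1)
print(f"aN vs S: observed mean difference = {res.observed_stat:.3f}, "
      f"p = {res.p_two_tailed:.4f} ({res.mode}, {res.n_perm} permutations)")
```

prints

```
    kind category     mean  n  se
syllable        S 0.000000  7 0.0
syllable       aN 0.666667  7 0.0
syllable       dN 0.666667  7 0.0
aN vs S: observed mean difference = 0.667, p = 0.0156 (exhaustive, 128 permutations)
```

Each of the 7 focal males shares RS = 40/60 ≈ 0.667 of its syllable
repertoire with its adjacent (aN) and distant (dN) neighbours — the analytic
value for a shared pool of 40 and private pools of 10 — and nothing with
strangers (S) from the other group. The paired permutation test on the 7
aN-versus-S differences enumerates all 2⁷ = 128 sign assignments and finds
the observed mean difference of 0.667 tied with one other assignment, giving
the smallest attainable two-tailed p of 2/128 ≈ 0.016.

A full end-to-end run (simulation → repertoires → permutation tests →
propagation degradation → playback PCA) is one command:

```
songshare run --seed 1 --out out/
```

which writes transcripts, territory and RS tables, permutation-test JSON, the
degradation table, the PCA report and a run record with per-file checksums
(two runs with the same seed are byte-identical).

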