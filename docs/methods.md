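# Methods

## Text normalization

All matching operates on a canonical form of the article text: lowercase,
canonical (NFD) decomposition with combining diacritical marks removed,
curly single/double quotes (U+2018–201B, U+201C–201F) mapped to ASCII
apostrophe/quote, en/em dashes and the minus sign (U+2013, U+2014, U+2212)
mapped to `-`, and every whitespace run (including newlines and
non-breaking spaces) collapsed to one space. The multiplication sign
U+00D7 is preserved because the P-value grammar needs it for scientific
notation. The function is total and idempotent (property-tested on fuzzed
Unicode). De-hyphenation of line-broken words is deliberately not
attempted: silently joining `margin- ally` would risk manufacturing phrase
hits that are not verbatim present in the source text.

Records are filtered to publication dates from January 1990 through
September 2020. Records without a month are filtered at year level (kept
if year ≤ 2020): month metadata is frequently missing, and year-level
behavior is predictable. Dropped counts are reported so
kept + dropped = read always holds.

## Phrase matching

Matching is exact substring matching of a fixed phrase dictionary over the
normalized text — no word boundaries, no stemming, no elastic matching.
Elastic strategies can invert meaning (e.g. by detaching a negation), so
exactness is a feature: every hit is verbatim present. A `word_boundary`
option exists for sensitivity analysis.

The scanner is a hand-built Aho–Corasick automaton: one pass per document
finds all occurrences of all phrases, including overlapping matches of
different phrases and repeated matches of the same phrase. Its correctness
contract is equivalence with a brute-force check of every (offset, phrase)
pair, enforced by property tests over random corpora.

Nested dictionary phrases ("marginally significant" inside "only
marginally significant") are both reported; the shorter hit is annotated
with the longer phrase that subsumes it. Document-level counts are
produced in two variants — all hits, and subsumed-hits-excluded — because
either convention is defensible and the choice visibly changes per-phrase
counts. Document-level statistics use "contains the phrase at least once";
hit-level statistics keep every occurrence.

The shipped dictionary has exactly 505 entries and every entry is a fixed
point of the normalizer. It is a **synthetic stand-in** assembled from the
published high-frequency phrase list plus systematic variants built from
the same templates (adverb + "significant", article + adjective + "trend",
verb phrase + "statistical significance", …); a user with the original
curated list can drop it in unchanged.

## P-value extraction

For each phrase hit the 100 characters directly following the match are
searched for the first token of the grammar

    "("? "p" ("value"|"values"|"-value(s)")? (=|<|>|<=|>=|≤|≥) number

where `number` is a plain decimal (`0.052`, `.06`) or a power-of-ten form
(`1.2 × 10-3`, `1.5 x 10^-2`, `3e-4`). The `p` must not be immediately
preceded by an alphanumeric character (`bp = 0.03` is blood pressure, not
a P value), and a parsed number above 1 (a ratio or percentage) rejects
the token and the scan continues. These choices favor precision over
recall, mimicking careful manual extraction. Only the first valid token in
the window counts — the extraction targets *the* P value directly referred
to by the phrase; later tokens in the window typically belong to other
comparisons. Long-range referrals (tables, figures, other sentences) are
out of scope by design.

The comparator is retained for audit, and the numeric literal is used for
banding: `below` (< 0.05), `mid` (0.05 ≤ v ≤ 0.15, both boundaries
closed — the band is described as *between* 0.05 and 0.15 while the low
band is written *<* 0.05), `above` (> 0.15). Summary quantiles use linear
interpolation between order statistics (numpy's default), pinned so
summaries are reproducible.

## Prevalence and confidence intervals

Prevalence is the fraction of documents in a time bin containing at least
one phrase. The overall series uses yearly bins; per-phrase series use
3-year bins anchored at 1990 (1990–92, …, 2017–19) to stabilize estimates
for rare phrases, with 2020 as a partial terminal bin (the collection
window ends in September 2020). The partial bin is excluded from trend
fitting by default and includable by flag.

Intervals are the continuity-corrected Wilson score interval in Newcombe's
closed form, with z = 1.959964 pinned for bit-stable output. At study
scale (49,134/567,758) this reproduces 8.65% (8.58%–8.73%) and agrees
with the corrected-Wald form to four decimals; at small n it is the
better-behaved of the two (respects [0, 1], near-nominal coverage).
Simulated coverage at n = 5,000, p = 0.0865 sits in the 93–97% range —
nominal to slightly conservative, as expected for a continuity-corrected
interval. Degenerate cases are clipped: lower bound 0 when x = 0, upper
bound 1 when x = n.

## Trend Bayes factors

Per phrase, the binned prevalence point estimates are regressed on the bin
midpoint year (ordinary least squares, unweighted — an inverse-variance
weighted variant would privilege large bins and is left as future
sensitivity analysis). Evidence for a temporal trend is the Bayes factor
of the linear model against the intercept-only null under the JZS default
prior: a Cauchy with scale r = √2/4 ("medium") on the standardized slope,
equivalently a mixture of g-priors with g ~ InvGamma(1/2, n r²/2). With
one covariate this gives the one-dimensional integral

    BF₁₀ = ∫₀^∞ (1+g)^((n−2)/2) (1 + g(1−R²))^(−(n−1)/2) π(g) dg,

which depends on the data only through n and R² — hence BF₁₀ is invariant
to affine rescaling of time and shifts of prevalence (asserted
numerically). "Uninformative" is not a prior specification; pinning the
standard default of mainstream Bayes-factor software is the only
reproducible choice.

Numerics: the integral is evaluated in v = log g space. The integrand can
peak near the prior mode g = 2a (a = n r²/2) or near the likelihood mode
g ≈ 1/(1−R²); both candidate peaks are bracketed, the log-integrand
maximum is subtracted before exponentiation (no overflow at large n or
R² → 1), and adaptive quadrature integrates over [min peak − 80,
max peak + 120] with the peaks passed as split points, to relative
tolerance 1e-8. R² = 1 returns +∞. The implementation is cross-checked
against two independent oracles — a 400k-point extended-precision
trapezoid rule and a 10⁶-draw Monte-Carlo average over the g prior — on a
grid of (n, R²) including the near-degenerate corner.

Phrases with fewer than 5 nonempty time bins are flagged, not evaluated
(too few points for a meaningful trend comparison). Bins with zero
documents are dropped (0/0 carries no information); bins with documents
but no hits contribute prevalence 0. Evidence bands: BF ≤ 3.2 "mention",
(3.2, 10] "substantial", (10, 100] "strong", > 100 "decisive" — each
boundary belongs to the weaker band, a convention that had to be pinned
because the classical taxonomy is silent about ties.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes, not
prose. Defaults mirror the study conditions: years 1990–2019; per-phrase
occurrence Bernoulli with P(t) = logistic(logit(π₀) + β(t − midpoint));
direct-referral probability q = 0.41; P values from a below/mid/above
mixture with weights 0.25/0.68/0.07. Band shapes are scaled Betas —
below: 0.001 + 0.049·Beta(0.705, 1); mid: 0.05 + 0.10·Beta(0.804, 3.059);
above: 0.15 + 0.35·Beta(0.8, 3) — solved so that the overall distribution
has median ≈ 0.06, quartiles ≈ [0.05, 0.08] and a 5th percentile ≈ 0.006,
the observed quantile structure, without claiming knowledge of the true
density within bands. The overall 95th percentile lands slightly above
0.15 (≈ 0.17) because 7% of mass lies in the open above-band; this is the
one quantile the mixture reproduces only approximately.

Filler text is drawn from a fixed vocabulary of methods-section words
screened at config-build time against the phrase list (no shared words,
plus a scan of filler-only text), so a generated corpus with no injected
phrases produces zero hits against the full dictionary — scanner
specificity is guaranteed, not assumed. Each phrase is inserted at most
once per document, keeping ground-truth bookkeeping exact; multiplicity is
exercised through multi-phrase configs. When a P token is injected it is
placed 1–4 filler words after the phrase, always inside the 100-character
window.

`simulate_bin_counts` is the count-level view of the same occurrence
model: per-bin binomial draws of the positive count, for simulation
studies (trend recovery, null calibration) where document text is
irrelevant and generating it would dominate runtime.

What passing tests on synthetic corpora do **not** show: robustness to
real PDF-conversion noise (broken words, ligatures, tables), to phrase
occurrences inside quotations or negations, or to P values separated from
their phrase by more than the window. The generator's direct-referral
placement is cleaner than real prose, so real-world extraction rates will
differ from q more than the synthetic ones do.

## Problem sizes in the shipped checks

Tests and the acceptance script run on deliberately modest sizes chosen to
exercise each statistical claim at adequate power: the demo pipeline at
500 docs/year × 30 years; calibration checks at 2,000 binomial replicates
(n = 5,000); trend recovery at 50 replicates of 60,000 documents per
3-year bin via the count-level simulator; scanner–oracle equivalence on
200 random corpora of up to 100 documents; 10,000-case grammar fuzz. The
full-corpus analysis (~570k documents) is far larger but the pipeline is
linear in total text length, and every statistic is either
size-independent (arithmetic, CI forms) or improves with n.

## Known limitations

- Exact matching undercounts paraphrased spin; this is inherent to the
  design, which trades recall for certainty.
- Per-phrase counts depend on the nesting convention; both variants are
  emitted rather than one being silently chosen.
- The trend response is the unweighted prevalence point estimate; bins
  with very different document counts contribute equally.
- The BF model assumes Gaussian residuals on prevalence, which is an
  approximation for binomial proportions near 0.
- The shipped dictionary is a synthetic reconstruction, not the original
  curated list; analyses of real corpora should substitute the curated
  phrases.
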