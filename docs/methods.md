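# Methods

## The model

The package analyses single-nucleus RNA-FISH surveys of escape from
X-chromosome inactivation (XCI), as in marsupial fibroblasts where XCI is
incomplete and locus-specific. Each scored nucleus reports, for one X-borne
probe, how many alleles show a nascent-transcript signal (0, 1 or 2),
together with the signal count of an autosomal control probe.

The generative model has three ingredients per locus:

- **Active-X transcription.** One X (the active X, Xa) transcribes an
  expressed locus in every cell; the allele on the inactive X (Xi)
  transcribes with a locus-specific *escape probability* `e ∈ [0, 1]`.
  Escape is a per-nucleus Bernoulli event — the stochastic-escape
  hypothesis — not a uniform down-regulation of the Xi allele.
- **Detection dropout.** Each transcribing allele yields a visible signal
  independently with *detection efficiency* `d ∈ (0, 1]`. Males carry a
  single X, so the male one-signal fraction estimates `d` directly.
- **Diploid control.** Both autosomal control alleles are detected
  independently with `control_detection` per allele; analysis is restricted
  to nuclei with two control signals. Zero-signal "shielded" nuclei emerge
  from dropout; there is no separate shielding parameter.

The female signal-count distribution is therefore the trinomial

    P2 = e d²,   P1 = e·2d(1−d) + (1−e) d,   P0 = e(1−d)² + (1−e)(1−d),

which at `e = 1` reduces to the familiar two-allele expansion
`p² + 2pq + q² = 1` with `p = d`. Goodness-of-fit uses Pearson's chi-square
with 2 degrees of freedom (three cells, expectation fully specified; `d` is
plugged in from the independent male sample, so no parameter is fitted to
the female counts — the same df is used in self-fit diagnostics for
comparability, which makes those slightly conservative).

## Estimators

- **Detection** `d̂ = n1/n` from diploid male nuclei, with a Wilson 95%
  interval (preferred over Wald at `n ≈ 100` and proportions near 1). Loci
  with `d̂ < 0.05` are flagged not expressed and excluded downstream; the
  margin above exactly 0 guards simulated edge cases.
- **Escape, raw** `e_raw = n2/n`: the 2X-active fraction, the quantity such
  surveys print. Zero-signal nuclei stay in the denominator (published rows
  sum to ~100%, which implies they are counted).
- **Escape, corrected**: the MLE of `e` under the trinomial above with `d`
  known, by bounded 1-D likelihood maximization on [0, 1] (`xatol` 1e-7,
  boundary-snapped), with a 95% profile-likelihood interval (cutoff
  χ²₁(0.95)/2). Zero-probability cells are floored at 1e-300 inside the
  log-likelihood. Tests require agreement with a dense grid search
  (step 1e-4) to 1e-3, and CI coverage in [0.93, 0.97] under the generative
  model at `n = 200`. The sampling error of `d̂` is not propagated by
  default; at `n ≈ 100` male nuclei it is dominated by the female trinomial
  noise.

## Two-locus coordination

Scoring conditions on nuclei in which at least one of the two loci shows
two signals (published design: 100 such nuclei per pair). Three expected
concordant-escape scales are reported for escape frequencies `e_a, e_b`:

- unconditional independence: `e_a e_b` (the scale quoted in print);
- conditional independence: `e_a e_b / (e_a + e_b − e_a e_b)` — the scale
  the design actually samples;
- coordination: `(e_a + e_b)/2`, the concordant fraction if one
  domain-level event drove both loci, evaluated at the average frequency
  (an interpretation, flagged as such in reports).

The test is a two-sided exact binomial of the concordant count against the
conditional independence probability: the conditioned design has no fixed
margins and small expected counts, so a 2×2 chi-square is inappropriate.
Verdicts: *independent-compatible* when the test does not reject at α and
the observed fraction lies below the coordination expectation;
*coordinate-compatible* when it rejects and the observed fraction is closer
to the coordination expectation; otherwise *neither* (which includes pairs
with significantly **fewer** concordant nuclei than independence predicts).

In the simulator, the pair's escape events are coupled by a single mixture
parameter `ρ ∈ [0, 1]`: with probability `ρ` one shared uniform draw
thresholds both escape probabilities (comonotone coupling), otherwise the
draws are independent. This spans exactly the two hypotheses (`ρ = 0`
independent, `ρ = 1` fully coordinated) with marginals invariant to `ρ`;
a copula family would add flexibility no analysis here uses.

## Positional structure and Y-paralogue association

No test is named in qualitative "no polarity" claims, so the package makes
the claim falsifiable with two rank-based statistics over the activity map
(escape estimates ordered along the chromosome):

- **trend**: Spearman correlation of `e_raw` with position (polarity from
  one end); two-sided;
- **adjacency**: mean absolute difference of `e_raw` between map-adjacent
  loci (clustering; small = neighbors alike); one-sided low.

Null distributions come from permuting estimates across positions
(estimates exchangeable under "location does not matter"), with
`p = (1 + #extreme)/(1 + n_perm)` so p-values are never exactly 0. Both
p-values are reported unadjusted; a Bonferroni factor of 2 can be applied
by the reader — the headline claim is a non-rejection, so conservatism is
harmless. Both statistics are rank-based in position, hence invariant to
monotone position rescaling; with synthetic evenly spaced coordinates (see
below) only the published locus order matters.

Association of escape with Y-paralogue status ({none, expressed, silent})
uses the Kruskal-Wallis numerator (size-weighted squared deviations of
group mean ranks) with a label-permutation null; empty groups are collapsed
away with a notice.

## qPCR dosage ratios

Relative expression per well is `eff^(Ct_ref − Ct_test)` against an
autosomal reference (GAPDH), with amplification efficiency fixed at 2.0
(no calibration data accompany comparative-quantification outputs);
replicate wells are averaged on the linear scale, with replicates more than
1 Ct from the replicate median flagged (kept — flags are for inspection,
not silent exclusion). The female:male ratio of mean expression gets a
seeded percentile bootstrap CI (2000 resamples) and a two-sided
label-permutation p-value on the mean log-expression difference (≥ 9999
permutations) — distribution-free at the 5–6 samples per sex of such
designs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: ~100 diploid nuclei per
locus, detection efficiencies 0.94–0.99, per-allele control detection 0.97,
escape probabilities 0.05–0.7, pair scoring at 100 conditioned nuclei, and
the 6-female/5-male triplicate qPCR design with Ct noise of ~0.05–0.15
cycles. `simulate_counts` and `simulate_pair_conditioned` draw the implied
multinomials directly (distributionally identical to tallying per-nucleus
records) for replicated calibration studies.

It does **not** model: spatial nucleus geometry or signal distances (the
co-location assay enters only as escape-state coupling), signal intensity,
tissue-specificity of escape (one cell type), parental origin of the Xa,
between-individual variability, or probe cross-hybridization. Passing
calibration tests therefore validates the estimators under the stated
stochastic model, not against microscopy artifacts outside it.

## Fixtures and the locus map

Fixtures encode the published percentage tables. Where integer counts are
needed they are reconstructed at the nominal `n = 100` by largest-remainder
apportionment (deterministic tie-break: larger remainder, then earlier
cell); published per-locus denominators ("at least 100") are not recoverable,
so reconstructed counts are nominal. The published clone coordinates are not
reproduced in the locus map; coordinates are synthetic, evenly spaced, and
preserve the published centromere-down order (positional tests are
rank-based, so only order matters). Replays verify fixture SHA-256 checksums
and abort on mismatch. Invalid input rows abort a run by default; a
permissive mode downgrades them to warnings — silent data loss is worse than
failure.

## Study sizes and numerical choices

Calibration experiments follow the stated study conditions: 500 panels for
CI coverage (10 loci × 200 nuclei), 1000/500 replicate pairs for type-I
error/power, 500 replicates for permutation-test calibration. Inside such
replicated loops each permutation test uses 999 permutations; single-run
analyses use ≥ 9999. All randomness flows from one seed via
`numpy.random` generators (spawned per stage in the pipeline), and reports
are serialized with sorted keys so identical configurations are
byte-identical.

## Known limitations

- The dropout correction treats `d` as exact; a parametric bootstrap over
  `d̂` would widen escape CIs slightly.
- With 23 loci the positional tests have limited power against weak
  gradients; the power analyses show reliable detection only for gradients
  spanning most of the observed escape range.
- The coordinate-model expectation `(e_a + e_b)/2` is one formalization of
  "both loci driven together" when the pair's frequencies differ; perfect
  comonotone coupling would instead predict `min(e_a, e_b)` concordance on
  the unconditional scale.
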