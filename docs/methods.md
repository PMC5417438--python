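# Methods

## Model and procedure

`distotu` groups dereplicated amplicon sequences into OTUs with a greedy,
abundance-sorted merge loop. Candidates are visited in order of decreasing total count
(ties broken by sequence ID so runs are bit-reproducible); each is screened against the
existing OTUs with three criteria applied cheapest-first — abundance, then genetic,
then distribution — and merges into the first OTU, in order of increasing genetic
dissimilarity, that passes all three. Otherwise it founds a new OTU. An OTU's counts
grow with every merge; its representative sequence is frozen at founding, so it is
always the sequence of the OTU's most abundant member. The abundance screen compares a
candidate against the OTU's *current* (post-merge) counts, since the counts are defined
to accumulate and no freeze rule would be consistent with that.

**Genetic criterion.** Dissimilarity is `2E/(ℓ₁+ℓ₂)` where `E` is the Levenshtein edit
distance. The comparison is inclusive: a pair exactly at the threshold may merge,
since merging is only blocked when the metric *exceeds* the threshold. The edit
distance is computed with edlib under a distance bound of `⌊threshold·(ℓ₁+ℓ₂)/2⌋`, so
far-apart pairs are abandoned early without changing any criterion decision.
Comparison is case-insensitive; `N` mismatches every base including another `N` — the
conservative treatment for an ambiguity code, whose semantics under edit distance are
otherwise undefined. Characters outside A/C/G/T/N are rejected at input.

**Distribution criterion.** The null model draws the OTU's count in sample i from
Poisson(λ(i)) and the candidate's from Poisson(ρλ(i)) with a single proportionality
constant ρ; the alternative frees all 2n rates. Maximum likelihood gives ρ̂ = X₂/X₁ and
λ̂(i) = X₁(x₁(i)+x₂(i))/(X₁+X₂), and the deviance collapses to
Λ = −2[f(x₁+x₂) − f(x₁) − f(x₂)] with f(y) = Σ y(i) ln y(i) − (Σ y(i)) ln Σ y(i) and
0·ln 0 := 0 (the continuity limit; samples where both vectors are zero contribute
nothing). Degrees of freedom are n − 1 by parameter counting: 2n under the alternative
minus n + 1 under the null. With a single sample the models coincide (Λ = 0); the
result is returned with p = 1 and a `single_sample` flag rather than an error. The
p-value is the plain asymptotic χ² upper tail with no continuity correction — the speed
of that tail is the reason this test exists. ρ > 1 (candidate more abundant than the
OTU) is allowed by the formulas and not rejected here; in the calling loop the
abundance criterion makes it unreachable. p-values are operational merge thresholds,
never corrected for multiple testing.

**Simulated χ² oracle.** The Pearson statistic of the 2×n table is referred to a
Monte-Carlo null: tables drawn uniformly among those with the observed row and column
margins (Patefield's algorithm via `scipy.stats.random_table`, the same null as R's
`chisq.test(simulate.p.value=TRUE)`). The estimator carries the +1 correction,
p = (1 + #{sim ≥ obs})/(B + 1), so it never returns 0 and thresholding stays
well-defined; simulated statistics within 1e−9 of the observed one count as ≥ to make
ties deterministic in floating point. Zero-total columns are dropped — they contribute
nothing to margins or statistic. Default B = 10⁴ for pipeline-scale use; evaluation
runs use larger B from the CLI. For tiny tables `exact_pvalue` enumerates all tables
with the observed margins, weighting each by its multivariate hypergeometric mass
(∏ⱼ C(cⱼ, aⱼ) / C(N, R₁)); it is the independent check on the sampler and refuses
tables with more than ~10⁵ configurations.

**Alignment gold standard.** For evaluating the Levenshtein approximation, the
reference dissimilarity is the proportion of mismatched sites in a global pairwise
alignment (Bio.Align.PairwiseAligner; match +1, mismatch −1, gap open −2, extend −0.5 —
match-favoring so that substitutions are preferred over spurious gaps), with gap
columns excluded from the denominator. An in-repo aligner keeps evaluation free of
external binaries; any external aligner can be substituted where exact reproduction of
published confusion tables matters.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `dist` (genetic threshold) | 0.1 | max normalized edit distance 2E/(ℓ₁+ℓ₂), unitless in [0, 2) |
| `abund` (abundance fold) | 10.0 | min OTU:candidate total-count ratio before merging is considered |
| `pval` (distribution threshold) | 0.0005 | min LRT p-value to merge |

The genetic default 0.1 is where the Levenshtein metric tracks alignment dissimilarity
well; above ~10% true dissimilarity it underestimates, making the genetic screen an
*inclusion* filter — borderline pairs are admitted to the distribution test rather than
excluded. The distribution default sits below the legacy simulated-test threshold of
0.001 because the asymptotic tail is anti-conservative at sparse counts; a roughly
twenty-fold smaller threshold best reproduces the simulated criterion, and benchmark
reproduction uses 0.001 explicitly. The abundance fold of 10 treats candidates at less
than a tenth of an OTU's abundance as plausible error.

## Synthetic communities and what they show

The fixture generator emulates a dereplicated mock-community dataset: `n_base_seqs`
(default 5) mutually dissimilar random sequences of `seq_length` 187 nt across
`n_samples` 6, base rates λ(i) ~ Uniform(50, 500) per sample. Each base gets error
derivatives (1–2 edits; counts Poisson(ρλ(i)), ρ = 0.1) that should merge, and an
ecological twin (1–2 edits; rates drawn independently on half the samples, zero
elsewhere) that should stay separate. Counts are drawn from exactly the Poisson model
the LRT assumes, so under the merge truth the test's null holds exactly and recovery
rates are interpretable as operating characteristics. The generator does **not**
emulate real error profiles (per-base quality, homopolymer indels, chimeras),
compositional (multinomial) coupling between sequences, or overdispersion, so passing
recovery says the machinery is correct under its own model — not that real data meet
that model.

**Recovery protocol.** Ground-truth recovery (≥95% of error derivatives merged, ≥95%
of twins separated, over 50 seeds) runs the caller at abundance fold 3, not the
pipeline default 10. With ρ = 0.1 the expected OTU total sits exactly at 10× the
derivative's, so a fold-10 screen applied to two Poisson totals is a coin flip by
construction (P(X₁ ≥ 10X₂) → 0.5, at any rate scale); the recovery statistic is meant
to measure the distribution criterion, and fold 3 — safely below 1/ρ while still
demanding the candidate be several-fold rarer — isolates it. Measured recovery at
these settings is 99.8% merge / 100% split.

**Type-I calibration.** The LRT's rejection rate is checked against α under the null
generator with both vectors at moderate rates (ρ = 0.5, λ ∈ (50, 500); 10⁴ replicates,
±3 Monte-Carlo SE). At sparse candidate counts (ρ = 0.1, per-sample means 5–50) the
asymptotic tail is systematically, mildly anti-conservative (≈0.055–0.06 at α = 0.05);
a unit test pins that behavior, which is the known low-count inaccuracy that motivated
the slower simulated test and the twenty-fold-smaller default threshold.

## Numerical choices

- Λ is clamped at 0: the models are nested, so negative values are rounding artifacts.
- Tie-breaks: candidate order (total count desc, ID asc); eligible-OTU order
  (dissimilarity asc, OTU creation order asc). No randomness anywhere in the caller.
- The Fisher z-transform supplies the 95% CI on Pearson correlations (the standard
  parametric choice); percentages are rounded to one decimal only at report time.
- Degenerate inputs fail loudly: empty FASTA, duplicate IDs, non-integer or negative
  counts, zero-total rows, FASTA/table ID mismatches (first 10 offenders listed),
  all-zero vectors in f, zero-margin rows in the simulated test.

## Problem sizes

Tests run on communities of ~20 sequences × 6 samples (50 seeds for recovery), 10⁴
null replicates for calibration, B = 10⁵ for Monte-Carlo/exact agreement, and 10³
random string pairs against a full dynamic-programming edit-distance oracle; these
sizes give Monte-Carlo errors well inside the asserted tolerances.

## Known limitations

- The Levenshtein metric underestimates dissimilarity above ~10–15%; treat the genetic
  threshold as an inclusion criterion, not a taxonomy.
- The asymptotic tail is anti-conservative at sparse counts (see above); rare
  candidates are rejected from merging slightly too often at a given threshold.
- The Poisson model ignores overdispersion and compositional constraints of real
  amplicon counts.
- The greedy loop is order-dependent by design; results are deterministic but not
  invariant to abundance re-ordering.
- The published pipeline-level benchmark counts require the original benchmark inputs,
  which are not redistributed here; the acceptance tests that need them state the
  expected location.
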