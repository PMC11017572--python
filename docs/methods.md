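# Methods

## Problem setting

Prokaryotic annotation pipelines call a coding locus a pseudogene when its
sequence implies a broken product — typically an internal (premature) stop
codon or a frameshifting indel.  Both signatures are also exactly what a
base-call error or a small assembly indel produces, so an assembly's
pseudogene count mixes biology with technical error.  The package treats the
technical component as a measurable quantity: compare annotations across
near-identical genomes, model the spurious-pseudogene rate as a function of
read coverage and quality, and flag assemblies whose pseudogene count is
statistically inconsistent with their nearest neighbor.

## ORF classification

A candidate coding sequence `obs` is classified against a trusted intact
reference ORF by global alignment (match +1, mismatch −1, gap open −3, gap
extend −1 per base, deterministic tie-breaking).  Two independent signals are
read off the alignment:

- **Frameshift.**  Indel runs are scanned left to right; a run that leaves
  the cumulative indel balance ≢ 0 (mod 3) marks a downstream out-of-frame
  segment.  Runs anchored in the final 5% of the reference are ignored:
  end-gap placement is unreliable, and real terminal variation (alternative
  stops) would otherwise produce false calls.  A 3k-length indel never
  triggers the call; compensating +1/−1 indels do, because an interior
  segment is still read out of frame.
- **Internal stop.**  Observed codons are read in the frame inherited from
  the reference through the alignment: a reference codon contributes only
  when all three of its bases align to consecutive observed bases with zero
  cumulative indel offset.  An in-frame stop strictly before the reference's
  terminal stop is premature, except in the last complete codon before the
  terminal stop (a stop there terminates where the gene terminates).
  Reading only in-frame codons keeps the two causes orthogonal: a frameshift
  does not also generate internal-stop calls from its scrambled downstream
  frame.

Sequences with more than 10% ambiguous bases are refused rather than guessed
at.  The genetic code defaults to the bacterial table (11), with starts
{ATG, GTG, TTG}.

Nucleotide identity used elsewhere (clustering, ANI fragments) is defined as
matches / aligned columns, gap columns included in the denominator, computed
from a unit-cost global alignment.  The classifier is a deliberately simple,
reproducible stand-in for homology-search annotation; its verdicts are
validated against the synthetic generator's ground truth (≥ 99% agreement on
single-event corruptions), not against any external annotation tool.

## ANI

The query genome is cut into non-overlapping 1000-bp fragments.  Candidate
placements in the subject are found by exact 15-mer seeding (sampled every
37 bp, both orientations, diagonal voting); the best placement is scored by
a banded edit-distance alignment in a ±60-bp window.  Fragments with ≥ 70%
identity over ≥ 70% of their length contribute; ANI is the mean contributing
identity, averaged over both directions, in percent.  When nothing passes
the cutoffs the result is undefined, never zero.  Self-comparison returns
exactly 100.  These are the usual fragment-based (gANI-style) conventions;
the fragment length and cutoffs are exposed as parameters.

## Pairing and congruence

Coding sequences of two assemblies are single-linkage clustered at ≥ 90%
nucleotide identity (exact-duplicate grouping first, then a shared-k-mer
prefilter before alignment; the prefilter can only skip pairs that share no
14-mer, which at coding lengths and a 90% threshold does not change the
result).  Clusters with more than two members suggest paralogy and are
excluded.  For each remaining cross-assembly pair containing a pseudogene,
the pair is *congruent* for a cause (frameshift or internal stop) when both
members are pseudogenes and at least one carries the cause, *incongruent*
when exactly one member is a pseudogene carrying it.  The incongruent
fraction per cause is incongruent / (congruent + incongruent); each pair's
weight (that denominator) is carried so survey trends can be weighted by the
number of informative pairs, with a weighted moving median standing in for
spline smoothing.

Spurious pseudogenes against a trusted reference are reassembly pseudogenes
whose retained cluster partner is an intact reference gene; within each
cluster only the single highest-identity cross-assembly pair is retained
(ties broken lexicographically), again to exclude paralogs.  Counts are
normalized by the reassembly's CDS count (the binomial denominator) and per
Mbp (for reporting).

Two sanity filters mirror common practice for accepting a reassembly:
assembly length within 95–105% of its reference (inclusive), and for
subsampled-read experiments, size and observed coverage within 80–120% of
target (inclusive) with shared gene content strictly > 80%.

## The binomial coverage/quality model

Each of the *n* coding features of an assembly is assumed to independently
become a spurious pseudogene with probability

    π(coverage, Q) = expit(β₀ + β_cov·log₁₀(coverage) + β_q·Q)

so the observed count is Binomial(n, π).  The logit link and log-coverage
are modeling choices: they make the error–coverage decay monotone and
scale-free, and match how coverage spans orders of magnitude in practice;
mean base quality Q enters untransformed.  Fitting is maximum likelihood by
iteratively reweighted least squares, converged at |Δ log-likelihood| <
1e-8 within 100 iterations.  A constant quality column is dropped (the
coefficient is reported as absent, not zero).  An all-zero (or saturated)
response has no finite MLE and sets a `boundary` flag instead of returning
numbers; suspected separation (non-convergence or |η| > 30) triggers a refit
with a 1e-6 ridge and a visible `separation` flag, never a silent one.
Standard errors come from the observed information at the optimum.  The
implementation is tested against an independent GLM fit and a grid-search
MLE oracle.

Two derived quantities summarize a fit, both on the per-Mbp scale
(π·n_cds·10⁶/genome length): the expected density at a 50-fold reporting
coverage, and the coverage at which the density curve crosses a target of
1 pseudogene per Mbp.  The inversion is by bisection on log₁₀(coverage)
over [0.1, 10⁶] to 1e-6 relative tolerance, cross-checked against the
closed-form logit inversion; a target met everywhere (or nowhere) in the
bracket is reported with an explicit status rather than extrapolated.

## The anomaly filter

For an assembly with a nearest neighbor at ≥ 99.9% ANI, the neighbor's
internal-stop rate r = stops/n_cds defines the null; the assembly is
rejected when its own stop count strictly exceeds the discrete 99th
percentile min{t : CDF_Binomial(t; n_cds, r) ≥ 0.99} (no normal
approximation).  With r known this rejects ≤ 1% of true nulls by
construction.  When r is itself estimated from a single neighbor draw — the
realistic screening situation — the paired test runs anti-conservative
(≈ 5% null rejection in simulation), because an unlucky low neighbor draw
lowers the threshold.  The screen is therefore a flagging device, not a
calibrated hypothesis test, and the workflow reports the neighbor rate and
threshold alongside each verdict.

## Synthetic data

`make_genome` builds a single-contig genome of `n_genes` ORFs (ATG + random
sense codons + stop; lengths Normal(900, 200) bp rounded to codons, floor
150 bp) separated by Normal(120, 30)-bp spacers, random strand, GC
adjustable (default 0.5).  Defaults emulate a small enterobacterial
chromosome at desk scale: ~1000 genes ≈ 1 Mbp.  A fraction (default 2%,
near the pseudogene fraction of well-studied enterobacteria) are true
pseudogenes, split evenly between an internal-stop substitution and a 1–2-bp
indel; every feature keeps its intact ancestral ORF so the classifier has a
reference.

`corrupt` produces a "reassembly" at a nominal (coverage, Q):

- **feature_level** (default): each intact gene flips to a spurious
  pseudogene independently with the logit-linear π above — by construction
  exactly the model family the fit assumes, making parameter recovery a
  sharp test.  Default coefficients (β₀, β_cov, β_q) = (2, −3, −0.1) put
  the per-CDS probability at ~2.6% at 5-fold/Q35 and ~2·10⁻⁴ at 200-fold,
  i.e. spurious pseudogenes essentially vanish above a few hundred fold —
  the qualitative regime observed with real short-read assemblies.
- **base_level**: substitutions and indels (lengths 1–3, half deletions)
  scattered genome-wide at per-base rates with the same covariate
  dependence, anchored at 3·10⁻⁴ substitutions/bp (≈ the Q35 error rate)
  and 3·10⁻⁵ indels/bp at the 50-fold/Q35 reference condition.  Labels are
  derived from the event effects (prefix indel balance for frameshifts;
  in-frame codon edits for stops), and this mode exercises the classifier
  on realistic mutation patterns.

`fragment` splits contigs at uniform random breakpoints, drops pieces under
200 bp, and removes features spanning a break, logging them as truncations —
truncation/partial calls are deliberately never counted toward frameshift or
internal-stop tallies, since they are confounded with assembly
incompleteness.

`simulate_experiment` runs the full factorial grid (default coverages
{5, 10, 25, 50, 100, 250, 500}, qualities {20, 30, 35} available, 3
replicates) with independent per-condition RNG streams derived from one
master seed.  Spurious counts are taken either straight from the event log
(`event_log`, the default — in feature-level mode this is exactly the
count's sampling distribution) or through the complete
classify→cluster→count pipeline (`pipeline`); a test asserts the two agree.

What the generator does *not* emulate: read-level errors and their
correlation structure, k-mer/de-Bruijn misassembly, repeats and paralogy,
platform-specific error profiles, and truncation-inducing contig breaks at
gene boundaries.  Passing tests therefore demonstrate correctness of the
statistics and the internal consistency of the pipeline under the stated
error model, not the behavior of any particular assembler on real reads —
where variance is known to be substantially larger.

## Numerical and design choices

- All tie-breaks (cluster members, nearest neighbors, retained pairs) are
  lexicographic on identifiers, so outputs are deterministic.
- The k-mer prefilters (15-mers for ANI seeding, 14-mers for clustering)
  only prune candidate pairs; alignment always confirms.
- Gap costs: a length-L gap costs 3 + L (open −3, extend −1 per base).
- Pseudogene recognition accepts the union of annotation dialects
  (`pseudo=true`, `gene_biotype=pseudogene`, feature type `pseudogene`);
  causes are case-insensitive keyword matches ("frameshift",
  "internal stop", "incomplete"/"partial") in Note/pseudogene attributes.
  A pseudogene may carry several causes and counts once per cause.
- Problem sizes in the test suite are chosen for statistical resolution at
  desk scale: e.g. the coverage-decay ordering test uses an 8000-gene pool
  and 20 replicates, for which an a-priori Poisson tail calculation puts
  the probability of a sampling-noise inversion at the sparse high-coverage
  end of the grid below 1%; parameter-recovery uses 63-observation grids on
  1000-gene genomes, giving standard errors small enough that a 3-SE check
  is meaningful.

## Known limitations

- The classifier needs the reference's intact ancestral ORF; classifying
  against a reference that is itself a frameshifted pseudogene violates its
  preconditions.
- ANI seeding can miss placements for fragments diverged far beyond the 70%
  cutoff region; such fragments simply do not contribute, which is the
  intended behavior but means `aligned_fraction` conflates divergence with
  true absence.
- The binomial model ignores overdispersion; real reassembly replicates
  show more variance than Binomial(n, π), so fitted standard errors are
  optimistic for real data.
- The anomaly screen with an estimated neighbor rate is anti-conservative
  (see above); with plug-in rates from a single genome it flags roughly 5%
  of clean assemblies at the nominal 1% level.
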