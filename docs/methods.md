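# Methods

This note documents the statistical model, the tunable parameters, the
numerical conventions, and what the synthetic-data generator does and does
not emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Matching model

Per-base sequencing quality enters all matching as the correct-call
probability Q_p = 1 − 10^(−Q/10). The probability that a candidate
reference string explains a read is the product over aligned positions of
Q_p where read and candidate agree and (1 − Q_p) where they disagree.
Candidates — primer sequences, or the partial-EAG sequences of one locus,
exon and read direction — are stored in a prefix tree and evaluated by a
depth-first walk that carries the running product. Every factor is ≤ 1, so
the product is non-increasing along a path; pruning at the floor `p_min`
is therefore *exact*: a candidate survives the walk if and only if its full
product is ≥ `p_min`, and surviving probabilities equal the brute-force
per-candidate products bit-for-bit up to floating-point association
(verified to 1e-12 relative in the suite).

Conventions:

* IUPAC degeneracy in primers is expanded into tree branches at build
  time; a read base that matches any expansion contributes Q_p (primer
  degeneracy is intentional, not an error).
* A read shorter than a stored sequence is scored over the covered prefix
  and supports every candidate below the last node reached (they are
  indistinguishable from this read); read bases beyond a stored
  sequence's end are ignored.
* Reverse-direction PEAG sequences are stored reverse-complemented, so one
  walk implementation serves both directions, always 5'→3' in read
  orientation.
* Arg-max ties between candidates are recognized with a 1e-9 relative
  tolerance. Exactly tied paths arise whenever a read does not cover a
  discriminating position; ties from rounding do not occur in practice but
  the tolerance makes the behavior explicit.
* Within intronic flank segments of PEAG partial sequences (positions past
  the exon body, reached only when the covered span exceeds the exon) the
  walk admits single-base insertion/deletion moves, at most 3 per path,
  each multiplying the probability by `indel_penalty` (default 1e-3, the
  error weight of a Q30 mismatch). Exon bodies are matched strictly
  gap-free. The event bound and penalty are package choices; nothing in
  the underlying method prescribes them.

## Primer recognition

Three levels, cheapest first: (1) exact prefix comparison against the
primer library (IUPAC-aware); (2) exact lookup of the leading bases
(longest-primer-length prefix) in an artifact table of previously resolved
non-exact prefixes; (3) the probabilistic tree walk. A level-3 match is
retained only when the best primer's probability is at least
`dominance_ratio` times the runner-up's (ties at exactly the ratio are
retained, for determinism); successful resolutions are memoized into the
artifact table, which can be exported/imported as TSV to persist across
runs.

Defaults: `p_min = 1e-4` — an otherwise high-quality primer match survives
roughly one high-Q mismatch (factor ~1e-3) with slack; `dominance_ratio =
10` — a full decade of separation. The method defines both knobs but not
their values; these are conservative package choices, config-exposed.
Level-2 answers return the primer identity the level-3 walk stored for
that exact leading sequence; the memoized probability is that of the first
resolving read (qualities of later reads with the same bases may differ —
accepted, as the table's purpose is identity, not probability).

## Evidence accumulation

Each matched, primer-clipped read contributes its member EAGs at the
maximum probability over its matching PEAGs (a read supports its best
explanation). Per EAG three counters accumulate over both directions:
`n_match` (read explains the EAG at all), `n_best` (EAG is in the read's
arg-max set), `n_single_best` (unique arg-max). Only EAGs with ≥ 5
best-match reads are considered; ranking is by `n_best` descending with id
tie-break.

## Classification

Per sample-locus-exon, ranked EAGs are labeled top-down with fixed
precedence: **discarded** (below 1/50 of the top `n_best`; the ranking
metric `n_best` is also the discard metric) → **co-amplificate** →
**crossover** → **noise** → **potential new allele** → **result**.
Artifact labels precede novelty claims deliberately: a chimera or paralog
must not be promoted to a new allele.

* **Consensus** — majority base per exon position over the EAG's
  best-match reads (forward reads aligned at exon start, reverse reads
  reverse-complemented and right-aligned); ties break toward the EAG
  reference base, zero-coverage positions are flagged and filled with it.
* **Co-amplificate** — consensus within ≤ 2 mismatches of an allele of a
  different locus, *and* strictly closer to that allele than to any allele
  of the target locus (the second condition protects genuine results that
  happen to resemble a paralog; same-locus ties win).
* **Crossover** — consensus expressible as prefix(i) + suffix(j) of two
  higher-ranked, non-discarded EAGs for some single breakpoint; the scan
  over (b, i, j) is exhaustive via longest-common-prefix/suffix arithmetic
  and returns the smallest breakpoint, lexicographic pair.
* **Noise** — for each higher EAG labeled result or potential-new-allele:
  every best-match read of the higher EAG converts to the lower one with
  probability equal to the product of its per-base error probabilities
  10^(−Q/10) over the discriminating positions it covers (reads covering
  none convert with probability 1 — a deliberate conservative inflation
  that also handles direction-specific discriminating sites). The mean
  over reads is the conversion probability p; the p-value is the exact
  upper-tail binomial P(X ≥ n_low) with n = n_low + n_high. The lower EAG
  is noise when p-value ≥ `alpha` (default 0.01) — i.e. its count is
  *explainable* as noise. The one-line verbal description this implements
  does not fix the tail direction, the aggregation, or alpha; all three
  are package constructions and config-exposed.
* **Potential new allele** — an alternate base carried by ≥ 80% of
  covering reads, with ≥ 5 reads and mean Phred ≥ 25 (thresholds echo the
  5-read and Q25 conventions used elsewhere in the pipeline).

More than two results per exon raises an error, downgraded to a warning
when the third result has < 20% of the top result's best matches.

## Genotype combination and safeguards

Exons with < 20 result reads are ignored. Per informative exon the (≤ 2)
result EAGs are assigned to chromosomes in every order; a pairing is valid
when, for each chromosome, the intersection of its assigned EAGs' member
alleles across exons is non-empty. All valid pairings are enumerated; more
than one (the exon-2/exon-3 cross-pairings both viable) sets the
`exon_shuffling` flag and all pairings are reported — an intermediate-
resolution result, with the first enumeration kept as the primary one.
When no pairing exists, co-amplificate EAGs are added one at a time in
rank order and the combination retried (an off-target label can mask a
true allele whose sequence coincides with a paralog's); success sets
`coamp_rescued`.

Safeguards: a homozygous call needs ≥ 100 best-match reads summed over the
result EAGs of informative exons — at 20:1 amplification imbalance a
suppressed second allele sits near 5% of reads, and 100 reads keep it
safely above the 5-read consideration limit (100 × 5% = 5, the detection
limit; hence "20-fold above"). Below 100 the call becomes
`blocked_homozygous` and can never be auto-accepted. A second EAG with
n_best ≥ max(2% of top, 5) that survives classification is a genuine
second allele; the 2% relative rule and the 5-read absolute floor are
harmonized deliberately (100-read block × 2% = detection limit).
Whether the 100-read count uses best-match or all assigned reads is not
fixed by the method; this implementation counts best-match reads of result
EAGs.

## Rating and status

Three fractions per sample-locus: successful primer matches (computed per
sample — unmatched reads cannot be attributed to a locus), reads with at
least one EAG association among reads routed to the locus, and reads
contributing to the final result (best matches of the up-to-two result
EAGs over routed reads). Each maps through a two-threshold ramp — 0 below
the lower threshold, 1 above the upper, linear between — and the rating is
the product. Default thresholds: primer match (0.80, 0.95), EAG
association (0.70, 0.90), contributing reads (0.80, 0.95); the method
defines the ramp mechanics but not the values, which are package choices.
Status: `auto` requires rating exactly 1, no flags of any kind, and no
blocked homozygosity; unresolved >2-result conflicts give `edit_required`;
no valid pairing (or all exons ignored) gives `failed`; everything else is
`review`. Analyst decisions are a non-interactive override table
(include/exclude per sample-locus-exon EAG, plus a run-level
ignore-artifact list) whose application reruns combination and rating.

Ambiguity strings are explicit allele lists — groups sorted and joined
(`/` within a chromosome group, `+` between groups). Registry multi-allele
code tables are versioned external artifacts and are intentionally not
consulted; an optional user-supplied mapping can be layered on top.

## Primer-set QC (truth-based read classification)

For validation samples of known genotype: a 10-mer index over all
reference amplicon frames yields the most similar allele (diagonal-voted
ungapped placement, > 10 mismatches ⇒ not matched). Against the two truth
alleles the quality-weighted mismatch burden Q_sum (sum of Phred scores at
mismatching positions, computed on the primer-clipped insert frame) decides:
Q_sum > 80 against both ⇒ not matching (after a chimera-rescue check);
matching > 50 worse than an outside reference allele ⇒ other HLA allele;
otherwise the lower-Q_sum allele wins, ties to allele 1. A read assigned to
one allele carrying ≥ 2 bases with Q > 25 that agree with the *alternate*
allele is "allele n with crossover"; not-matching reads whose best
single-breakpoint chimera explanation has Q_sum ≤ 80 (and passes the same
≥2-base rule) are rescued as crossover. Per primer set, the allele balance
ratio (min/max of the two allele counts, crossover reads counted with
their assigned allele) must reach 20% for heterozygous truth; the
crossover rate is crossover reads over matched reads.

## The simulator

`simulate` emulates the data-generating process the caller assumes: per
locus an ancestral ~270 bp exon with conserved intronic flanks; alleles
derived by a configurable number of seeded substitutions; forward primers
ending at the exon start and reverse primers beginning at the exon end, so
251-cycle reads enter the exon at its boundary from both sides; binomially
split diploid coverage with configurable amplification imbalance;
single-breakpoint chimeras at a configurable rate (breakpoint uniform over
the exon — no positional model is claimed); optional co-amplification of a
paralog locus sharing the primer sites at 1–2 substitutions from the
target ancestor; dual indices assigned as (k mod 96, (k + k//96) mod 16),
giving every sample of a ≤ 96-sample run a distinct index1 so that a
single-index hop provably lands in an unused combination (a strictly
contiguous block would not have this property; larger runs keep unique
pairs but lose the per-hop guarantee); index hopping modeled as an index2
swap to another sample's value.

Emitted qualities are calibrated: each base errs with probability exactly
10^(−Q/10) of its emitted Phred score. A flat `error_rate` overrides the
per-cycle profile (mean Q 33 declining by 6 over the read, ± 3 uniform,
clamped to [2, 41]); `error_rate=0` is an idealized error-free mode.
Defaults (1000 pairs per amplicon, 15% crossover, 96×16 index space)
mirror routine operating conditions at desk scale.

What the simulator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: read indels and homopolymer artifacts
(the error model is substitution-only; the matcher's intronic indel
handling covers reference indels, not read indels), instrument-learned
quality profiles, PhiX or cluster-density effects, primer-binding-site
polymorphism (flanks are conserved within a locus), full-gene references,
and the allele-frequency structure of real populations (alleles are
equidistant from an ancestor rather than phylogenetically structured).

The validation-pair generator used for primer-QC experiments builds a
heterozygous allele pair whose differences extend to the extreme ends of
the insert (positions 0, 1, 2 and L−3, L−2, L−1 plus an internal grid), as
validation panels are chosen to be maximally informative; chimeras with a
breakpoint outside the discriminating range are undetectable in principle,
and this placement confines that blind window to under 1% of breakpoints.

## Problem sizes and numerical choices

The validation experiments run a 96-sample × 3-locus cohort at 500 read
pairs per amplicon (0.3%/base error, 15% chimeras, imbalance up to 5:1) for
genotype recovery; 20 replicates of a 500-pair validation sample for
recovering a 25% chimera fraction; and 500 single-allele replicates (one
120 bp exon, 80-cycle reads, 1%/base error — a deliberately harsh regime
that generates a steady supply of spurious EAGs) for noise-test
calibration. These are the smallest cohorts at which binomial error bars
are decisively narrower than the effects under test.

Floating point: probabilities are accumulated as raw double products
(shortest path ~250 factors; underflow is impossible above `p_min`);
binomial tails use `scipy.stats.binom.sf`, cross-checked in the suite
against an exact rational-arithmetic oracle to 1e-9. Determinism: EAG and
PEAG ids are `locus:exon[:direction]:sha1(sorted members)[:8]`, all
orderings are explicit (rank, then id), and every source of randomness in
the simulator flows from one integer seed.

## Known limitations

* Exon bodies are matched gap-free; a true allele with an exonic indel
  relative to its nearest reference allele will not be recognized as a
  potential new allele (substitution SNPs only).
* Crossover detection models a single template switch; double-switch
  chimeras are not searched for (they are correspondingly rarer).
* The noise test conditions on the ranked counts and tests pairwise
  against one higher EAG at a time; joint noise from several sources is
  approximated by the most permissive pairwise explanation.
* Rating fractions use the primer-match rate of the whole sample for every
  locus of that sample, since unmatched reads carry no locus label.
* The 10-mer prescreen assumes ungapped placement, appropriate for
  primer-anchored amplicon reads only.
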