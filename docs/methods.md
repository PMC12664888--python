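# Methods

## The benchmark model

`hrrbench` evaluates host-read-removal (HRR) methods as binary classifiers
over individual reads. The positive class is *a read removed by the method*;
a read's truth status is positive when it entered the mixture from a
human-sample pool and negative when it came from a target (viral/microbial)
pool. Ground truth is carried by a provenance label serialized into each
read name (`base#<class>#<donor>#<contig:start-end>`), which makes fate
scoring exact after any tool, including tools that truncate names at
whitespace or add `/1`/`/2` suffixes. The label delimiter (`#`) is a package
choice — any whitespace- and slash-free injective encoding would do — and is
configurable.

Truth classes are three-valued. HOST reads come from a donor's genome;
CONTAMINANT reads are microbial reads embedded in a donor's pool, emulating
the true microbial contaminants present in real human-sample read sets;
TARGET reads are the organisms of interest. For fate metrics, HOST and
CONTAMINANT collapse to truth-positive ("originating from a human sample"),
which is exactly what makes the false-negative composition analysis
meaningful: a retained contaminant is a false negative whose taxonomic
classification is microbial.

## Synthetic data generator

The generator is first-class, tested code, not a fixture. Genomes are i.i.d.
uniform base sequences (optional GC target); donor genomes are derived from
one base host genome by i.i.d. substitutions at `snp_rate` (default 0.001–
0.005 in the shipped configurations), so donors are mutually similar the way
human genomes are. Paired-end reads use uniform fragment starts, Gaussian
insert lengths truncated to [read_length, genome length], and
substitution-only errors (default 0.002/base). Indels, platform quality
profiles and structural variation are deliberately not modelled: the
evaluation engine consumes read *names* and fates, so sequence-level realism
beyond "alignable, donor-specific, error-bearing" adds nothing to what the
tests can show. Consequently, passing tests demonstrate correctness of the
bookkeeping, statistics and analyses — not that any particular real aligner
achieves a particular sensitivity on real human reads.

Every operation is deterministic under its seed; compound seeds are derived
by SHA-256 hashing of the coordinate tuple (31-bit outputs), so per-cell
seeds are stable under design reordering. Pool compositions are exact:
`round(contamination_fraction · n)` contaminant pairs (half away from zero),
remainder host.

## Titration design

Human titer *t* ∈ 1..9 means host fraction *t*/10, spanning proportions 1:9
to 9:1. Host pairs are allocated across donors equally — floor(n/D) each,
remainder to the lexicographically first donors — so per-donor counts never
differ by more than one pair. Sampling is without replacement everywhere
(pools are finite read sets), independently per iteration. Two sizing modes
exist because observed mixture totals in real benchmarks vary: FIXED_TOTAL
(default; total pairs constant per mixture, deterministic totals for
testing) and FIXED_VIRAL (target count constant, host count scaled as
`round(viral · t/(10−t))`).

## Removal contract and the singleton rule

A method flags reads; post-processing removes the un-flagged mate of any
flagged read ("singleton"), so only intact non-host pairs are retained.
Singleton-removed reads count as removed (positive) by default, since they
are absent from the retained output; this means a target-class mate of a
flagged read becomes a false positive. The choice is configurable
(`count_singletons_as_removed`) because the convention materially affects FP
accounting. A consequence worth noting: under per-read flagging at rate *s*,
the pair-level removal probability of a host pair is 1 − (1 − s)², so
modestly different per-read sensitivities converge near 1 at pair level.
Parameter-recovery checks therefore measure pre-singleton flag rates on
pure-class pools, where the configured rates are the estimands.

The simulated remover flags each read by its truth class at configured rates
(sensitivity for HOST, false-positive rate for TARGET, a separate
contaminant rate defaulting to the FPR), in PER_READ ("unpaired") or
PER_PAIR mode. Real tools attach through a subprocess adapter that
reconciles retained-output names against input names and never inspects
labels; running actual aligners against multi-gigabase references is out of
scope.

## Statistics

*Aggregation.* Per (method, reference, titer): mean and 95% CI as
mean ± t₀.₉₇₅,ₙ₋₁·sd/√n. A t-interval rather than normal or bootstrap —
honest at n of a few dozen cells; n = 1 yields a zero-width band with a
degenerate flag.

*Wilcoxon tests.* Implemented from first principles. Signed-rank: zero
differences discarded (classic convention; Pratt available), average ranks
for ties, statistic W⁺. The exact null for usable n ≤ 25 is computed by
convolving the rank generating function (identical to enumerating all 2ⁿ
sign vectors); beyond that, normal approximation with tie and continuity
corrections. Rank-sum: exact enumeration of all C(nₐ+n_b, nₐ) labelings for
nₐ+n_b ≤ 12, normal approximation otherwise. Two-sided p doubles the smaller
tail, capped at 1. Degenerate inputs (all differences zero) report p = 1
with a flag.

*Metrics.* Closed forms at read level. Any zero denominator reports the
metric as 0.0 with an explicit degenerate flag instead of NaN, keeping
downstream aggregation robust without hiding the condition.

*PERMANOVA.* SS_total = (1/n)Σ_{i<j}d²; SS_within = Σ_g (1/n_g)Σ_{i<j∈g}d²;
pseudo-F = [SS_between/(g−1)]/[SS_within/(n−g)]; p by label permutation with
the add-one rule (1 + #{F_perm ≥ F_obs})/(1 + N), never 0. Exact enumeration
of all label permutations is available for n ≤ 8. The test runs on distances
in the original coverage space (Euclidean by default; Bray-Curtis and
binarized Jaccard available) rather than on t-SNE coordinates, to avoid
testing embedding artifacts. Depth thresholds are inclusive (≥).

*Embedding.* PCA to min(50, n−1) components, then t-SNE with perplexity 30
and 5000 iterations, seeded; perplexity is auto-shrunk with a warning when
it reaches the unit count.

## False-negative composition

The 6-column hierarchical classification report (percentage, clade reads,
direct reads, rank code, taxid, 2-space-indented name) is parsed into a
tree with the clade-sum invariant verified on load; merging across samples
unions nodes by (path, taxid) and sums counts, so merge is associative and
commutative and preserves hierarchy. "Microbial" means classified and not
within the human clade (default: the Homo sapiens subtree, taxid 9606;
configurable — whether broader chordate clades should count as "human" is a
configuration question, not hard-coded). Running the classifier itself is
external; for tests, composition is validated against provenance-label
truth, which needs no classifier. Donor-group balance of FN reads uses a
Pearson chi-square with expectations proportional to donors per group and a
seeded Monte-Carlo p when expected counts are small.

## Residual-human identifiability

Per-chromosome residual summaries use reads per megabase per million
evaluated reads (the normalization is a documented package choice) and
length-weighted mean depths. The pseudo-log display transform is
asinh(x/2σ)/ln 10 — odd, finite at zero, ≈ log₁₀ for large x. The sex score
is Y mean depth over autosomal mean depth; thresholds (male-consistent
≥ 0.1, female-consistent ≤ 0.01) are score-scale configuration chosen to
separate zero-signal from male-like regimes by an order of magnitude, not
biological claims. Re-alignment of post-HRR reads is the caller's step; the
synthetic path recovers each residual read's chromosome from its provenance
label instead.

## Problem sizes and numerical choices

Shipped configurations are desk-scale by design: the demo runs 2 samples ×
9 titers × 3 iterations at 1,000 pairs/mixture with 4 donors; the design
cardinality check uses the full 13 × 9 × 3 grid (351 mixtures);
rate-recovery checks use 10⁵-pair mixtures per titer (2×10⁵ reads), large
enough that 99% binomial bands around sensitivity 0.995 and FPR 3×10⁻⁵ are
a few parts in 10⁴ wide. Monte-Carlo calibrations use 2,000 null replicates,
at which the simulation SD of a 5% rejection rate is ≈0.005. Tolerances on
binomial checks are 99% central intervals computed from `scipy.stats.binom`.
All file outputs are deterministic under the run seed (gzip members written
with zeroed mtime).

## Known limitations

- Headline numbers from real aligner benchmarks (e.g. minimum MCC across a
  real titration series, fold reductions in FN counts) are properties of
  those tools and references; the toolkit reproduces the *procedures*, and
  its simulated remover recovers whatever rates it is configured with.
- No long-read formats, interleaved FASTQ, or BAM/CRAM ingestion.
- The substitution-only error model cannot exercise indel-sensitive
  behaviour of real removers.
- ROC/PR analysis is absent by design: the removal contract is not
  threshold-parameterized.
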