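# Methods

## Scope and data model

The package operates on per-sample somatic mutation calls in MAF conventions
(1-based inclusive coordinates, `Tumor_Seq_Allele2` as the alternate allele),
a reference sequence (FASTA, an open `pyfaidx.Fasta`, or an in-memory
`{contig: string}` mapping), and genes × samples expression tables on the
log2 scale.  Every SNV is reduced to its pyrimidine-strand canonical form:
records with a purine reference (A/G) are reverse-complemented together with
their flanking bases, mapping each substitution to one of 96 channels.  The
channel ordering is substitution-major (C>A, C>G, C>T, T>A, T>C, T>G) with
the 16 upstream × downstream contexts in A/C/G/T lexicographic order per
block — the de-facto ordering of published SBS catalogs, so user-supplied
96-row tables align row-wise.

Records that cannot participate in motif analysis are excluded and tallied,
never silently repaired: reference-mismatching calls (the stated reference
allele disagrees with the genome) are flagged and dropped from motif counts;
N-context and non-SNV records are skipped with a running exclusion count.
Silent "fixing" of alleles would corrupt motif statistics.

## APOBEC enrichment score

For a sample's C>T and C>G SNVs (pyrimidine-normalized; C>A never counts),

    AMES = [ n_TCW / n_C ] * [ nC_bg / nTCW_bg ]

- `n_TCW`: mutations whose canonical triplet is T-C-W (W ∈ {A, T});
- `n_C`: all counted C>T/C>G mutations;
- `nC_bg`, `nTCW_bg`: cytosines (C or G on the forward strand) and TCW/WGA
  motif starts within ±`window` bp of each counted mutation (default 20),
  windows truncated at contig ends, motifs required to lie fully on the
  contig.

Background windows are **summed per mutation**: overlapping windows of
clustered mutations contribute once per mutation, not once per base.  The
statistic is a per-mutation background weighting; unioning windows would
under-weight clustered mutations.  The mutated base itself lies inside its
own window, so the central cytosine (and, for TCW-context mutations, its own
motif) is part of the background tally.  This is the classical construction
and it carries a small, quantifiable consequence: background windows are
centered on a guaranteed cytosine, so they are slightly C-enriched relative
to the genome at large, and the **null expectation of AMES is ≈ 1.05 rather
than exactly 1** for uniform cytosine mutagenesis on a 50% GC reference
(site-averaged calculation and Monte-Carlo agree; the unit suite checks the
simulated mean against the genome's own site-averaged expectation rather
than against 1).  Users comparing cohorts against the conventional cutoffs
(1 and 2) should be aware that "1" is an idealization of "no enrichment".

Undefined scores (no counted C mutation, or zero background motifs)
propagate as missing values, never as 0, since a zero score is a meaningful
"no TCW mutations" observation.  Stratification uses left-closed cutoffs
(score = 1 → "M", score = 2 → "H"); cutoffs and labels are configurable
(e.g. a <1 vs >4 contrast), and a minimum counted-mutation floor can
suppress scores for sparsely mutated samples (off by default).

## Mutational signatures

`build_context_matrix` tallies usable SNVs into a samples × 96 count matrix.
Factorization uses scikit-learn's NMF with multiplicative updates under the
generalized Kullback–Leibler objective — the standard choice for count
data — with `restarts` random initializations per rank (default 10 in the
library, 30 in the CLI); the best-objective factorization is kept.  Profiles
are column-normalized to sum 1, with the scale absorbed into exposures.  An
ARD/Bayesian NMF variant would select rank automatically, but its
hyperparameters are not part of this package's contract; rank selection is
instead delegated entirely to the consensus procedure below, which is also
what it would be validated against.

**Rank selection.**  Each restart assigns every sample to its dominant
signature; the consensus matrix holds the fraction of restarts in which two
samples co-assign, and the cophenetic coefficient correlates consensus
distances (1 − consensus) with the average-linkage dendrogram distances
derived from them.  "Begins to drop significantly" is operationalized as the
first successive drop exceeding `drop_threshold` (default 0.05); the
selected rank is the one immediately before that drop, falling back to the
argmax (ties toward smaller rank) when no drop qualifies.  Degenerate cases:
rank 1 is defined to have cophenetic 1; an all-zero consensus distance
matrix is 1; a constant nonzero one is 0.  The consensus needs enough
restarts to expose initialization variability — with very few restarts an
underfitting rank can look perfectly stable because every restart finds the
same merged local optimum, which inflates its cophenetic value; 30 restarts
is a sensible default at 96-channel scale.

**Annotation and exposures.**  De novo profiles are labeled with the
best-cosine catalog entry (ties to the earlier column), "unassigned" below
`min_cosine = 0.8`, similarity reported to 3 decimals.  Exposures solve
per-sample NNLS (`min ||v − P h||, h ≥ 0`, active-set solver); with
column-stochastic profiles the exposures are in mutation-count units.  A
small synthetic catalog ships for tests and demos (APOBEC-like TCW C>T and
C>G profiles, a CpG-deamination-like C>T profile, a T>G-heavy profile, and a
flat background); it is constructed, not measured, and users supply real
catalog tables (same 96-row shape) for real analyses.

## Burden, DDR, co-occurrence

TMB = non-synonymous mutations / 38 Mb (configurable exome size).  The
non-synonymous vocabulary is the MAF list (frame-shift and in-frame indels,
missense, nonsense, nonstop, splice site, translation start site, with
`_Mutation`-suffixed aliases); unknown terms fall through to synonymous with
a warning.  "Non-silent" in the DDR rule is equated with this same list —
the two phrases are used interchangeably in practice.  A DDR pathway is
mutated if any of its genes carries a non-synonymous record; the sample is
DDR-Mut if any pathway is.  The bundled pathway map contains only the ten
frequently mutated DDR genes with unambiguous published pathway assignments
(ERCC2/EP300/POLE/INO80 → NER, ATM/BRIP1 → HRR, ATR → FA, SETD2 → MMR,
PRKDC → NHEJ, REV3L → TLS) and is deliberately partial; real analyses should
supply a full map (TSV: pathway, gene).

Co-occurrence testing collapses per-sample per-gene hits to binary presence
(the standard somatic-interaction convention), skips genes mutated in fewer
than `min_mutated = 3` samples, applies a two-sided Fisher exact test per
pair, and adjusts with Benjamini–Hochberg across all tested pairs.
Direction is co-occurrence at odds ratio ≥ 1, exclusivity below.

## Expression scores

ssGSEA per sample: rank genes by expression descending (ties broken by the
stable input gene order — the published description is silent on ties, so
the rule is fixed and documented); gene at descending position *i* of *N*
gets rank value *N − i*; the enrichment score is Σ over the ranked list of
(weighted in-set ECDF − uniform out-of-set ECDF) with in-set weights
rank^alpha, alpha = 0.25.  Raw scores are returned by default; optional
normalization divides each set's scores by their max − min across samples.
The construction is rank-based, hence exactly invariant to per-sample
monotone transforms.  A set equal to the whole matrix leaves the out-of-set
ECDF empty (defined as 0).

CYT = sqrt((PRF1 + ε)(GZMA + ε)) on linear TPM with ε = 0.01 (log2 input is
back-transformed as 2^x − 1).  Linear signatures are applied on the log2
scale as Σ coef(g)·expr(g, s); absent genes contribute 0 with a warning;
the default split is at the cohort median (score > median → "high").  Gene
membership and coefficients (e.g. an 18-gene T cell-inflamed panel or a
21-gene prognostic panel) are data inputs, not package constants.

## Synthetic data generator

The generator exists so that every stage has a testable ground truth:

- `gen_reference`: i.i.d. bases with P(C) = P(G) = gc/2 (default length
  10 kb, GC 0.5) — no replication timing, chromatin, or regional composition
  structure.
- `plant_mutations`: per mutation, with probability *w* a uniform
  TCW-context cytosine (either strand), else a uniform cytosine; C>T or C>G
  with equal odds; positions without replacement per sample (defaults: 50
  samples × 200 mutations).  The background process draws **cytosines
  only**: AMES concerns C>T/C>G fractions, and an all-base background would
  dilute counts without moving the null.  At *w* = 0 the mutated-motif
  fraction matches the genomic C-site motif fraction, giving the ≈1 null
  (with the ≈ +5% window-centering offset discussed above); at *w* = 1 every
  counted mutation is in TCW.  Records default to a single Missense class so
  burden/DDR tests stay orthogonal; a class-mixing option and a gene-pool
  option exist for annotation tests.
- `sim_signature_counts`: multinomial draws from P·h per sample — sampling
  noise only, no sequencing artifacts or cohort covariates.
- `sim_expression`: per-gene Normal(5, 2) baselines, i.i.d. Normal(0, 1)
  cell noise, a +2 log2 shift on a 25-gene set in one of two 20-sample
  groups — no gene–gene correlation, batch structure, or heavy tails.

Because these emulations are deliberately minimal, passing recovery tests
demonstrates correctness of the *computations* under the stated statistical
model, not robustness to the messiness of real cohorts (alignment artifacts,
subclonality, expression normalization differences).

## Problem sizes and numerical choices

The test and acceptance runs use 10 kb references, 50–200 samples, 100–200
mutations per sample, 60 samples × 2,000 mutations for signature recovery
(10 replicates, ranks 2–5, 30 restarts), and 20 replicates for expression
recovery — sizes at which every expected value is either exactly computable
or tightly concentrated.  NMF runs with `max_iter = 2000`, `tol = 1e-6`;
per-(rank, restart) seeds derive deterministically from one master seed, so
identical inputs give bit-identical outputs.  NNLS uses the classical
active-set solver; cross-checks compare against an independent bounded
least-squares route.  Fisher p-values follow the conventional two-sided
definition (sum of table probabilities not exceeding the observed, with a
1 + 1e-7 relative slack); degenerate margins give p = 1.

## Known limitations

- The AMES null offset (≈ +5% at GC 0.5, window 20) described above is a
  property of the windowed background construction, not a bug; it shrinks
  with window size and is irrelevant to between-sample comparisons at fixed
  window.
- Only SNVs enter motif and signature analyses; indels are carried for
  burden/DDR only.  No transcriptional-strand channels, no multi-cohort
  joint extraction, no driver detection or survival model fitting (risk
  scores are consumed, not fitted).
- The bundled DDR map and SBS catalog are starters/synthetic stand-ins;
  conclusions about real cohorts require the user's curated versions.
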