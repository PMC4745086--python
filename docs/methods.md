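# Methods

This note records the models and procedures snailnet implements, the
defaults and why they were chosen, the numerical decisions, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Assembly statistics

N50 is computed by sorting lengths in descending order and returning the
first length at which the cumulative sum reaches at least half the total
(inclusive `≥`, so the bound "sequences of that length or longer contain
at least half of the total" holds with equality cases included). Mean
length is rounded to the nearest integer with ties away from zero; this
convention reproduces standard assembly-report tables in which, e.g.,
99,427,155 nt over 413,539 contigs prints as a mean of 240 nt.

## Protein-coding prediction

Candidates are maximal stop-free codon runs in all six reading frames —
stop-to-stop, with no ATG requirement, because assembled unigenes are
frequently 5'-truncated and requiring a start codon would systematically
truncate or discard genuine coding sequence. Runs left open at the 3' end
(no closing stop before the sequence ends) are valid candidates; trailing
partial codons are ignored. Codons containing N translate to `X`, and `X`
never terminates a run: ambiguity is not evidence of a stop. The single
longest candidate is selected; predictions shorter than `min_orf_aa = 30`
amino acids are discarded, the conventional floor below which "protein"
predictions on assembled transcripts are mostly noise. Equal-length ties
are broken deterministically by frame order +1, +2, +3, −1, −2, −3, then
by smallest forward-strand start, so repeated runs are byte-identical.
Coordinates are always reported on the forward strand, 0-based half-open,
making `seq[start:end]` (reverse-complemented for negative frames)
re-translate exactly to the stored protein — an invariant the test suite
asserts on random sequences.

## FPKM

`FPKM(g) = C·10⁹ / (N·L)` with `C` the fragments uniquely aligned to gene
*g*, `N` the total uniquely aligned fragments and `L` the gene length in
bases. The 10⁹ constant is the standard per-kilobase (10³) × per-million
(10⁶) scaling. FPKM is used for reporting; the differential-expression
test operates on raw counts, which the negative-binomial model requires.

## Differential expression without replicates

With one library per condition, a per-gene variance cannot be estimated
within conditions. The test therefore follows the classic DESeq blind
construction:

1. **Size factors** by median-of-ratios: factor_j is the median over
   genes (restricted to rows positive in every sample) of
   counts[g,j] / geometric-mean(counts[g,·]). This equalises sequencing
   depth without letting a few highly expressed genes dominate, as a
   total-count ratio would.
2. **Blind dispersion.** Treating the two conditions as replicates, the
   per-gene method-of-moments dispersion is
   `(var(q) − mean(q)·mean(1/s)) / mean(q)²` on normalised counts
   `q = k/s` (the subtraction removes the Poisson shot-noise component).
   The mean–dispersion trend `α(μ) = a₀/μ + a₁` is fitted by ordinary
   least squares of raw dispersion against 1/mean over genes with
   normalised mean ≥ 1 (below that, the moment estimates are dominated by
   discreteness). Predictions are floored at `α_min = 10⁻⁸`: the floor
   keeps the NB size parameter finite while being far below any
   biologically meaningful dispersion. Genuinely differential genes
   inflate this trend, so the resulting test errs conservative — the
   correct failure direction when replication is absent.
3. **Exact test.** Conditional on the total `k_S = k_A + k_B`, the
   two-sided p-value sums the probabilities of all splits `(a, k_S−a)`
   whose joint NB probability (means `s_A·q̂`, `s_B·q̂` with
   `q̂ = k_S/(s_A+s_B)`; variance `μ + α(q̂)·μ²`) does not exceed the
   observed split's, normalised by the total. `k_S = 0` returns p = 1.
   For totals above 20,000 the summation is windowed to ±40 conditional
   standard deviations around the mean (always including the observed
   split), discarding < 10⁻¹² of the mass.
4. **Calls.** Benjamini–Hochberg q-values across all tested genes; a gene
   is `up`/`down` only when q < 0.05 **and** |log₂ fold change| > 1, the
   standard paired threshold for no-replicate designs. The fold change is
   `log₂((k_B/s_B + 0.5)/(k_A/s_A + 0.5))`; the 0.5 pseudo-count keeps
   one-sided zeros finite while preserving direction.

In the Poisson limit (α → 0, equal size factors) the test reduces to a
two-sided exact binomial(k_S, ½), which the suite uses as an independent
oracle.

## Annotation transfer

"Most similar protein" is interpreted as the hit with minimal E-value —
E-value being the cutoff currency of the whole pipeline — with ties
broken by larger bit score, then lexicographically smallest subject id.
Domain assignment keeps hits at E < 10⁻⁵ and deduplicates accessions per
protein. Pfam accession version suffixes (`PF13465.1` → `PF13465`) are
stripped at parse time because domain-interaction resources key their
records by unversioned accessions; every downstream join is unversioned.
GO/KEGG/COG attachment is a join of best-hit subject ids against
user-supplied subject→term tables; the upstream annotation pipelines that
produce those tables are out of scope.

## Interactome inference and topology

An edge (p, q), p ≠ q, exists iff some domain of p and some domain of q
form an unordered pair in the DDI table. Self-loops are excluded: a
self-interacting domain justifies edges between distinct proteins
carrying it, not a protein–self edge, and the simple-graph convention is
what the downstream topology metrics assume. Multiple supporting domain
pairs accumulate as edge evidence rather than parallel edges. Which DDI
confidence classes to accept is exposed as an option; the default accepts
all classes.

The power-law exponent of `P(k) ~ k^-b` is the negated slope of the
least-squares line of log₁₀ P(k) on log₁₀ k over degrees with nonzero
count — the convention of the widely used network-analyzer tooling this
mirrors, chosen for comparability; a zeta-normalised discrete MLE
(k_min = 1) is available via `method="mle"` for users who prefer a
principled estimator. The topological coefficient of node n is the mean,
over nodes m sharing at least one neighbor with n, of
(|shared neighbors| + 1 if adjacent), divided by degree(n). Betweenness is
standard shortest-path betweenness, reported as unnormalised pair counts
by default (a flag enables (n−1)(n−2)/2 normalisation). Shortest-path
histograms count unordered reachable pairs once.

## Steiner subnetworks

Connecting a seed-gene set through the interactome is a Steiner-tree
problem (NP-hard), approximated by the Takahashi–Matsuyama shortest-path
heuristic with unit edge weights: seed the tree with the smallest-id
terminal, then repeatedly attach the terminal nearest to the current tree
via one shortest path. BFS processes nodes in sorted order and the
nearest terminal is chosen by (distance, id), so results are
deterministic. The heuristic is a 2-approximation; the suite verifies the
2× bound against an exhaustive optimum on every connected graph with ≤ 7
nodes. Terminals absent from the network are dropped and reported;
terminals spanning several components yield one tree per component (a
forest) with a warning, since seed lists routinely contain genes outside
the network's giant component. Hub nodes of a subnetwork are its members
ranked by degree in the *parent* network — tree degrees are
uninformative by construction.

## Enrichment statistics

Fisher's exact test is computed from hypergeometric log-probabilities via
log-gamma, summing (two-sided) all tables with probability ≤ the observed
table's (with a 10⁻⁷ relative tolerance against floating-point ties, the
same guard scipy uses) or (one-sided) the upper tail. Log-space
arithmetic is mandatory at genome scale: the worked two-set comparison in
the test suite (5,098/83,697 vs 3,230/102,971) has p ≈ 10⁻²⁰⁶, far below
what factorial arithmetic survives. Set-vs-background over-representation
is one-sided; the two-set frequency comparison is two-sided — matching
how each question is posed. "Corrected p-value" means Benjamini–Hochberg
throughout: no other procedure is implied anywhere in the pipeline's
vocabulary, and BH is the field default for pathway enrichment.

## Synthetic data

The generator emulates the *post-assembly* state of a three-tissue
transcriptome study at desk scale, with every stage's ground truth
recorded:

- **Unigenes** (default bundles: 100 genes, ids mixing `CL*.Contig1`
  cluster and `Unigene*` singleton prefixes) carry one planted ORF each;
  30% are planted below the 30-aa retention threshold (5–29 aa), the rest
  at 30–80 aa. Planting is by rejection sampling: codons and flanking
  stop-enriched context are redrawn until an internal brute-force
  six-frame scanner (independent of the production ORF finder) confirms
  the planted run is the strict six-frame maximum (coding genes) or that
  every run is below 30 aa (sub-threshold genes). The truth is therefore
  unambiguous by construction.
- **Domain hits** draw 1–3 domains per coding protein from a
  12-accession Pfam pool, E-values 10⁻⁵·²–10⁻³⁰, 40% of proteins get a
  decoy row above the cutoff; accessions are written versioned to
  exercise version stripping. **DDI tables** sample ~25% of the pool's
  unordered pairs (self-pairs included); the true network is derived by
  an exhaustive O(n²) all-pairs join, independent of the production
  builder.
- **Counts** are negative binomial with dispersion α = 0.05 (a typical
  bulk-RNA-seq value), gene means log-uniform on [50, 500], and 10% of
  genes planted differential at |log₂ fold change| = 2, half up, half
  down. α = 0 is rejected — Poisson behaviour is requested via a tiny
  positive dispersion.
- All randomness derives from one seed through fixed sub-stream labels,
  so bundles are byte-identical across regenerations and adding a new
  generator never perturbs existing outputs.

What the generator does **not** emulate: read-level sequencing error,
length-dependent count bias, isoform redundancy, homology structure
between genes, realistic (scale-free) network topology — the 12-domain
pool makes toy networks far denser than a real interactome — or
database-scale annotation coverage. Passing the truth-recovery tests
therefore demonstrates the correctness of the parsing, joining, selection
and testing machinery under the stated models, not performance on real
libraries; the no-replicate test's operating characteristics on real data
depend on how well the blind-dispersion assumption holds there.

## Problem sizes and determinism

The statistical suites use 2,000-gene simulations for the DE null and
power checks, 1,000 replicates of 100 p-values for BH false-discovery
control, 500 replicates for enrichment-null uniformity, and the full
graph atlas (all connected graphs on ≤ 7 nodes) for the Steiner bound —
sizes at which every quoted operating characteristic is stable across
seeds. All tests are seed-fixed; hypothesis-based property tests run
derandomised.

## Known limitations

- Two-condition, single-library designs only; no multi-factor models, no
  replicate-aware shrinkage.
- The dispersion trend is a two-parameter hyperbola fitted by unweighted
  least squares; a handful of extreme moment estimates can tilt it
  (mitigated by the mean ≥ 1 gene filter, and conservative in effect).
- The least-squares power-law fit is a comparability choice, not a
  recommended estimator for new analyses; use `method="mle"` when the
  exponent itself is the inference target.
- Edge-TSV network output cannot represent isolated nodes (SIF and
  GraphML can).
- The exact-test windowing for totals > 20,000 discards < 10⁻¹² of
  probability mass; p-values that small are reported at that fidelity,
  not exactly.
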