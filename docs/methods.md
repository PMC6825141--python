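# Methods

This note documents the models, statistics and design choices behind
`tautx`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic-data experiments do and do not
demonstrate.

## Tissue-specificity index (tau)

For a gene with expression x_i across n tissues,

    tau = sum_{i=1..n} (1 - x_i / max_j x_j) / (n - 1).

tau = 0 for perfectly uniform expression and approaches 1 when expression
is confined to a single tissue. Inputs are TPM, floored at 2 before
normalisation to damp sampling stochasticity in tissues with little or no
detected expression; because of the floor the attainable maximum is
1 − floor/max rather than exactly 1. tau is computed on raw floored TPM by
default; a `log2` variant (tau on log2(TPM+1)) is available since both
conventions appear in the tissue-specificity literature. Genes with
tau < 0.3 are classed *broad* (the housekeeping regime), tau > 0.8 *high*
(tissue-specific), and the closed interval [0.3, 0.8] *moderate*, so the
three classes partition [0, 1]. The broad/high regimes are calibrated by a
two-sample Kolmogorov–Smirnov test comparing the most abundant unique gene
per tissue against a housekeeping panel (SDHA, UBC, GAPDH, RPL4, HMBS,
ACTB).

"Summed expression" on the specificity–expression correlation is
log10(sum over tissues of TPM + 1); the alternative reading
(sum of per-tissue log TPM) is not the default because it is dominated by
the tissues where a gene is absent.

Per-tissue summaries assign each gene to its maximal-expression tissue
(ties go to the first tissue in the configured order and are flagged) and
report mean tau with a normal-approximation 95% CI (mean ± 1.96·SE; the CI
degenerates to the mean for singleton groups).

## Expression profiling

TPM is computed as 1e6·(c_g/L_g)/Σ_h(c_h/L_h) per tissue, so every column
sums to 1e6 (enforced to 1e-6 relative error). A transcript with TPM < 1
is called absent from a tissue; expression bins are low [1, 10),
medium [10, 50] and high (50, ∞). The bin boundaries at exactly 10 and 50
are assigned to medium — the conventional open-interval description leaves
them undefined, and inclusive-medium keeps the bins a partition. Exclusive
intersections count every present-somewhere gene in exactly one tissue
subset (its full presence pattern), the quantity an UpSet plot displays;
counts therefore sum to the number of present genes.

## Annotation confidence filtering

BLAST tabular hits are retained when e-value < 1e-10, percent identity
≥ 70 and coverage ≥ 0.5, where coverage is alignment length divided by the
*subject* (full-length protein) length — identity/coverage thresholds are
inclusive ("at least"), the e-value bound strict. Each transcript is
assigned the gene of its best surviving hit: lowest e-value, ties broken
by highest bit score, then lexicographically smallest subject id, making
the assignment fully deterministic.

Redundancy collapse follows the cd-hit-est recipe in outline: sequences
sorted by decreasing length, each joining the first cluster whose founder
shares estimated identity at or above the threshold (default 0.95), else
founding a new cluster. Identity is estimated by canonical k-mer
containment (k = 8): the fraction of the query's canonical 8-mers present
in the representative's. This is an overestimate-prone proxy for alignment
identity (a true substring scores 1.0); an optional `verify` flag
additionally requires a global-alignment identity (matched bases over the
shorter sequence) to clear the threshold. Full cd-hit short-word indexing
and banded heuristics are deliberately out of scope. N50 is the largest
length L such that contigs of length ≥ L cover at least half of the
assembled bases; GC% is computed over unambiguous A/C/G/T only.

## Orthology and the branch-site selection scan

**Similarity graph and MCL.** Nodes are (species, gene) pairs; edge
weights are −log10(e-value) capped at 200 (the e-value-zero convention).
Markov clustering adds self-loops at each node's maximum incident weight,
column-normalises, and alternates expansion (matrix squaring) with
inflation (elementwise power, default 1.5, with pruning at 1e-5 and
renormalisation) until the maximum entry change falls below 1e-6; clusters
are the attractor supports, merged when overlapping. Nodes are sorted
internally so the result is invariant to input order. The single-copy
filter keeps groups containing exactly one gene from every required
species and nothing else.

**Masking.** Codon columns whose gap fraction exceeds the threshold
(default 0: any gap) are removed, then surviving runs shorter than 5
codons are removed, in the style of GBlocks' block criterion; output
length stays divisible by 3 and a fully-masked alignment is an error.

**Codon model.** The substitution model is GY94-style over the 61 sense
codons: q_ij = 0 for multi-nucleotide changes, and otherwise pi_j times
kappa for transitions and omega for nonsynonymous changes. The matrix is
reversible with respect to pi (detailed balance holds exactly). Codon
frequencies default to F1x4 estimated from the alignment (with a
half-count pseudocount so pi stays strictly positive); equal and F3x4 are
options.

**Branch-site parameterisation.** Four site classes with proportions
(p0, p1, p2a, p2b), p2a = (1−p0−p1)·p0/(p0+p1) and p2b analogously:
class 0 evolves with omega0 ∈ (0, 1] everywhere, class 1 neutrally
(omega = 1), classes 2a/2b take omega0 (resp. 1) on background branches
and omega2 ≥ 1 on the single foreground branch (tagged `#1` in Newick, the
PAML convention). Under the null omega2 is pinned at 1. Per branch role
(foreground/background) the class rate matrices are jointly rescaled so
the class-proportion-weighted mean substitution rate at stationarity is 1;
branch lengths are therefore expected substitutions per codon averaged
over site classes, and the simulator uses the identical convention.

**Likelihood.** Felsenstein pruning over the 61 states, run as stacked
matrix products over the four classes jointly, with per-node rescaling of
partial likelihoods to prevent underflow; gapped or ambiguous codons
contribute unit partial likelihoods (missing data). Transition matrices
come from the symmetric eigendecomposition of the reversible rate matrix.
The pruning likelihood is verified against exhaustive marginalisation over
all internal-node codon assignments on small trees (agreement < 1e-8 in
log-likelihood).

**Optimisation and the LRT.** Parameters are fitted by bounded L-BFGS-B on
transformed scales (log kappa, sigmoid transforms for omega0 and the class
proportions, log(omega2 − 1) under the alternative, log branch scale),
with seeded restarts (default 3) and the alternative warm-started from the
null fit. By default branch lengths are re-optimised under each hypothesis
through a single multiplicative scale on the input gene-tree lengths
(`branch_mode="scale"`); per-branch optimisation (`"free"`) is available.
The rationale: per-gene input trees already carry their own ML branch
lengths, and the 6-parameter fit keeps replicate-level calibration
experiments tractable while preserving per-hypothesis re-optimisation.
LRT = 2(lnL_alt − lnL_null), clamped at zero; the p-value uses the
chi-square(1) reference by default — conservative, since the null places
omega2 on the boundary — with the ½chi²₀ + ½chi²₁ mixture as an option.
The scan runs per gene on that gene's own tree (robust to gene-tree
discordance from incomplete lineage sorting), once per aligner variant;
per-variant p-values receive Benjamini–Hochberg correction and the final
gene list is the intersection of the per-variant significant sets
(q < 0.05), which suppresses alignment-induced false positives.

## Enrichment and comparative statistics

GO overrepresentation is one-sided: per term with at least 3 *study* genes
annotated (the stricter reading of the ≥3-gene rule, configurable), the
upper hypergeometric tail P(X ≥ k) is computed and BH-FDR applied across
tested terms. Terms are flat labels; no ontology propagation is performed.
Spearman correlation uses average ranks with either the t-approximation
(n − 2 df) or a seeded permutation test that switches to exhaustive
enumeration for n ≤ 8. The bootstrap comparison resamples each group with
replacement B times (default 10,000), reports percentile 95% CIs per group
and for the mean difference, and a two-sided sign-crossing p-value floored
at 2/B; it is bit-reproducible under a fixed seed. One-way ANOVA is
followed by Tukey's HSD over all group pairs.

## Steroidogenic panel

The default panel orders the sex-steroid cascade synthesis (StAR, P450scc,
CYP17, 3bHSD1) → conversion (SRD5A1, SRD5A2, AROM) → receptor (AR, ESR1,
ESR2, GPER1); symbol matching is case-insensitive with a user-extensible
synonym map (e.g. AROM ↔ CYP19A1) because annotation sources disagree on
names. Missing symbols are reported, never dropped. The stagewise trend is
the Spearman correlation of stage index against per-gene tau. 17bHSD
isoforms are clustered agglomeratively (complete linkage, Euclidean
distance on log2(TPM+1) profiles, default k = 2); complete linkage and the
log transform were chosen for determinism and robustness to the heavy
right tail of TPM — raw-TPM distance and other linkages are flags.

## Synthetic data: what it emulates and what it does not

The expression generator plants three gene classes in a 6-tissue panel
(brain, blood, ovary, spleen, liver, muscle): housekeeping genes
(near-uniform, high expression; true tau < 0.3 by construction),
tissue-specific genes (one dominant tissue; off-target leak ~0.05–0.1 TPM,
below the presence threshold; true tau > 0.8), and intermediate genes
(2–4 tissues at moderate levels). True TPM columns are normalised to 1e6;
counts are negative-binomial around TPM×length-proportional means with
library size 5e6 per tissue. The NB dispersion (alpha in
var = mu + alpha·mu²) defaults to 0.01: each tissue column models a single
pooled sequencing library, for which residual overdispersion beyond
Poisson is modest; with biological-replicate-level dispersion (alpha ~0.1,
CV > 30%) no gene would measure as uniformly expressed across tissues and
the housekeeping construction would be meaningless. Housekeeping genes are
placed at higher expression than tissue-specific ones, reproducing the
negative specificity–expression correlation seen in real tissue panels.
The generator does not emulate transcript-isoform structure, mapping
ambiguity, batch effects, or within-tissue cell-type mixtures — recovery
results demonstrate correctness of the pipeline's arithmetic and the
internal consistency of the tau regimes, not performance on real reads.

The codon simulator draws a site class per site, the root codon from pi,
and evolves each branch with exp(Qt) using the branch's
class-and-role-appropriate omega, sharing the likelihood code's scaling
convention; alignments are generated gap-free (gaps enter only through
masking tests), and no indels are simulated. Calibration experiments use
a symmetric 9-leaf fixture tree (focal terminal branch 0.2 expected
substitutions per codon, tagged as foreground; other terminals 0.1–0.15,
internals 0.05). The null arm simulates omega2 = 1 with p0 = p1 = 0.45;
the power arm simulates strong selection, omega2 = 4 with p0 = p1 = 0.35
(30% of sites in class 2), the effect-size regime used in published
branch-site power studies — at markedly smaller class-2 fractions the
branch-site LRT is known to have little power, which is a property of the
test, not of an implementation. Replicate counts are scaled to 40 + 40 in
the test suite and 30 + 30 in the acceptance script, sizes chosen so the
full suite runs in minutes on one core; at these sizes the type-I bound
and the ≥ 0.3 power separation are comfortably resolved.

## Numerical choices and degenerate inputs

Likelihood rescaling is per internal node and per class (log-scale
accumulators), so alignments of hundreds of codons on deep trees do not
underflow. Transition matrices are clipped at 0 and row-renormalised after
eigendecomposition to remove ~1e-16 negatives. Optimiser failures and
non-convergence are flagged on the result, never silently dropped; LRT
values in (−1e-4, 0) from optimiser tolerance are clamped to 0 and larger
negative values additionally clear the convergence flag. All-floored
expression rows get tau = 0 with a `no_expression` flag. Ties are broken
deterministically throughout (gene id, subject id, first-tissue order,
input row order).

## Known limitations

* The branch-site fit in `scale` mode cannot reshape a badly wrong input
  tree; genes with unreliable gene trees should use `branch_mode="free"`
  at ~3x the cost.
* Bayes-Empirical-Bayes identification of the selected *sites* is not
  implemented; the scan reports gene-level evidence only.
* k-mer containment identity saturates for repetitive sequences; enable
  `verify` when collapsing low-complexity transcript sets.
* GO enrichment treats annotations as flat labels; propagate up the
  ontology beforehand if DAG-aware testing is wanted.
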