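# Methods

## Model and procedure

`clustercore` identifies per-context core reaction sets from a
genes × contexts abundance matrix and a metabolic model's GPR rules,
in four stages.

**1. Enzyme expression.**  Every GPR rule is expanded to disjunctive
normal form; each AND-clause is one enzyme (canonical id: sorted gene
ids joined by `&`, deduplicated across reactions), OR-clauses stay
separate isoenzymes, and complex stoichiometry is ignored (it is not
curated for most reconstructions).  Enzyme expression in a context is
the minimum over the clause's genes — the scarcest subunit limits how
much functional complex can form.  By default an enzyme with any gene
absent from the data is dropped and reported (`missing_gene_policy=
"drop_enzyme"`), restricting analysis to genes present in both model
and data; `"treat_zero"` instead floors missing genes at zero.
Duplicate gene rows in the expression file are merged by elementwise
maximum before mapping.

**2. Profile clustering.**  Each enzyme's positive values are
log10-transformed and histogrammed over uniform bins spanning
[log10 min positive, log10 max] of the whole matrix; zeros are not
counted — the profile records in how many contexts, and at what
level, the enzyme is expressed.  Profiles are clustered
agglomeratively (Euclidean distance, complete linkage; both
configurable) and the tree is cut at N clusters.

**3. Cluster-specific thresholds.**  With μ_c, σ_c the mean/SD of
cluster c's pooled positive log10 values (all member enzymes ×
contexts) and M, Δ the same statistics for the whole matrix,

    θ_c = (σ_c − Δ)/max_c(σ_c − Δ) − (μ_c − M),

normalised affinely so min θ ↦ 0 and max θ ↦ 100.  The normalised
value Θ_c is a *top percentile* of the cluster's own pooled values: the
cutoff is the quantile at probability (100 − Θ_c)/100, and an enzyme
is active in a context when its log10 value is **strictly above** the
cutoff.  Θ_c = 100 is special-cased to the dataset mean M.  The two
terms implement one idea each: a cluster much tighter than the dataset
(σ_c ≪ Δ) is consistently expressed and earns a permissive threshold;
a cluster expressed below the dataset mean is not penalised for its
absolute level.  A reaction is core when ≥ 1 of its enzymes is active;
reactions named in a protected list (e.g. biomass) are appended to
every context's core.

**4. Extraction-method inputs.**  From the threshold distance
D = log10(x) − cutoff (log10 units): ubiquity U = 1 where D ≥ 0 and
1 − D/min(D) where D < 0, with min(D) the most negative entry of the
whole matrix, so U ∈ [0, 1] and exactly one enzyme-context pair
touches 0; reaction U = max over isoenzymes, −1 for gene-free
reactions, 1 for protected ones.  INIT weights are D/max|D| (enzyme
level, in [−1, 1]) summed over isoenzymes (sums are deliberately not
clipped); gene-free reactions weigh 0.  GIMME reuses that vector with
its activity threshold fixed at 1.  MBA's high/medium sets use a
multiplicative ±10% band around the back-transformed (linear-scale)
cutoff; a reaction with both a high and a medium enzyme counts as
high.  iMAT's non-core set is the catalog minus the core minus
gene-free reactions.

### Cluster-count selection

N is selected by core-list stability: for each candidate N the mean
(over contexts) Jaccard similarity between the core sets at N and
N + 1 is recorded, and the smallest N is chosen whose similarity
exceeds 0.90 *and stays above it for every larger N tested*.  If no N
qualifies the range maximum is returned with a warning flag.  The
mean-over-contexts aggregation (rather than pooled unions) keeps every
context's core equally weighted.

### Baseline schemes

* **global**: one cutoff, the top-25th-percentile value of all
  positive log10 values.
* **localT1** (`variant="methods"`, default): enzymes whose
  cross-context mean falls below the dataset's 25th-percentile value
  are inactive everywhere; the rest are active above their own mean.
  The `"results"` variant never unconditionally inactivates — each
  enzyme's cutoff is max(own mean, bound).  Both variants exist
  because the two published descriptions of this scheme disagree; the
  operational one is the default.
* **localT2**: as localT1 plus an upper bound — enzymes whose mean
  exceeds the dataset's 75th-percentile value are active in *every*
  context, including contexts where they measure zero.

Baselines operate on log10 values for internal consistency; the
dataset-level percentile bounds are rank-based and therefore identical
to linear-scale percentiles, but the per-enzyme means are log-scale
(geometric) means of the positive values.  An enzyme with no positive
values has no mean and is inactive everywhere.  On data where no
enzyme mean clears the upper bound, localT2 reduces exactly to
localT1.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `n_bins` | 60 | log10 bins | ~0.13 decades per bin over a typical 8-decade FPKM range |
| `distance`, `linkage` | euclidean, complete | — | standard agglomerative choices for count profiles |
| `jaccard_cut` | 0.90 | fraction | stability level for selecting N |
| `top_percentile` (global) | 25 | percent | conventional global cutoff |
| `lower_top_percentile` | 75 | percent | local schemes' unconditional-inactive bound |
| `upper_top_percentile` | 25 | percent | localT2's unconditional-active bound |
| `band` (MBA) | 0.10 | fraction | ±10% margin around the cutoff |
| `max_clauses` (GPR) | 256 | clauses | hard cap on DNF blow-up; real GPRs stay far below |
| `gini cutoff` | 0.24 | normalised GC | housekeeping call boundary |

## Numerical conventions

* "Top X percentile" always means the linear-interpolation quantile at
  probability (100 − X)/100 (numpy's default, type-7); activity is
  strict `>`, so Θ_c = 0 (cutoff = cluster maximum) activates nothing.
* Zeros are excluded from the log10 transform, binning, all μ/σ/M/Δ
  statistics and quantiles throughout.  In the threshold-distance
  matrix, zero expression is floored at one decade below the smallest
  positive value in the matrix (configurable) so it sits strictly
  below every data-derived cutoff.
* Degenerate inputs fall back with a `DegenerateDataWarning`: all
  σ_c = Δ sets the spread term to 0 for every cluster; a constant raw
  threshold vector maps every cluster to Θ = 100 (dataset-mean
  cutoff); a distance matrix with no negative entry yields all-1
  ubiquity; an all-zero distance matrix yields all-0 weights.  When
  every cluster is tighter than the dataset the spread term's
  denominator is negative; the formula is applied as written and a
  warning notes it (on clustered multi-decade data this situation is
  in fact typical, because Δ is dominated by between-cluster spread).
* The Θ = 100 comparison uses a 1e-9 tolerance; quantiles are taken
  over cluster values pooled across member enzymes and contexts, not
  per-enzyme summaries.
* Agglomeration tie-breaks follow the input row order; cluster labels
  are arbitrary but deterministic, and leaf order is not part of any
  contract.
* Gini coefficients are computed on linear-scale expression including
  zeros, with the small-sample n/(n−1) normalisation, via the sorted
  rank formula; all-zero genes are excluded and reported.
* Hypergeometric enrichment is upper-tail ("at least the observed
  count"); the population is the union of reactions carried by all
  clustered enzymes, and a reaction whose isoenzymes sit in several
  clusters counts in each of them.
* Jaccard of two empty sets is defined as 1 (identical contents) —
  relevant when comparing empty toy models.

## The synthetic data generator

`synthetic.generate_fixture` emulates a multi-context transcriptome
with planted expression-pattern clusters.  Genes in a cluster share a
per-context log10 factor ~ Normal(mean, sd_between) plus independent
per-gene noise (0.01 decades by default); the marginal per-gene
distribution is Normal(mean_log10, sd_log10) with
sd_between² = sd_log10² − noise².  The shared factor is what makes a
cluster a *pattern*: co-regulated genes rise and fall together, and an
AND-complex's minimum stays within its cluster's profile instead of
drifting below it.  Dropout is likewise drawn per context — a silenced
pathway is off for all its genes — at the cluster's marginal rate.
The catalog wires genes into single-gene enzymes, 2–3-subunit
AND-complexes, isoenzyme pairs (20% / 15% of 300 reactions) and 5%
gene-free reactions, cycling clusters so enzyme counts stay balanced;
complexes draw all subunits from one cluster, so every enzyme has a
well-defined planted label.

The default fixture (40 contexts, 4 × 50 genes) plants four regimes
chosen to be realistic for log10 FPKM data and to exhibit the
housekeeping mechanism: `high_variable` (mean 3.8, SD 0.80, 5%
dropout), `moderate` (1.2, 0.35, 10%), `housekeeping` (−0.3, 0.08, no
dropout) and `rare` (−0.65, 0.08, 50% dropout).  The rare cluster's
low mean hands it the largest raw threshold, so *it* — not the
housekeeping cluster — takes the Θ = 100 dataset-mean special case and
is excluded, while the housekeeping cluster lands just below 100 and
is captured in > 90% of contexts.  Because both low clusters are
tight, that ordering rests on the stable mean difference rather than
on noisy spread estimates, which keeps the fixture's behaviour
reproducible across seeds.

`synthetic.selection_fixture_spec` provides a second layout for
exercising the cluster-count rule: K tight, well-separated clusters in
which the mid-scale cluster carries the largest within-cluster noise.
Cutting the tree deeper than K then splits that cluster first, and
since its threshold sits mid-scale the core lists barely move — the
stability trace crosses 0.90 exactly at K.  On the default fixture the
rule is noisier: when the lowest-mean (Θ = 100) cluster splits, one
half flips from the dataset-mean cutoff to a near-top-0 percentile,
a large relative change when only 4 clusters exist.  With realistic
cluster counts (dozens) that flip touches a small fraction of the
core, which is why the selection rule is useful at scale but is
demonstrated here on the dedicated layout.

What the generator does **not** model: read-count noise
(negative-binomial sampling), gene-length or library-size artefacts,
between-sample normalisation issues, genes shared between clusters,
and real-genome GPR topology.  Passing tests on these fixtures
therefore demonstrates correctness of the algorithms and the
qualitative capture mechanism, not performance on any particular real
dataset.

## Design choices

* GPR parsing is delegated to cobrapy's parser; the DNF expansion,
  deduplication and clause cap are implemented here.  DNF clauses are
  deduplicated exactly but *not* logically absorbed (`a or (a and b)`
  keeps both enzymes): OR-clauses are biological isoenzymes, not
  boolean redundancy.
* Gene identifiers match exactly by default; a `case_fold` flag
  handles case-mismatched resources.
* min(D) in the ubiquity decay and max|D| in the weight scaling are
  taken over the entire matrix (all enzymes × contexts), which
  guarantees the stated ranges.
* The MBA band is multiplicative on the linear abundance scale
  ("110% of the threshold") with an optional log-scale (±band
  decades) flag.
* The pipeline writes every stage artifact plus a manifest carrying
  the package version, the full configuration and its hash;
  deterministic stages reproduce byte-identically from the same
  config and seed.

## Limitations

* The method needs *many, diverse* contexts: with few or homogeneous
  contexts the binned profiles carry little information and a global
  threshold can be the sounder choice.
* Cluster-specific thresholds inherit the clustering's failure modes;
  with complete linkage a single outlying profile can redraw a cut.
  The selection rule mitigates but does not remove this.
* The extraction algorithms themselves (fastCORE, iMAT, MBA, mCADRE,
  INIT, GIMME), flux-consistency checking and exometabolomic
  constraint construction are out of scope — this package produces
  their inputs.
* GIMME's fixed activity threshold of 1 on a weight vector scaled into
  [−1, 1] leaves almost no sub-threshold structure; it is implemented
  literally as specified for compatibility.
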