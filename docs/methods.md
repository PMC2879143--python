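# Methods

## Scope and data model

protmap analyzes protein-by-sample spectral-count matrices with a sample
design of condition (disease/control) and stage labels. Counts are
nonnegative; raw inputs are integers, normalized values real. All gene-set
work happens in one flat identifier namespace: cross-type conversion
tables (e.g. accession → gene) are applied with the same two-column
mapping machinery as orthology tables.

## Length-bias correction

Spectral counting over-counts long proteins because they expose more
observable tryptic peptides. The correction divides each protein's counts
by its expected-peptide number: the count of *distinct* peptides produced
by in-silico trypsin digestion (cleave C-terminal to K/R unless followed
by P; X is never a cleavage site) whose length lies within the observable
window. Defaults: window [6, 35] residues, 0 missed cleavages — typical
LC-MS/MS observability settings; both are configuration-exposed because
instrument setups differ. A protein whose digest yields no in-window
peptide keeps a divisor of 1 (with a warning) so it stays in the analysis
rather than dividing by zero. Digestion itself is delegated to
`pyteomics.parser.cleave`; the test suite checks it against an independent
brute-force enumeration.

## Cross-sample lowess normalization

Residual per-sample differences (loading, run-to-run drift) are removed on
the log2 scale with pseudocount 0.5 (so zeros are admissible). The
reference is the per-protein mean of log2 values across samples — a
geometric mean on the pseudocounted scale; the standard MA regression
fits M = log2(sample) − log2(reference) on A = (log2 sample + log2
reference)/2 with a lowess smoother (default span 0.4, statsmodels'
robustifying iterations) and subtracts the fit. Values are
back-transformed and clipped at zero; entries that were exactly zero stay
zero.

Numerical property worth knowing: lowess-subtract is a *contraction*, not
a projection. A second application re-finds trend of magnitude roughly
sd/√(span·n) — the smoother's response to residual noise — i.e. a
median relative value change on the order of 1% here, never machine
epsilon. On discrete low-count data the fit-subtract fixed point is not
even stable under iteration, so the implementation deliberately performs a
single pass. The test suite asserts the contraction property (second pass
changes values an order of magnitude less than the first) rather than
exact idempotence.

## Signed KS ranking

Per protein and stage, the two-sample Kolmogorov–Smirnov statistic
compares ≥2 disease vs ≥2 control replicate values; D is the maximum
vertical ECDF distance (scipy, asymptotic p by default, exact mode
available). The ranking score is sign(mean difference) · (−log10 p),
capped at ±16 when p underflows: signed, monotone in significance, and
assumption-free about the count distribution. With few replicates D is
discrete, so scores tie frequently; ordering is made strict by descending
score, then descending D, then protein id. Swapping condition labels
negates every score and reverses the score sequence exactly; id order
inside tied groups follows the same deterministic tie-break in both
directions.

## Gene-set assembly

GMT collections are concatenated with ontology-derived sets: gene→term
annotations are up-propagated to all ancestors along the supplied
child→parent (is_a) structure — the transitive closure; this is idempotent
and only grows annotation sets. Each term then becomes one gene set.
Orthology mapping replaces each member by all of its targets (one-to-many
expands fully, preserving detectability; unmapped members and emptied sets
drop, with counts logged). Size filtering keeps sets with effective size
s, min < s ≤ max (defaults 15 and 500): small sets are noise-prone, huge
ones uninterpretable. Effective size is computed after intersecting with
the quantified-protein universe — the filter then reflects what the test
actually sees; raw-size filtering is available by passing no universe.

## Enrichment statistic and its null

The running sum over the ranked list increments by |score|ᵖ / Σ_hits
|score|ᵖ at member positions and decrements by 1/(N − n_hits) elsewhere;
ES is the maximum-magnitude deviation (first such position on ties), and
the leading edge is the members at or before (ES>0) / at or after (ES<0)
the extremum. Weight p defaults to 1 (score-weighted); p = 0 gives the
unweighted KS-like form. A set whose members all carry score 0 under p>0
has undefined weights and falls back to p = 0 with a warning and a
degenerate flag. The main-path running sum is computed by a strictly
sequential scalar scan so it is bit-identical to step-by-step enumeration;
vectorized reductions would reorder floating-point additions.

The null model is gene-set permutation: random same-size member subsets
drawn without replacement from the ranked universe — appropriate when
replicate counts are too small for phenotype permutation. Each set gets
its own substream derived from (master seed, crc32 of the set name), so
results are independent of collection order and stable across processes.
Per set: p = (1 + #{same-sign null ES at least as extreme}) / (1 +
#{same-sign nulls}) (add-one: never zero at finite permutations);
NES = ES / mean |same-sign null ES|. FDR: every null ES is normalized by
its own distribution's same-sign mean, pooled across sets; for each
observed NES*, q = [same-sign pooled null fraction ≥ |NES*|] / [same-sign
observed fraction ≥ |NES*|], capped at 1 and monotonized within each sign
by a cumulative minimum from the least to the most extreme NES. Defaults:
1000 permutations (≥100 enforced), significance working point p < 0.01 and
FDR < 0.1.

The sign conditioning plus the discreteness of KS-based scores makes the
nominal p slightly conservative; on fully null synthetic data the
measured fraction of sets at p < 0.05 is ~0.035–0.045, within the pooled
binomial 99% band.

## Enrichment Map

Nodes are sets significant in at least one phenotype (OR rule — a
stage-specific set appears with the other ring neutral/white); each node
carries both phenotypes' p/FDR/NES and significance flags as attributes,
so renderers can map phenotype 1 to the node center and phenotype 2 to the
border (red up, blue down, intensity by |NES|). Edges join pairs with
overlap coefficient |A∩B|/min(|A|,|B|) strictly greater than 0.5 (the
strict reading of the ">0.5" rule; threshold configurable), computed by
default on memberships restricted to the ranked universe so displayed
similarity matches what was tested (raw-membership mode available).
Layout: per-connected-component seeded spring embedding, components packed
left-to-right with a unit gap so bounding boxes stay disjoint; a lone node
sits at the origin. Exports: GraphML, GML, and node/edge TSV tables that
round-trip losslessly; term-cloud summaries are case-folded, stop-word-
filtered word frequencies over set names and descriptions with
lexicographic tie-breaks.

## Synthetic experiments

The generator emulates what matters to this pipeline: per-protein
log-normal baseline rates (median 0.4 counts per expected peptide,
σ = 1.0) multiplied by the protein's expected-peptide count (lengths
log-normal, median 350 aa, σ = 0.5; residues drawn at natural amino-acid
frequencies so tryptic-site density is realistic), per-sample log-normal
depth factors (σ = 0.15) that the lowess step must remove, and Poisson
sampling — the undersampled, zero-inflated regime of spectral counting.
Optional Gamma mixing adds over-dispersion. Planted sets multiply their
members' disease-sample rates by a fold change in the affected stage(s)
only, so stage-specific and shared perturbations both occur. The canonical
configuration — 2000 proteins, 4 replicates/condition, 2 stages, one up-
plus one down-regulated 50-member 2-fold set per stage, 48 null sets of
20–100 members, 1000 permutations — recovers all planted sets at the
p < 0.01 / FDR < 0.1 working point in well under a minute on one CPU.

What the generator does **not** emulate: peptide-to-protein inference
ambiguity (shared peptides), identification error, correlated biological
co-regulation outside the planted sets, and batch structure beyond a
scalar depth factor. Passing the recovery tests therefore demonstrates the
statistical machinery under the stated count model, not robustness to
those real-data complications.

The ontology fixture builds a complete rooted tree with `depth` total
levels (depth 1 = a lone root; depth 3, branching 2 = 7 terms with 3-term
leaf closures), optionally adding extra child→parent links to create
diamonds, and records the ground-truth closure.

## Determinism and problem sizes

One master seed drives everything: the generator, the per-set permutation
substreams, and the layout. Reruns with the same configuration reproduce
all numeric outputs byte-for-byte (checked in the pipeline tests). The
test suite and acceptance script use desk-scale problem sizes — the
canonical 2000-protein experiment, 500-protein/200-permutation null
calibration series over 20 seeds, exhaustive oracle checks at list length
≤12–15 — chosen so the whole suite completes in well under a minute while
each check still exercises the full code path.

## Known limitations

- Replicate-based KS on 3–4 samples per group is coarse (few distinct D
  values); the score is honest about this but cannot distinguish proteins
  within the same tie class.
- Gene-set permutation calibrates against random member sets, not
  inter-gene correlation; FDR on strongly co-regulated null sets will be
  optimistic, as for any gene-set-permutation GSEA.
- The asymptotic two-sample KS p-value can hit 0 at tiny sample sizes
  (fully separated 4v4 groups); scores are capped at ±16 and exact-p mode
  is available.
- Up-propagation traverses only the parent links present in the supplied
  ontology structure (is_a); part_of-style relations are propagated only
  if encoded as parent links by the caller.
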