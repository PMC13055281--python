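# Methods

## Abundance model

The pipeline treats a metagenome as a mixture of K organisms with relative
cell abundances `a_i` (Σ a_i = 1) and genome lengths `L_i`. Under shotgun
sequencing at fixed total depth N, each read originates from organism *i*
with probability proportional to `a_i · L_i` — a cell with a longer genome
contributes more template. A recovered bin under-represents its genome by
its completeness and over-represents it by its contamination, so the
assembled size relates to the genome actually sequenced as

    size_i = L_i · (1 + cont_i/100) · comp_i / 100,

which the correction `true_length_i = size_i · 100 / ((1 + cont_i/100) ·
comp_i)` inverts exactly. Dividing the mapped-read count by the corrected
length removes the length weighting, so the normalized counts are unbiased
(up to multinomial noise) estimates of quantities proportional to `a_i`,
and the reported percentages converge on `100 · a_i`. Without the
correction, a length-naive estimator converges on the read shares
`100 · a_i L_i / Σ a_j L_j` instead, which is biased whenever completeness
and contamination vary across bins; `GroundTruth.expected_read_share`
exposes that quantity so the bias is measurable.

Assumptions worth keeping in mind: one genome copy per cell, uniform read
recovery along each genome, and mapping that assigns each counted read to
its source bin. Multi-mapping is handled only crudely, by the MAPQ filter.

## Read counting

Reads are counted per reference at an *inclusive* mapping-quality threshold,
default 60. The upstream convention is often phrased as "quality greater
than 60", but 60 is the cap short-read mappers emit, so a strict reading
would retain nothing; the inclusive threshold is the only interpretation
that yields nonzero counts and is therefore the package's semantics (the
threshold is a parameter of `count_filtered_reads`). At MAPQ 60 the mapper's
nominal error probability is ≤ 1e-6.

## Selection and grading

MIMAG draft-genome grades are applied with the conventional strictness:
high needs completeness strictly above 90% and contamination strictly below
5%; medium needs completeness ≥ 50% and contamination strictly below 10%.
Selection keeps grades high/medium and additionally requires completeness ≥
`min_completeness` (default 90%). Zero-mapped MAGs stay in the abundance
table at 0% rather than being dropped, so the selected set is conserved.

Percentages are computed over the selected set by default (they then sum to
100 within 1e-9 relative tolerance; the reference table's printed values sum
to 99.99 only because of per-row display rounding). Passing
`total_normalized` — the normalized-count total of the whole metagenome —
switches to whole-community shares, which no longer sum to 100. Rendered
output uses round-half-even at a configurable precision (default 2
decimals); internal arithmetic is double precision throughout, and the test
suite pins it to an arbitrary-precision oracle at 12 significant digits.

## Mixed-rank aggregation

Display labels are assigned per MAG: domain for domains in
`domain_collapse` (default Archaea), class for phyla in `class_split_phyla`
(default the Proteobacteria/Pseudomonadota pair, so either spelling of the
phylum triggers the split), phylum otherwise; an empty phylum maps to
"Unclassified". The 0.5% display cutoff applies to *aggregated label
totals*, not per-MAG values — a phylum carried by two 0.3% MAGs survives at
0.6% — and sub-cutoff labels pool into "Other", which sorts last. Output
order is descending percentage with lexicographic tie-breaks, so rendering
is deterministic.

Name harmonization is a separate, explicit step (`adjust_names`): a
transitively resolved synonym map (cycles rejected) renames labels and
merges collisions by summation. The packaged default covers common
GTDB→LPSN phylum renames plus GTDB's alphabetic phylum splits
(Myxococcota_A → Myxococcota), without which GTDB's split phyla would show
as separate labels. The historical Betaproteobacteria are available as an
opt-in `(class, order)`-keyed relabel preset — `(Gammaproteobacteria,
Burkholderiales) → Betaproteobacteria` — kept off by default because it
deliberately departs from GTDB semantics.

## Cross-site comparison

Sites are compiled over the exact-string union of labels with absent labels
imputed as 0; fuzzy matching is deliberately absent, the synonym map being
the single merge mechanism, so unharmonized names produce visible gaps
rather than silent merges. Each site is renormalized to 100 (a warning is
logged when an input total deviates from 100 by more than 1%). Bray-Curtis
dissimilarity is computed from its definition; it is scale-invariant,
symmetric, bounded in [0, 1], and a *semimetric* — the triangle inequality
can fail and is not asserted. The matrix is built from the upper triangle
and mirrored, so symmetry is exact by construction; nearest-site rankings
sort ascending with lexicographic tie-breaks.

## Synthetic data generator

`simulate_community` draws `a ~ Dirichlet(α·1_K)` (default α = 1, a flat
prior over compositions that still produces the uneven communities typical
of real biofilms), `L ~ log-uniform(2.5, 8.0 Mb)` (the span of the reference
bins), completeness uniform on (90, 100] percent (the range the selection
filter admits) and contamination uniform on [0, 10) percent; the default
community size is K = 19 bins. Read counts are multinomial at fixed total
depth (default 10⁶) with `p_i ∝ a_i L_i` — multinomial rather than
per-taxon Poisson because a sequencing run has a fixed read total, which
also makes the sampling-error bound exact. Observed bin sizes are produced
by pushing the true length through the inverse of the correction formula,
so the correction recovers the truth to floating-point accuracy (tested at
10 significant digits). A `frac_ambiguous` binomial share of each taxon's
reads is emitted at MAPQ 30 (sub-threshold), the rest at 60; because the
thinning is uniform across taxa it rescales counts without biasing
percentages. All randomness flows through a single seeded numpy Generator;
identical seeds give bit-identical output, including the lazily generated
per-read stream.

What the generator does **not** emulate: mis-assignment of reads between
related genomes, contamination that *attracts* reads from the contaminating
organism, coverage non-uniformity (GC bias, origin-of-replication skew),
errors in the completeness/contamination estimates themselves, and
unbinned community fraction. Passing tests therefore demonstrate that the
estimator inverts the stated sampling model, not that it is robust to
binning artefacts beyond it.

The packaged 19-bin reference fixture carries the published sizes, quality
metrics, lineages and percentages exactly as printed; its lineage strings
are completed with standard GTDB interior ranks where the published table
abbreviates them (only domain/phylum/class affect any computed quantity).

## Numerical and design choices

- Estimator percentages over a selected set sum to 100 within 1e-9 relative
  tolerance; an all-zero count vector is a degenerate-input error, not NaN.
- Profile and matrix TSVs are written lexicographically ordered at fixed
  precision; re-reading reproduces the object at that precision, and matrix
  round-trips are exact.
- Parameter-recovery checks use 20 simulated communities of 10 taxa at 10⁶
  reads — small enough to run in seconds, large enough that the multinomial
  standard error (~0.05 pp per taxon share) sits far below the 0.5 pp
  acceptance margin.
- The CLI stages outputs in a temporary directory and publishes on success,
  so a failed run leaves no partial files; runs are byte-deterministic for
  identical inputs and flags.

## Known limitations

- Relative abundances only; no absolute quantification.
- The contamination term assumes contaminating sequence recruits reads like
  the host bin does — the same simplification the correction formula makes.
- Cross-study comparison inherits whatever rank conventions the source
  studies used; harmonization is limited to the synonym map, and 16S-derived
  profiles are comparable only as far as their labels can be mapped.
- Bray-Curtis values depend on the label resolution chosen (phylum vs mixed
  rank); matrices are only meaningful within one compilation convention.
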