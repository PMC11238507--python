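# Methods

## Model

### Meta-positions

A domain family alignment defines, for each match column, the set of
evolutionarily equivalent residues across its member proteins (domain
copies). Match columns are read from the Stockholm `#=GC RF` line when
present; otherwise a column is a match state iff its gap fraction is at
most 0.5 (lowercase insert residues count as gaps for this rule), the
usual profile-HMM convention. The residue → column map walks each aligned
row once: `-` and `.` consume nothing, lowercase letters consume a protein
position without mapping, uppercase letters in match columns map. The map
is injective per member, and within one family a protein residue belongs
to at most one domain instance — when instances overlap on a protein the
instance with the smaller envelope start claims the shared residues, and
exact duplicate members are dropped with a warning. These two rules are
this package's own conventions for situations the underlying method leaves
open; they only matter for pathological inputs. Aggregation is strictly
within one family; no clan-level merging.

### Variant space

Every coding transcript of CDS length `L` contributes exactly `3L`
possible SNVs. Genomic coordinates run through the exon map with
strand-aware complementation; consequences come from the standard nuclear
codon table. Any SNV altering the ATG start codon is `start_lost`
(including changes whose translated amino acid would otherwise read as
missense), `synonymous`/`missense`/`nonsense`/`stop_lost` follow from the
codon comparison otherwise. Trinucleotide contexts are reported on the
coding strand. Because mutability is a property of the genomic
neighbourhood, flanks at exon junctions and CDS edges are read from the
genome sequence when one is supplied; without a genome such positions get
an `N` flank and drop out of the assessable set (soft failure, not an
error).

The rarity filter keeps the observed and expected sides of the ratio
consistent: a possible SNV is *observed-rare* iff an exact
(chrom, pos, ref, alt) match exists at `0 < AF < 0.1%`; alleles at
`AF ≥ 0.1%` are common and are excluded from both the observed counts and
the expectation sums. AF is the global allele frequency of the input
cohort; no population-maximum logic. Multi-nucleotide variants and indels
are out of scope.

### Neutral expectation

Per possible SNV, `Expected = k · μ(context, alt, methyl) · c(depth)`.

* `μ` is a relative mutability keyed by coding-strand trinucleotide
  context and alternate base. CpG contexts (the central base is the C or
  the G of a CpG dinucleotide; contexts are not collapsed to the
  pyrimidine strand) carry three methylation strata {0, 1, 2}; missing
  strata fall back to the unmethylated rate with a warning. All 192
  (context, alt) pairs must be present at level 0.
* `c(depth) ∈ [0, 1]` is non-decreasing: 0 below `min_depth` (default 10),
  1 at or above `full_depth` (default 30), a user-supplied step table or —
  absent a table — a linear ramp in between. The defaults leave typical
  well-covered data uncorrected.
* `k` is a single global scale fixed on synonymous candidates within the
  assessed regions: `k = (# synonymous observed rare) / (Σ μ·c over
  synonymous candidates)`. Conservation of the synonymous count is then
  exact by construction. The underlying method defers its expectation
  model to prior exome-wide work whose exact calibration set and
  correction curves are not reproduced here; the synonymous-within-regions
  scheme is this package's declared substitute and is what all tests
  exercise.

A known limitation of the single global `k`: when per-variant observation
probabilities are not small, saturation (`P(observed) = 1 − e^{−λ}` rather
than `λ`) differs between context classes — CpG-rich synonymous sites
saturate first — which biases missense O/E upward by a few percent. At
realistic per-variant rates (large cohorts spread over many sites,
λ ≲ 0.1) the effect is negligible; the synthetic defaults keep that
regime.

### Score

At each meta-position, `O` counts *distinct* rare missense alleles over
the homologous residues (site-alt level, not allele-count weighted), `E`
sums per-variant expectations over all assessable missense candidates
there. With `O ~ Poisson(λE)` and an improper flat prior on the rate
ratio λ, the posterior is `Gamma(O + 1, rate = E)`; the score is its 0.95
quantile, i.e. the upper bound of the equal-tailed 90% credible interval.
The flat prior is chosen because it makes "score < 1" *exactly* equivalent
to one-sided posterior tail mass `P(λ ≥ 1) < 0.05`, which is the stated
interpretation of the threshold; it also guarantees score > MLE for every
O, E. Thresholds are strict and bins half-open: `[0, 0.5), [0.5, 0.6),
[0.6, 0.8), [0.8, 1), [1, ∞)`, with `< 0.8` labelled highly constrained.

Power: a position is assessable iff a fully depleted position could be
called, `hmc(0, E) < 1 ⇔ E > −ln(0.05) ≈ 2.996`, with an additional
configurable minimum of 2 contributing domain copies. The expectation-
based rule stands in for a copy-number rule whose exact form is not
public; the copy-number floor is kept as a second, configurable gate.
Optional pooling of neighbouring alignment columns exists only as a
config hook and is off by default: widening the column set trades
precision for sensitivity and is not part of the released score.

### Evaluation statistics

Published benchmarks of this kind report 95% CIs without naming methods,
so the harness uses standard choices and documents them: Katz log-normal CIs for
rate ratios (0.5 continuity correction on zero numerators), Garwood exact
Poisson CIs and one-sided enrichment p-values for DNM burden,
Haldane–Anscombe corrected odds ratios with Woolf CIs, and normal-theory
two-sided p-values on the log scale. Precision–sensitivity curves sweep
distinct score values with grouped ties (no intra-tie interpolation) and
are invariant under monotone score transforms; areas are trapezoidal over
sensitivity. `bin_report` supports both disjoint bins and nested
("tightening-threshold") strata; unscored variants form their own
stratum.

## Synthetic data

The generator emulates the structure of the real inputs, not their
content:

* **Families and transcripts.** Each family draws a consensus amino-acid
  sequence; copies diverge per column with probability
  `divergence · (1 − s)`, so strongly selected columns are conserved
  across copies, as in real families. Occasional 1–2 residue insertions
  (lowercase + `.` columns) and rare deletions exercise the full
  alignment dialect while keeping the alignment correct by construction —
  alignment inference is not simulated. Every copy is reverse-translated
  with uniformly chosen codons into its own two-exon transcript on its
  own toy chromosome, alternating strands, so junction and strand logic
  are always exercised. Filler genes without domains supply additional
  synonymous calibration mass.
* **Cohort.** Each possible SNV is present as a rare variant with
  probability `1 − exp(−(1 − s) · k_true · μ_adj)` — Poisson presence at
  the neutral rate thinned by the column's depletion `s`, with `s = 0`
  for synonymous and non-domain variants. Site-level presence (not
  per-individual genotypes) is simulated because the score consumes
  site-level presence. Rare AFs are log-uniform in [1e−5, ~8e−4]; 1% of
  sites instead carry a common allele (AF 0.002–0.05) to exercise the
  rarity filter.
* **Defaults as study conditions.** 4 families, 12–20 copies, 20–35
  columns, `k_true = 0.15`: per-column missense expectations land near
  20 — the regime where aggregation across copies is what creates power —
  while per-variant presence probabilities stay near 0.15, far from
  saturation. Where a condition requires per-column expectations near 50,
  it is realised with 90–110 copies rather than higher per-variant rates,
  mirroring real domain families (hundreds of copies, per-variant rates
  ≪ 1) and keeping the calibration bias discussed above negligible.
* **Labels.** P(pathogenic) follows a step rule in `s` (default: 0.95
  above s = 0.8, 0.02 below); benign weights are the complement. Case DNM
  draws weight mutability boosted 21× at strongly depleted columns;
  control draws use plain mutability. Ground-truth `s` is attached to
  every labelled variant.

What the generator does *not* emulate: human demography and linkage,
per-population AF structure, alignment errors, overlapping genes, indels,
and realistic gene length/composition. Passing tests therefore demonstrate
the correctness and calibration of the machinery under its own generative
assumptions, not performance on real cohorts.

## Numerical and design notes

* Scores are computed with the regularised incomplete-Gamma inverse
  (`scipy.stats.gamma.ppf`); at `O = 0` this equals the closed form
  `−ln(0.05)/E` to machine precision. Verified against a 10^7-draw
  Monte-Carlo posterior quantile to 1e−3 (relative above magnitude 1)
  over `O ∈ [0, 50] × E ∈ [0.1, 100]`.
* Coordinates: 1-based genomic in all I/O (VCF convention), 0-based
  half-open internally, 1-based protein positions. Contig names pass
  through unchanged.
* Degenerate inputs: `expected = 0` with candidates present →
  unassessable record, not an error; empty score tables are valid outputs
  (exit 0 with a warning in the CLI); duplicate observed alleles keep the
  maximum AF.
* Determinism: every stochastic operation takes an explicit seed; one
  seed reproduces byte-identical generated files and pipeline outputs.
* Problem sizes in the test suite (a few families, tens of columns,
  10–110 copies, 40 cohort replicates for the bias check, 100 label
  replicates for the null coverage check) were chosen as the smallest
  studies in which the targeted effects are comfortably resolvable above
  Monte-Carlo noise.

## Known limitations

* The expectation model is a deliberate simplification of exome-scale
  practice: no per-context calibration regression, no XY-specific rates,
  no per-gene recalibration.
* Constraint is aggregated per family only; residues in genes without
  domain annotations are never assessable, and scores say nothing about
  regional ("horizontal") constraint.
* The score is one-sided by design: `HMC ≥ 1` is absence of evidence of
  depletion, not evidence of neutrality — the MLE should be consulted to
  separate "unconstrained" from "underpowered".
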