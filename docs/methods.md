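# Methods

## The analysis model

The package treats two interaction datasets symmetrically: significant
TF–gene binding calls and significant TF–gene knockout-effect calls,
each a (tf, gene, p-value) list. Significance is strict `p < alpha`
(default alpha = 0.005); datasets that circulate as pre-filtered pair
lists can skip thresholding with a flag rather than abusing a sentinel
p-value. The study universe is the set of TFs assayed in both datasets
together with every gene either dataset records for those TFs; all
downstream statistics restrict to it. TFs or genes inside the universe
with no significant pairs simply contribute zero to both sums of any
pooled overlap percentage; their *per-entity* OP is reported as missing
(0/0), never as zero.

The pooled overlap percentage over a TF set M is
`OP = Σ_t |G_B(t) ∩ G_K(t)| / Σ_t |G_B(t)|`; the gene-set form is its
transpose. Both are ratios of pair counts, so for the full universe they
are identical — an invariant the test suite asserts on every simulated
world.

Functional similarity is the flat-set Jaccard index of annotation term
sets, and functional redundancy is the maximum similarity to any *other*
TF. The maximum excludes the TF itself — including it would make the
score identically 1 — and ties in the argmax partner are broken by
lexicographic identifier so runs are reproducible. Unannotated TFs are
missing data: they receive no score and are excluded (and logged), not
assigned 0, since absent annotation is not evidence of functional
uniqueness. Annotation catalogs from different sources (e.g. GO
biological process, GO molecular function, MIPS FunCat) are analyzed
independently; terms are consumed as given, with any ontology-graph
propagation left to data preparation.

## Stratified comparisons

Numeric properties are split into bottom-X% and top-X% strata with
k = floor(N·X/100) entities, X on the grid {10, 20, 30, 40, 50};
boundary ties are resolved by one global ordering (score descending,
identifier ascending), which keeps the two strata disjoint at every
X ≤ 50. Categorical properties compare two explicit lists, or one list
against the rest of the universe. Group 1 is always the bottom stratum
or the first list; the configured expected direction selects the
one-sided alternative of the test.

The two pooled OPs are compared with the two-sample proportion z test
using the pooled variance and no continuity correction; pair counts at
study scale are in the thousands, where the normal approximation is
accurate (the unit tests pin the p-value to an independent numerical
normal-tail integration at 1e-9). The test treats each binding pair as
an independent Bernoulli trial. This ignores within-TF correlation of
knockout effects — a deliberate simplification, inherited from pooling
pair counts, and a known caveat rather than something the package
corrects. P-values are reported raw, with no multiple-testing adjustment
across the X grid: the grid is a robustness display, not a family of
independent hypotheses. OPs are carried at full precision internally;
text reports round to one decimal in percent.

If the two groups have identical pooled proportions the statistic is 0
and the one-sided p-value 0.5; if the pooled proportion is degenerate
(0 or 1), the result carries a degeneracy flag with the same (0, 0.5)
convention instead of a division by zero.

## The synthetic-world generator

No public accessions accompany the analyses this package implements, so
the generator produces complete, self-consistent study inputs whose
statistical structure embodies the compensation (masking) hypothesis.
It emulates: 173 TFs, 4065 genes, a mean of 65.75 binding targets per
TF (≈11.4k significant binding pairs), a knockout dataset of similar
size, and an overall OP near 4%.

Mechanism, per seeded world:

1. **Paralog pairing.** A `paralog_fraction` (default 0.5) of TFs is
   paired; each pair draws its annotation terms from a shared base set
   (each partner keeps a term with probability `term_share_prob` = 0.9
   and adds a few private terms), so paired TFs have high Jaccard
   similarity by construction. Unpaired TFs draw independent sets from a
   300-term pool; their best-match similarity stays low. The computed FR
   therefore separates the two groups nearly perfectly, which is what
   lets FR-based strata recover the injected masking.
2. **Binding.** Each TF binds a Poisson(65.75)-sized gene set, sampled
   with a log-normal per-gene propensity (sigma 0.8) so bound-TF counts
   per gene are long-tailed, as in real promoter data.
3. **Knockout conversion.** A bound pair (t, g) becomes a knockout
   effect with probability built from a deterministic part —
   `base_effect_prob × (1 − masking_strength·1[t paired]) × class
   multipliers` — adjusted on the log-odds scale by the z-scored numeric
   gene properties with slopes `numeric_property_coupling`, each slope
   mean-normalized (c·z − c²/2) and z clipped at ±2.5 so no single gene
   dominates the pooled statistics. The logistic (log-odds) form keeps
   probabilities bounded and tames the tail that a purely multiplicative
   model produces when several couplings combine with the long-tailed
   binding degree.
4. **Background effects.** Unbound pairs convert at an independent
   background rate (0.0167), mimicking indirect regulatory effects and
   keeping |G_K| ≈ |G_B| (≈12k vs ≈11.4k).
5. **P-values.** Significant pairs draw p ~ U(0, 0.8·alpha); about 10%
   extra non-significant records draw p ≥ 0.05, so the thresholding
   stage is genuinely exercised.

Injected directions follow the biology being emulated: TATA-containing
genes ×1.8, NFR-containing ×0.55, ribosomal ×2.5, chromatin-remodelling
TFs ×2.0, and positive couplings (0.4–0.5) for expression, plasticity,
bound-TF count, TFBS count and TFBS–TSS distance — i.e. lowly expressed,
TATA-less, NFR-containing, low-plasticity, sparsely bound genes are less
sensitive to knockout of their binding TFs. The bound-TF-count property
is only defined for genes with at least one bound TF (an unbound
promoter has no such count, and it would pool empty denominators into
every bottom stratum).

`base_effect_prob` (0.0590) and the background rate were frozen after a
one-time Monte-Carlo calibration so the realized overall OP across seeds
sits at 0.040 ± ~0.005 under the default masking strength of 0.8; the
manifest written next to every world records the exact parameters, and
regenerating from a manifest reproduces the world byte-for-byte. The
`null_params` preset (masking 0, unit multipliers, zero couplings,
flat 4% conversion) defines the null world used for calibration checks:
stratum p-values there are uniform and the level-0.05 rejection rate is
5% (verified over 500 replicates in the acceptance tests).

What the generator does **not** emulate: promoter sequence, binding-site
positions or motif strength (TFBS count and distance are sampled
covariates, not positional data); correlated condition-specific
expression programs; annotation incompleteness structured by study bias;
and measurement-level artifacts of ChIP or microarrays. Passing tests on
synthetic worlds therefore demonstrate that the pipeline's statistics
recover the effects the model injects at realistic scale and noise —
not that any particular biological dataset shows those effects.

## Problem sizes and numerical choices

The acceptance tests run the generator at full study scale: 100
replicate worlds for the conservation identity, 100 for masking
recovery across the whole X grid, 100 for gene-property direction
recovery, and 500 null worlds for calibration; unit tests use a reduced
16-TF × 120-gene world where scale is irrelevant. Reported quantities
in `scripts/acceptance.py` use one default world for headline numbers,
20 replicates for the masking-recovery rate and 100 null replicates for
the false-positive rate.

Stratum sizes use the floor convention; any convention keeping top and
bottom disjoint at X ≤ 50 gives the same qualitative results. Identifier
matching is verbatim and case-sensitive — aliasing ORF and common gene
names is data curation, out of scope. Entities named in property files
but absent from the universe are dropped and logged, never silently
imputed.

## Limitations

- The proportion test's independence assumption across binding pairs is
  optimistic; a TF with many targets contributes many correlated trials.
- FR is only as good as the annotation catalogs; sparse annotation
  biases FR downward and the exclusion of unannotated TFs can shrink
  strata.
- The masking model is single-parameter and pair-based; real
  compensation can involve larger paralog families and partial,
  condition-dependent redundancy.
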