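# Methods

This note documents the models, parameter choices and numerical conventions
behind `relapse-trace`, and what the synthetic cohort does and does not
emulate.

## The generative model of the synthetic cohort

A patient is a rooted clone tree. Each clone carries a private mutation
count, a signature-exposure mixture, and a cell-fraction trajectory over
sampling days. Fractions are **inclusive** cancer-cell fractions of all
nucleated cells: a clone's fraction counts every cell carrying its private
mutations (itself plus descendants). This makes the tree invariants the
standard phylogenetic sum rules — a child never exceeds its parent and
sibling fractions sum to at most the parent — and it makes the expected VAF
of a heterozygous diploid variant in clone *c* at time *t* simply
`purity · fraction(c, t) / 2`.

Mutations are drawn per clone: first a generating signature from the
clone's exposures, then a trinucleotide substitution class from that
signature's catalog column, then an unused locus on the reference whose
trinucleotide matches the class (either strand; purine-centre loci record
the reverse-complemented allele pair). The per-clone empirical spectrum
therefore converges to the exposure-weighted mixture of catalog columns,
which is the inverse of the refitting stage and the basis of all
round-trip tests.

Read counts: per-site depth is Poisson around the platform mean (negative
binomial with configurable shape when overdispersion is wanted; the default
is Poisson because no per-site depth variance is claimed for the panel).
Alt reads are `Binomial(depth, q)` with

    q = v(1 − 3e) + (1 − v)e,

where `v` is the expected VAF and `e` the **per-allele** substitution error
rate: a read is miscalled to each specific wrong base with probability `e`
(total miscall rate `3e`). Under this convention a wild-type site at 3250×
with `e = 10⁻⁴` yields 0.325 expected alt reads toward the tracked allele,
and reads carrying one of the two other alleles (reported as
`other_reads`, rate `2e`) feed the MRD artifact check. Strand counts split
`Binomial(alt, ½)`. Structural-variant markers use the same sampling for
breakpoint-supporting reads but are immune to substitution error.

### Scenario construction

The three scenarios fix the tree shapes and trajectories; days are
(0, 15, 29, 80, relapse) with relapse at day 120, 250 and 400 respectively.
Fractions dip through induction (day 15, day 29) and regrow toward relapse;
a `remission` flag zeroes all fractions after day 29.

* `very_early_multiclonal`: a truncal clone with 400 private SNVs and two
  surviving subclones (250 SNVs each) that both persist at relapse, plus a
  chemotherapy-signature relapse subclone and a lost diagnostic subclone.
* `early_sweep_chemo`: the dominant diagnostic clone (500 SNVs) is lost;
  a minor clone at diagnostic cell fraction 0.008 by default (configurable
  above or below the detection limit) sweeps to 0.90, acquiring a
  thiopurine-dominated subclone. **The truncal clone carries no private
  SNVs** — the relapse lineage branches off before the diagnostic clone's
  mutation bulk. This reflects the low somatic burden of infant KMT2A-r
  leukemia and a relapse origin in an evolutionarily early cell, and it is
  what makes the swept diagnostic cluster disappear from the 2-D VAF plot
  instead of leaving a large shared cluster.
* `aml_dormant`: same sweep geometry (relapse clone present at diagnosis at
  fraction 0.02) but every clone shares the diagnostic clone's clock-like
  exposures — relapse mutations mirror the natural mutational process, no
  chemotherapy imprint.

Default mutation counts (hundreds per clone) are WGS-scale so that spectra
and clustering are informative; `mutation_scale` shrinks them
proportionally. The tracked MRD panel is up to 8 top variants each from the
major diagnostic and relapse clones plus the fusion marker (~17 mutations
per patient, matching deep-sequencing panel practice), sequenced at mean
3250× at every timepoint; all variants additionally get 43× WGS-like counts
at diagnosis and relapse.

### What the generator does not emulate

Indel/SV breakpoint sequences (SVs are abstract trackable markers),
library-preparation and amplification artifacts, mapping bias, subclonal
copy-number changes, contamination, and depth heterogeneity along the
genome. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated read-sampling model, not robustness to every
real-data failure mode.

## The bundled signature catalog

Six synthetic signatures ship with the package (`SBS_SYN_*`), one per
etiology class relevant here, including a thiopurine-like chemotherapy
signature. Each is a block profile: 70–75 % of mass uniform over a
characteristic context block (e.g. N[C>T]G for the clock-like signature,
T>A for the thiopurine-like one) plus a uniform floor. Blocks are disjoint,
so refitting on the bundled catalog is well conditioned; real COSMIC SBS
files in the same tab-separated layout load through the same reader, with
etiologies supplied as a two-column TSV. The catalog is a synthetic
stand-in, not a copy of any published signature set.

## Numerical choices

* **NNLS refitting** operates on raw counts (no sparsity pruning) and
  normalizes the solution to sum 1; the residual is reported. An empty
  spectrum returns an empty profile rather than dividing by zero.
* **Per-motif attribution** uses raw catalog columns by default (each motif
  maps to the signature with the highest probability there); an
  exposure-weighted mode conditioned on a sample's fitted exposures is
  available behind a flag, since either reading of "most likely signature"
  is defensible. Ties break by catalog order and are queryable.
* **Primary signature**: argmax of summed per-class contributions (not a
  count of signatures per class), reported both over all classes and
  excluding Unknown; exact ties resolve alphabetically with a flag.
* **EM clustering**: binomial likelihoods on raw (alt, depth) pairs in both
  samples, k-means++-style seeded initialization on the VAF points, 10
  restarts, BIC over k = 1..6 with 3k − 1 free parameters. The
  log-likelihood is asserted non-decreasing on every run; k = 1 reproduces
  the pooled closed-form estimate exactly. Cluster probabilities are
  floored at 10⁻⁷ to keep zero-alt clusters finite. Fewer than three
  variants yield a single flagged trivial cluster.
* **Seeding classification**: relapse clusters are those with relapse
  centroid above the clonal-presence threshold (VAF 0.05); the pattern
  depends on how many of them had diagnostic centroids at or above the
  panel detection limit (VAF 0.002). Presence and detection are distinct
  thresholds because a clone can be reliably *detected* far below clonal
  *presence*; both are configurable.
* **Trajectories**: clone fraction = 2 × mean member VAF (heterozygous
  diploid; CCF-corrected upstream where copy number is aberrant), capped at
  the parent fraction. Parent assignment uses a containment heuristic with
  a deliberately coarse tolerance (0.1) so that noisy containment still
  yields a tree; residual child-over-parent excesses beyond 0.02 raise a
  violation flag instead of being silently clipped. Missing timepoints are
  linearly interpolated and flagged.
* **MRD calls**: artifact exclusion first, then the two-highest-VAF mean.
  The fusion marker gates the call but is excluded from the VAF average (a
  breakpoint-read fraction is not a substitution VAF). With exactly one
  usable variant the single VAF is used and flagged — discarding the
  timepoint would lose signal the statistic is designed to capture; with
  none the call is invalid. The rescue rule requires strictly more than two
  qualifying variants from the union of the major-diagnostic and relapse
  clone sets (the union reading of "and/or"; a per-set mode is available).
  Lead time is measured from the first qualifying detection after the
  diagnostic sample (configurable `min_day`).
* **Limit of detection**: nine two-fold steps from VAF 1.0 end at
  0.5⁹ ≈ 0.00195. The default detection rule (≥ 3 alt reads, both strands
  represented) gives ≈ 0.92 per-replicate detection at the terminal step at
  3250× under `e = 10⁻⁴`, so the reported LOD at the 90 % reliability level
  is the terminal step — VAF ≈ 0.002, i.e. 0.4 % of leukemia cells.
* **Coordinates**: VCF and all variant positions are 1-based; copy-number
  segments are 0-based half-open; conversions are centralized in the
  readers.

## Design choices where the design was open

* The unpaired-sample single-strand rule is applied only at ≥ 3 alt reads;
  with 1–2 alt reads single-strandedness is uninformative (a fair coin
  lands one-sided half the time) and taking the rule at face value would
  discard nearly all true observations near VAF 0.002 that the MRD
  statistic relies on — such variants are kept with a low-evidence flag.
* Scenario postconditions (e.g. "exactly one clone above fraction 0.5 at
  relapse" for the sweep) are evaluated on non-truncal clones: with
  inclusive fractions the root dominates every descendant by definition.
* Hypermutation exclusion and gene-list scoping of the unpaired cascade are
  exposed as user parameters without asserted defaults.
* The report validator is a minimal structural checker (type / required /
  properties / enum) against the bundled schema files.

## Problem sizes

The test suite simulates cohorts of 50 patients per scenario at panel depth
for seeding-pattern recovery, 50 random three-signature mixtures at 10,000
mutations for refit calibration, and 1,000-replicate dilution series; these
sizes give Monte-Carlo standard errors comfortably below the asserted
margins while keeping a full run in a few minutes.

## Known limitations

Parent assignment is a containment heuristic, not a phylogeny
reconstruction; multi-sample CCF-based tree building is out of scope.
Signature discovery (NMF), doublet-base and indel signatures, and
transcriptional strand bias are not implemented. The seeding classifier
assumes the 2-D VAF geometry of paired diagnosis/relapse samples; patients
with a dominant shared truncal SNV cluster *and* a genuine sweep require
manual review, as the truncal cluster counts as a detected relapse cluster.
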