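# Methods

`plexqtl` implements bulked-segregant QTL mapping for autotetraploid F1
populations in which the causal allele may be simplex (on one of the
donor parent's four homologs) or duplex (on two), together with a
simulator of the full experimental design and allele-dosage genotyping
of individual lines. This note records the models, the parameters that
matter, and the choices made where the design was genuinely open.

## Segregation model

A tetraploid donor-by-nulliplex cross is described by the ploidy `2k`
and the donor plexity `m` (ALT copies among the donor's homologs). Under
random chromosomal (tetrasomic) segregation without double reduction, a
gamete receives a uniform random k-subset of the donor's 2k homologs, so
the transmitted ALT-copy number is hypergeometric:

    P(j) = C(m, j) C(2k − m, k − j) / C(2k, k).

With a nulliplex second parent the progeny dosage equals the gamete
dosage, giving the classical tetraploid F1 ratios — 1:1
nulliplex:simplex for a simplex donor, 1:4:1 nulliplex:simplex:duplex
for a duplex donor. Three closed-form consequences anchor the pipeline:

* expected SNP-index of an unselected bulk: `m / (2 · ploidy)` (0.125
  for tetraploid simplex, 0.25 for duplex);
* maximal ΔSNP-index under complete tail selection: `min(m, k) / ploidy`
  (0.25 simplex, 0.5 duplex);
* expected genotype counts for segregation tests (e.g. 29.7 : 118.7 :
  29.7 at n = 178 for a duplex donor).

Double reduction is excluded: the 1:1 and 1:4:1 ratios the model must
reproduce presuppose pure bivalent segregation, and the package's scope
is the analysis built on those ratios, not quadrivalent meiosis.

## The plexity filter

Donor variants of the target plexity are selected from a four-sample
depth table (two parents, two phenotype-tail bulks) by three rules:

* donor-parent SNP-index within a closed window — default 0.10–0.36 for
  simplex (`nplex = 1`) and 0.37–0.63 for duplex (`nplex = 2`). At read
  depth d the donor's index is Binomial(d, m/4)/d; the windows are sized
  so that roughly 95% of draws at depth ≥ 40 fall inside
  (`simulate_index_range_coverage` computes the exact binomial coverage:
  0.941 at depth 40, ≥ 0.95 from depth 50);
* the other parent effectively nulliplex: SNP-index ≤ 0.02 **and** at
  most 1 ALT read. The design requires the non-donor parent to be devoid
  of the polymorphism; a single stray read is tolerated as sequencing
  error, two are not;
* total depth ≥ `min_depth` (default 40) in all four samples. Applying
  the depth floor uniformly is the conservative reading; parents with
  thin coverage produce unreliable index windows just as bulks do.

In/Dels are treated like SNPs up to a configurable length (default:
records with |len(ALT) − len(REF)| ≥ 70 bp are dropped at the reader).

## Null distribution, P values, significance classes

Inference is against a Monte-Carlo F1 null that assumes no QTL: for each
bulk, n progeny genotypes are drawn i.i.d. from the tetrasomic dosage
distribution, pooled into an allele fraction f = Σdosage/(4n), and reads
are drawn Binomial(d, f); the null statistic is Δ = k₁/d₁ − k₂/d₂. Per
(d₁, d₂) depth pair, R replicates (default 10⁴) yield

* the empirical two-sided 95% and 99% bands (the confidence thresholds
  drawn on ΔSNP-index plots), and
* the sorted |Δ| sample used for two-sided P values with add-one
  smoothing: P = (#{|Δ_null| ≥ |Δ|} + 1)/(R + 1).

Depth pairs are binned to bound compute: each observed depth maps to the
nearest multiple of 10 and one null sample is shared per bin. Rounding
to the nearest multiple (rather than flooring into decades) means the
canonical design depths 40 and 60 are simulated at their exact values.

**Significance classing is by P value** — P ≤ 0.01 → class `P99`,
P ≤ 0.05 → `P95`, boundaries inclusive — not by raw band-crossing. The
distinction matters at fixed depth: Δ then lives on a lattice with
spacing 1/d, the empirical quantile usually coincides with a lattice
point, and counting boundary values as significant would absorb that
point's entire tie mass. Measured on no-QTL data at depth 60 (n = 178,
bulks of 18, R = 10⁴) band-crossing classes 1.3% of variants as P99;
the P-value rule gives 0.85% (slightly conservative, as add-one
smoothing on a discrete statistic should be). The reported bands and the
classes therefore agree except exactly at lattice ties.

Variants with Δ = 0 have no direction and never enter directional
counts.

## Windows and candidate regions

Window statistics use a 100-kb window sliding in 20-kb steps (the
scale at which QTL-seq signal is customarily smoothed). Windows are
half-open `[start, start + size)` in 0-based coordinates internally and
reported 1-based inclusive; a variant contributes to every window
containing it; terminal windows are clipped at the chromosome end. Per
window: variant count, mean bulk indices, mean Δ, mean −log₁₀P, and four
directional counts — `p99_pos/p99_neg` count class-P99 variants with
positive/negative Δ, while `p95_pos/p95_neg` count everything beyond the
95% level (i.e. they include the P99 variants, matching how the 95% dots
on a QTL variant-count plot are read).

A window is a candidate when its P99 count strictly exceeds the
threshold (default 100) in **exactly one** direction. The asymmetry
requirement is the core of the candidate rule: dense regions produce
index excursions past the thresholds by depth noise alone, but
symmetrically in both directions; only a real QTL pushes one bulk's
index up and the other's down coherently. Qualifying windows that
overlap or bookend and share a direction merge into one region (the rule
that turns window hits into reportable Mb spans; no merge rule is
canonical, and bookended merging is the most conservative choice that
never splits a contiguous run of qualifying windows). The analysis is
run once per donor orientation (donor = P2, then parents swapped) so
QTLs from either parent are found and labeled with their donor.

The count threshold of 100 presumes roughly the study's variant density
(~10⁵ donor-class variants per 100 kb are not needed — about 150–300
are); with sparser data the threshold should be lowered in proportion,
which is why it is a configuration value rather than a constant.

## The simulator

The simulator generates what the analysis consumes, end to end:

* **Parents.** Variants are planted along each chromosome as a Poisson
  process (density = expected variants/bp), assigned a donor parent, a
  plexity from the configured mix (default 80% simplex / 20% duplex,
  roughly the proportion seen in tetraploid potato crosses), and a
  carrier set among the donor's four homologs. Simplex carriers are
  uniform per variant — each homolog accumulates private variants along
  its whole length. Duplex carriers default to *coherent* phase: one
  homolog pair per parent and chromosome carries every duplex variant.
  This models the local identity-by-descent that makes real duplex
  variants in a region sit on the same two homologs; it is what makes a
  duplex QTL produce a one-directional ΔSNP-index excess. With
  independent random pairs (available as `duplex_phase="random"`),
  variants near a QTL would split 1:4:1 into in-phase (Δ = +0.5),
  half-overlap (Δ = 0) and anti-phase (Δ = −0.5) classes and the
  directional candidate rule could never fire — a useful negative
  control, not a model of a real cross.
* **Meiosis.** Per chromosome the four homologs pair at random into two
  bivalents each meiosis; each bivalent receives Poisson(genetic length
  in Morgans) crossovers at uniform positions (Haldane, no interference)
  and contributes one recombinant chromatid. Genetic length is constant
  cM/Mb (default 4); the real recombination landscape of any particular
  cross is not modeled. No double reduction, so marginal gamete dosages
  are exactly hypergeometric.
* **Phenotypes.** A single causal variant acts additively
  (baseline + effect·dosage, the dosage-dependent pattern of a
  starch-phosphorus-like trait) or dominantly (effect·1{dosage ≥ 1}, the
  presence/absence pattern of a flesh-color-like trait), plus Gaussian
  noise. Chroma C* = √(a*² + b*²) is provided to turn CIE L*a*b*
  colorimeter readings into the yellow-intensity score used as the
  flesh-color phenotype.
* **Bulks and reads.** Tails are selected by size (n lowest/highest) or
  by phenotype cutoffs; fractions are reported as percent to one
  decimal (19/169 → 11.2%). Read sampling is binomial over the pooled
  allele copies with an optional per-read error rate and fixed or
  Poisson depth (default: fixed 60, error 0). Output is a four-sample
  VCF (P1, P2, Bulk1, Bulk2) with AD fields, plus truth tables
  (dosages, phenotypes, planted-QTL BED).

Default study-scale parameters — population 178, bulks of 18 (~10%
tails), depth 60, effect 3× noise SD — mirror the design the package
targets at desk scale. What the simulator deliberately does not emulate:
alignment and calling artifacts (mapping bias, paralog collapse),
depth heterogeneity along the genome, allopolyploid subgenome
divergence, multi-QTL or polygenic architectures, and genotyping-stage
assay chemistry. Passing recovery tests on simulated data therefore
demonstrates the statistics and their plumbing, not robustness to
upstream calling errors.

## Dosage genotyping

Individual lines are classed nulliplex/simplex/duplex from three assay
families, each reduced to one measurement per line:

* **qPCR** relative allele dosage by ΔCt against a calibrator that mimics
  a simplex genotype (an equal mix of the parents' DNA):
  dosage = 2^(Ct_cal − Ct_sample), optionally ΔΔCt-normalized by a
  reference amplicon when template amounts vary. Default bins 0–0.1 /
  0.4–1.5 / 1.5–2.2.
* **Fragment analysis** ALT/REF peak-height ratio; bins 0.05–0.15 /
  0.25–0.55 / 0.55–1.15.
* **Amplicon sequencing** ALT-read fraction; bins 0.00–0.025 /
  0.150–0.375 / 0.375–0.700.

Bins are closed intervals; a value on an endpoint shared by two classes
(1.5 for qPCR, 0.55 for fragment, 0.375 for amplicon) resolves to the
higher dosage class — the interval is split "in the middle", and
checking duplex before simplex implements that while keeping
classification monotone in the measurement. Values in inter-bin gaps are
`unclassified` and treated as missing. Consensus across assays is the
modal class; exact ties and all-unclassified lines are `unresolved`; a
line is concordant when every classified call agrees. Population-level
segregation is tested by χ² goodness of fit against a configured ratio
(1:4:1 for a duplex donor), with the P value from the χ² survival
function at k − 1 degrees of freedom.

Note on precision: the classifier bins are narrow relative to the
spacing of their centers (the amplicon nulliplex bin spans only
±0.0125), so measurement noise first pushes values into gaps
(unclassified) rather than into the wrong class. Reliable (≥99%)
single-assay recovery needs noise SD no larger than about a third of
the narrowest bin's half-width; noisier assays rely on the multi-assay
consensus.

## Numerical and interface conventions

* Positions are 1-based (VCF convention); BED output is 0-based
  half-open; windows are reported 1-based inclusive.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seed and configuration give
  byte-identical outputs. Null samples per depth bin are seeded from
  (base seed, bin pair) so lazily built bins are order-independent.
* Multi-allelic VCF records are skipped; genotype (GT) calls are
  ignored — indices are always recomputed from allele depths.
* SNP-index is undefined (NaN) at zero depth; such variants cannot pass
  the depth filter, and zero bulk depth in the statistics stage is an
  error rather than a silent 0/0.
* The minimum R for null thresholds is 1000, below which the 99% tail of
  the empirical null is not resolved.

## Known limitations

* The null conditions on binned depths; extreme depth heterogeneity
  within a bin (width 10) slightly misstates individual bands.
* Bulks are modeled as equimolar pools of their individuals; unequal DNA
  contributions are not simulated.
* The candidate rule's count threshold couples to variant density, as
  noted above; regions whose density falls below ~threshold variants per
  window are undiscoverable regardless of effect size.
* Only even ploidies are supported, and only ploidy 4 is exercised by
  the test suite beyond the distribution-level checks.
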