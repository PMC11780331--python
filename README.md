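# plexqtl

Plexity-aware polyploid QTL-seq: bulked-segregant QTL mapping for
autotetraploid F1 populations, with a built-in simulator of the whole
experimental design and allele-dosage (plexity) genotyping of
individual lines.

## The problem

In an autotetraploid crop such as potato, every locus has four
homologous copies, and a trait allele may sit on one of them (*simplex*),
two (*duplex*), or more. Progenies of a cross between a carrier parent
and a non-carrier (*nulliplex*) parent segregate by tetrasomic
inheritance — 1:1 nulliplex:simplex for a simplex donor, 1:4:1
nulliplex:simplex:duplex for a duplex donor — which dilutes and reshapes
the allele-frequency signal that bulked-segregant analysis (BSA) relies
on. A QTL-seq analysis tuned to simplex variants can miss a duplex QTL
entirely; this package makes the plexity a first-class parameter of the
analysis, for breeders and geneticists mapping traits in polyploid F1
populations from pooled whole-genome sequencing.

## The method

Inputs are per-sample allele depths at biallelic variants for four
samples: the two parents and two phenotype-tail bulks. For each variant
the **SNP-index** of a sample is ALT reads / total reads, and

&Delta;SNP-index = index(Bulk1) &minus; index(Bulk2).

1. **Plexity filter.** Keep variants whose donor-parent index lies in
   the plexity window — 0.10–0.36 for simplex (expected index m/4 =
   0.25), 0.37–0.63 for duplex (0.50) — whose other parent is devoid of
   the allele, and with depth ≥ 40 in all four samples. The windows
   capture ~95% of binomial read draws at depth ≥ 40.
2. **Monte-Carlo F1 null.** Assuming no QTL, each bulk's n genotypes are
   drawn from the tetrasomic dosage distribution, pooled
   (f = &Sigma;dosage / 4n), and reads sampled Binomial(d, f). R
   replicates per depth pair give two-sided 95%/99% confidence bands for
   &Delta; and empirical P values, P = (#{|&Delta;<sub>null</sub>| ≥
   |&Delta;|} + 1)/(R + 1); variants with P ≤ 0.01 are classed P99,
   P ≤ 0.05 P95.
3. **Sliding windows.** 100-kb windows at 20-kb steps aggregate mean
   indices, mean &minus;log<sub>10</sub>P, and directional counts of
   P95/P99 variants.
4. **Candidate regions.** A window qualifies when its P99 count exceeds
   100 in exactly one &Delta; direction — a QTL displaces the index of
   one bulk toward the carrier fraction and the other toward 0, while
   depth noise alone breaches the bands symmetrically. Qualifying
   windows merge into regions; the analysis is repeated with the parents
   swapped to find QTLs from either donor.

Away from any QTL both bulk indices hover near m/(2·ploidy) (0.125 for
tetraploid simplex); complete tail selection at a QTL drives &Delta; to
±m'/ploidy (±0.25 simplex, ±0.5 duplex).

The genotyping module classifies individual lines as
nulliplex/simplex/duplex from qPCR &Delta;Ct allele dosage,
fragment-analysis peak ratios, or amplicon-sequencing read fractions,
forms a consensus across assays, and χ²-tests the population's
segregation ratio.

## Worked example

Simulate a phosphorus-like experiment — a duplex allele of parent P2
that *lowers* the trait by 3 noise-SD per copy, 178 F1 lines, 18-line
tail bulks, depth 60 — and analyze it in both donor orientations:

```sh
$ plexqtl simulate --chrom-length 2000000 --density 0.005 \
    --simplex-frac 0 --duplex-frac 1 --qtl-mode additive \
    --qtl-donor P2 --qtl-plexity 2 --effect -3 --noise-sd 1 \
    --seed 7 --out demo
wrote 10219 variants for 4 samples to demo/simulated.vcf (bulk fractions 10.1% / 10.1%)

$ plexqtl run demo/simulated.vcf --nplex 2 --both-orientations --seed 7 --out demo/qtlseq
donor=P1: 4800 variants analyzed, 0 candidate region(s) -> demo/qtlseq/donor_P1/regions.tsv
donor=P2: 4888 variants analyzed, 1 candidate region(s) -> demo/qtlseq/donor_P2/regions.tsv

$ cat demo/qtlseq/donor_P2/regions.tsv
chrom   start   end     direction       peak_p99_count  donor   plexity
chr01   1       1999229 negative        287     P2      2
```

The planted QTL is recovered only in the true donor's orientation, with
a negative &Delta;SNP-index direction — Bulk1 is the high-phenotype
tail, so the trait-lowering allele is enriched in Bulk2 (windows at the
causal position average bulk indices of 0.000 and 0.479: complete
selection). Rerunning the same VCF with `--nplex 1` leaves only 75
variants (duplex variants whose parental read draw strays into the
simplex index window) and calls no candidate region in either
orientation: the duplex QTL is invisible to a simplex-only analysis.

Genotyping the reference panel (the two parents and their 1:1 DNA mix,
which mimics a simplex line) across all three assay families:

```sh
$ plexqtl genotype assays.tsv
individual  call_amplicon:site1  call_fragment  call_qpcr  consensus   concordant
MIX         simplex              simplex        simplex    simplex     True
P1          nulliplex            nulliplex      nulliplex  nulliplex   True
P2          duplex               duplex         duplex     duplex      True
```

and testing an observed F1 segregation of 39:101:38 against the 1:4:1
duplex expectation:

```pycon
>>> from plexqtl.genotyping import segregation_chi_square
>>> stat, df, p, expected = segregation_chi_square([39, 101, 38], [1, 4, 1])
>>> round(stat, 3), df, round(p, 4), [round(e, 1) for e in expected]
(7.907, 2, 0.0192, [29.7, 118.7, 29.7])
```

a mild distortion from 1:4:1 (P ≈ 0.02), as a real duplex locus under
viability selection might show.

## Layout

| module | contents |
| --- | --- |
| `plexqtl.genetics` | tetrasomic segregation distributions, expected indices |
| `plexqtl.simulate` | parents, meiosis, phenotypes, bulks, read sampling |
| `plexqtl.core` | plexity filter, null thresholds, P values, windows, regions |
| `plexqtl.genotyping` | qPCR/fragment/amplicon dosage calls, consensus, χ² |
| `plexqtl.io` | VCF in, TSV/BED/manifest out, run configuration |
| `plexqtl.cli` | `plexqtl simulate / run / genotype / null-calibrate` |

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.
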