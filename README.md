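# mhcpopgen

Population-genetic analysis of MHC class II *DRB* exon-2 diversity when a
single primer pair co-amplifies several duplicated loci — the standard
situation in wildlife immunogenetics surveys. The package was built around a
study design of 122 golden snub-nosed monkeys (*Rhinopithecus roxellana*)
from three Qinling Mountains populations genotyped at two co-amplified
*DRB* loci, and covers that analysis end to end:

1. **Allele validation** from clone sequencing: a distinct sequence is a
   real allele only if seen in ≥ 2 individuals or in ≥ 3 independent PCRs of
   one individual (or it matches a published allele); everything else is
   treated as a PCR artifact. Translation screening flags stop codons,
   frameshifts and in-frame indels.
2. **Assignment of alleles to loci** (the hardest step): with *m* duplicated
   loci each individual yields a pooled, locus-unresolved set of 2–4
   alleles. The package partitions the allele panel into loci by maximizing
   the Hardy–Weinberg likelihood of the whole sample,

   L(partition) = Π_i Σ_{d ∈ D_i} Π_l P_HWE(g_l(d)),

   where D_i are the per-locus genotype decompositions compatible with
   individual *i*'s observed set and P_HWE = p², 2p_a p_b. Locus allele
   frequencies are EM estimates over the latent decompositions, candidate
   partitions are scored by AIC = 2k − 2lnL or BIC = k·ln n − 2lnL with
   k = Σ_l (k_l − 1), and the partition space is searched by simulated
   annealing (Metropolis acceptance, geometric cooling, restarts) with an
   exhaustive set-partition enumerator as oracle for small panels.
3. **Diversity and differentiation**: Nei's unbiased gene diversity H_E,
   observed heterozygosity H_O, Botstein's PIC, effective allele number
   A_E = 1/Σp², hypergeometric rarefaction A_R(g), Weir–Cockerham θ/f/F (and
   Nei's G_ST), Chakraborty/Brookfield null-allele estimators, the
   Guo–Thompson exact HWE test (full enumeration or Markov chain with switch
   proposals), Mann–Whitney U and Bonferroni helpers. Integer allele counts
   can be reconstructed from printed (rounded) frequency tables by
   largest-remainder rounding.
4. **Selection statistics**: variable/parsimony-informative sites, pairwise
   p-distances with site-bootstrap SEs, Nei–Gojobori (1986) d_N/d_S with
   Jukes–Cantor correction and codon-bootstrap SEs over an antigen-binding
   site (ABS) mask, the one-sided Z-test for d_N ≠ d_S, and Tajima's D on
   population samples of gene copies reconstructed from allele counts.
5. **Simulators** for every input: duplicated-locus clone-sequencing data
   with known truth (HWE genotypes, null alleles, PCR artifacts),
   island-model multi-population genotypes with a target F_ST
   (Balding–Nichols), and codon alignments with site-class-specific ω.

## Worked example

Rebuild the published per-population diversity summary from the bundled
printed allele-frequency table (counts are reconstructed per population ×
locus, pooled rows follow the conventional mixed semantics — H_E/PIC from
pooled counts, A_E as the across-population mean):

```bash
mhcpopgen stats --freqs src/mhcpopgen/data/rhro_drb_allele_frequencies.csv --out stats.csv
```

```
population locus   n  k    h_exp      pic      a_e      a_r
        FP  DRB1  32  6 0.580605 0.542259 2.337690 5.994120
        NS  DRB1  36  7 0.636933 0.605607 2.691589 6.992700
        ZZ  DRB1  54  8 0.748537 0.700541 3.877698 6.898513
       All  DRB1 122 11 0.697357 0.664937 2.968992 8.029843
        FP  DRB2  30  4 0.523729 0.478531 2.064220 4.000000
        NS  DRB2  36  6 0.627465 0.589429 2.617571 5.992814
        ZZ  DRB2  53  6 0.639676 0.578799 2.729801 5.529842
       All  DRB2 119  8 0.621072 0.584415 2.470531 6.352274
```

Reading the FP/DRB1 row: from the printed frequencies at n = 32, the locus
carries 6 alleles with unbiased gene diversity 0.581, PIC 0.542, an
effective allele number of 2.34 (diversity concentrated in one common
allele), and an expected 5.99 distinct alleles in a rarefied sample of
g = 60 gene copies (the smallest sample in the study, FP/DRB2).

A full simulated round trip — generate clone data, validate alleles,
assign them to two loci, call genotypes, summarize:

```bash
mhcpopgen simulate multilocus --seed 3 --out-dir sim/
mhcpopgen validate --clones sim/clones.csv --known sim/alleles.fasta \
    --out alleles.fasta --sets sets.csv
mhcpopgen assign --sets sets.csv --loci 2 --seed 1 --allow-null \
    --out config.json --genotypes genotypes.csv
mhcpopgen stats --genotypes genotypes.csv --out stats.csv
```

`config.json` records the best partition with its frequencies, lnL, AIC and
BIC; on data of this size the annealed search returns the same optimum as
exhaustive enumeration of all set partitions.

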