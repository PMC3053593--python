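# utrsnp

Targeted SNP discovery for species with duplicated genomes.

## The problem

In partially tetraploid species such as salmonids, a recent whole-genome
duplication left large numbers of highly similar paralogous gene copies.
PCR primers placed in conserved coding sequence routinely co-amplify a
gene and its paralog, and every fixed difference between the two copies —
a *paralogous sequence variant* (PSV) — then masquerades as a
heterozygous SNP in every individual tested.  `utrsnp` implements a
discovery strategy built around two observations:

1. **3'UTRs diverge faster than CDSs.**  Full-length-sequenced cDNAs
   (FLIcs) provide the complete 3'UTR of each target gene, so primers can
   be placed where paralogs differ most, keeping amplification
   locus-specific, and where SNP density is highest.
2. **A PSV betrays itself in a population panel.**  A true SNP segregates
   by Hardy-Weinberg: the probability that all *n* diploid individuals
   are heterozygous is (2*pq*)^*n* ≤ 0.5^*n* — about 0.001 for a
   10-individual panel.  A co-amplified fixed difference is heterozygous
   in *everyone*, so total heterozygosity is grounds for exclusion.

The package covers both discovery routes end to end: 3'UTR-primed
amplicon design straight from annotated FLIcs, and *in silico* candidate
mining from EST-to-FLIc alignments followed by candidate-spanning
amplicon design; both converge on the same panel-genotyping validation
(≥ 2 carriers of the rare allele, extension typing for single carriers,
PSV exclusion) and summary statistics.  A synthetic-data module
simulates paralog pairs with tunable divergence, diploid panels with
planted SNPs/DIPs at chosen minor-allele frequencies, and error-bearing
ESTs, so every stage is testable without real data.

## Worked example

```bash
utrsnp simulate --out demo/ --seed 17
utrsnp mine --flics demo/targets.fa --annot demo/targets.tsv \
            --ests demo/ests.fa --out demo/candidates.tsv
utrsnp design --method utr_primed --flics demo/targets.fa \
              --annot demo/targets.tsv --out demo/designs.tsv
utrsnp genotype --panel demo/panel.fa --flics demo/targets.fa \
                --annot demo/targets.tsv --vcf demo/out.vcf --tsv demo/out.tsv
```

which prints:

```
wrote 20 targets, 7 paralogs, 100 ESTs, 20 panels to demo
wrote candidates (329 passing) to demo/candidates.tsv
wrote 19 designs to demo/designs.tsv, 1 failures to demo/designs.failures.tsv
20 amplicons (0 failed QC), 35 validated variants
```

Reading the numbers: 20 simulated genes, 7 of which carry a paralog
copy at the default 3% 3'UTR divergence.  Mining the 100 simulated ESTs
leaves 329 candidate sites after the filter chain (96% identity floor,
> 4 differences per 100 bp paralog rule, 50-bp read-end trim,
simple-repeat mask).  Most of those are paralog-derived: at 3%
divergence a paralogous EST averages only ~3 differences per 100 bp and
slips under the clustering rule — exactly the false-positive burden
that makes the downstream panel validation necessary.  The 3'UTR-primed
designer returns a 350-450 bp amplicon for 19 of the 20 genes (the one
failure is a 3'UTR shorter than the 350 bp minimum product — reason
codes are in the failures table) with both primers inside the 3'UTR,
melting temperatures scored against a 60 °C optimum, and M13 sequencing
tails prepended.  Panel genotyping of the 10-individual panel validates
35 variants: rare allele carried by ≥ 2 individuals, no site
heterozygous in all individuals.  `demo/out.vcf` is VCF 4.2 with
per-individual genotypes and INFO fields REGION, EFFECT, CARRIERS and
ALLHET_P.

The same machinery is importable as a library:

```python
from utrsnp import all_het_probability, chi2_2x2

all_het_probability(10, 0.5)   # 0.0009765625 -> the 0.001 PSV p-value
chi2_2x2(14, 46, 6, 54).statistic  # 3.84, df 1: method comparison
```

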