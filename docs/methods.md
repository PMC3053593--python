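# Methods

## System and model

`utrsnp` models targeted SNP discovery in a partially tetraploid genome:
most genes have a recently duplicated paralog, and the two copies have
accumulated point differences — fast in the selectively permissive 3'UTR,
slowly in the coding sequence.  The discovery targets are full-length
insert cDNAs (FLIcs): transcripts with an annotated CDS and a complete
3'UTR.  Two discovery routes are implemented.

**3'UTR-primed route.**  A 350-450 bp amplicon is designed entirely
within the 3'UTR, amplified (here: extracted in silico), and sequenced
in a small diploid population panel.  The panel step is simultaneously
discovery and validation.

**In silico mining route.**  Single-pass EST reads are aligned to the
FLIc; the surviving differences are putative SNPs; a short 130-170 bp
amplicon spanning the candidate is then genotyped in the same panel.
The short product limits co-amplification of introns when the template
is genomic DNA.

### Validation model

Each of the *n* panel individuals (default 10) contributes a Sanger-style
consensus with heterozygous positions as IUPAC ambiguity codes.  Per
aligned column, calls decode to diploid genotypes; columns with two
observed alleles become candidate variant sites.  Three rules:

1. **Amplicon QC** — if the initial two-individual screen shows ≥ 5
   heterozygous columns (pooled over the two individuals), the amplicon
   is discarded as co-amplifying or low quality.
2. **Carrier rule** — the rare allele must be carried (het or rare
   homozygote) by ≥ 2 individuals.  A single carrier triggers a request
   for an extension typing of 5 further individuals; the carrier and PSV
   rules are then re-tested on the pooled 15.  "Carrier" counts
   individuals, not chromosomes.
3. **PSV rule** — a site heterozygous in *every* called individual is
   excluded as a paralogous sequence variant.  Under Hardy-Weinberg the
   all-heterozygote probability is (2pq)^n, maximal at p = 0.5:
   0.5^10 ≈ 0.000977 ≈ 0.001 for the default panel.  The module also
   reports the exact conditional heterozygote-excess probability
   (sum over genotype tables with the observed allele counts and at
   least the observed heterozygote count, weights
   n!/(n_AA! n_Aa! n_aa!)·2^n_Aa·n_A!n_a!/(2n)!), but partial excess
   does not auto-exclude: only total heterozygosity does, which is the
   stated criterion of the protocol this follows.  Exclusion on the
   general excess probability is available but off by default.

Missing calls (N) shrink n; sites with fewer than 6 called individuals
carry a low-power flag because (2pq)^n loses discrimination quickly.

CDS SNPs are classified synonymous/missense/nonsense by translating the
affected codon under the standard genetic code; CDS DIPs are
frameshifts.  DIPs are validated by the same carrier rule as SNPs.

### EST filter chain (mining route)

An EST alignment (global, free end gaps; match +1, mismatch −2, gap
open −5, gap extend −2) is usable evidence only if:

* identity ≥ 0.96 over aligned columns;
* aligned length ≥ 100 columns.  This stands in for a database E-value
  cutoff, which has no meaning without a database context; at
  transcript scale the identity floor plus a length floor dominates it;
* no 100-column window contains > 4 differences — more indicates a
  paralogous source, and *every* difference in such an EST is
  disqualified, not just the clustered ones.  (The protocol's two
  sections print ">3" and "more than 4" as examples; the operational
  Methods figure of 4 is the default, configurable.)

Per difference column, two further rules: differences within the first
or last 50 bases of the EST read itself (read-end quality decay;
measured in the read's own coordinates, orientation-corrected) and
differences inside simple repeats of the target are not candidates.
"Simple repeat" is operationalized as homopolymer runs ≥ 5 nt and
perfect di-/tri-nucleotide tandem repeats ≥ 3 units (configurable);
the named concern is poly-G/C runs, which this covers.

Evidence is merged per site: a site is a candidate when ≥ 1 EST
supports it cleanly (configurable), even if other ESTs covering it were
rejected — per-EST filters are evidence filters, not site vetoes.
Rejected-only sites are reported with a rejection status under a fixed
precedence (identity, short, paralog, end-trim, repeat) so nothing is
silently dropped.

### Primer design

Product-size windows are hard constraints per method: 350-450 bp
(UTR-primed), 130-170 bp (candidate-spanning), 200-250 bp (the
exon-primed intron-crossing configuration, kept as an experimental size
range only — without genomic sequence no intron can actually be
crossed).  Within the window the best pair minimizes
|Tm − 60 °C| per primer + 50·(GC distance outside [0.35, 0.65])
+ 0.05·|product − range midpoint|, plus 5 (+1 per extra base) when the
two 3' ends can anneal over ≥ 4 nt (primer-dimer proxy).  Primer length
18-24 nt; ties break leftmost-then-shortest, so designs are
deterministic.  The candidate must sit ≥ 20 nt inside both primers in
candidate-spanning mode.  The pair search scores the full
(start, product-length) grid exactly on the Tm/GC/length terms and
applies the dimer penalty by re-scoring the 200 best base-score pairs —
a bounded, deterministic heuristic (the dimer term is small and rarely
reorders beyond that depth).  Universal M13 tails
(5'-TGTAAAACGACGGCCAGT / 5'-CAGGAAACAGCTATGACC) are prepended to the
returned tailed primers; the reverse tail's source notation ends in a
stray "2", read here as a typo for "3'" and the tail as the standard
18-mer.

Melting temperatures use unified nearest-neighbor thermodynamics
(dimer-stack ΔH/ΔS plus terminal initiation terms) at fixed standard
conditions — 50 mM monovalent salt, 0.25 µM total oligo, entropy salt
correction 0.368·(N−1)·ln[Na⁺] — implemented in the package and
cross-checked in the tests against Biopython's independent
implementation; the Wallace rule 2(A+T)+4(G+C) is available as a
documented alternative.  The original protocol used primer3 defaults;
this module is a self-contained scorer with the protocol's stated size
and Tm settings (primer length and GC bounds are primer3-like defaults,
i.e. package decisions, not protocol values), so primer3 is not a
dependency.

## Synthetic data generator

The generator emulates the study conditions; its defaults are the
stated study parameters where they exist and fixed realistic choices
where they do not.

| parameter | default | why |
|---|---|---|
| panel size / extension | 10 / 5 | the study's validation panel and extension |
| 3'UTR length | 200-800 nt | typical annotated 3'UTR range |
| CDS length | 300-1500 nt | typical complete CDS range (forced to a codon multiple, ATG…stop) |
| paralog fraction | 0.5 | a recently duplicated genome: duplicate status common but not universal |
| paralog 3'UTR divergence | 0.03/base | free parameter of the system; keeps paralogs just above the 0.96 mining floor |
| CDS divergence factor | 0.3× | CDS conservation relative to 3'UTR |
| planted variants per gene | 2, MAF ∈ {0.05, 0.1, 0.25, 0.5} | spans rare-to-common validation regimes |
| DIP fraction | 16/79 | the observed DIP share among discovered polymorphisms |
| EST error rate | 0.01/base | single-pass Sanger read accuracy |
| ESTs per gene, length | 5, 300-600 nt | small public EST coverage per gene |

Panel genotypes are two independent allele draws per individual at the
site's minor-allele frequency (Hardy-Weinberg sampling), emitted as
IUPAC consensus.  In co-amplification mode the paralog allele joins
each individual's allele set, so every fixed difference becomes an
all-heterozygote column — the PSV signature.  ESTs are windows of
allelic haplotypes (alleles drawn at MAF) or of the paralog, with
uniform substitution errors; optional single-base deletion errors at
half that rate.  Base composition is uniform with no
transition/transversion bias (no substitution model is specified by the
protocol; uniform is the minimal assumption).  DIPs are single-base
deletions (minimal case; lengths unspecified in the protocol).  An
optional flag plants poly-G/C runs (6-10 nt) to exercise the repeat
mask.

Determinism: each top-level operation derives its RNG from the config
seed plus a fixed stream offset, so a given config yields byte-identical
FASTA/JSON regardless of call order.

**Artifact conventions.**  The IUPAC alphabet has no heterozygous
base/gap code, and how heterozygous DIPs appear in a Sanger consensus
is genuinely ambiguous (frameshifted double traces).  The package uses
lowercase a/c/g/t for a base/gap heterozygote and '-' for a homozygous
single-base deletion; this keeps encode/decode a bijection and genotype
counts well defined.  It is a file-format convention of this package,
not a community standard.

**What the simulation does not capture**: coalescent genealogy,
linkage/recombination, selection, realistic per-base quality decay
along reads (errors are uniform, not end-loaded — the end-trim filter
is therefore exercised by position, not by an error gradient), intron
structure (so in silico PCR product length is exact), and multi-gene
families beyond a single paralog.  Passing tests demonstrate the
pipeline's rules behave as specified under these conditions; they do
not measure wet-lab PCR or sequencing success rates.

## Statistics

Stage success rates are reported as printed-table arithmetic: value =
numerator/denominator, half-up at 2 decimals, alongside the fraction;
zero denominators print "-".  For the mining strategy the initial-PCR
rate divides by candidates (one amplicon per candidate), for the
UTR-primed strategy by genes.  SNP density is scanned bp per (SNP+DIP),
half-up to the nearest 10.  The 2×2 method comparison is Pearson
chi-square without continuity correction (the uncorrected statistic is
what the printed 60-gene table reproduces: 3.84 at df 1), with Yates
and one/two-sided Fisher exact companions always co-reported.  The
published p-values for the two method-comparison tests (0.001 and
0.028) are not reproducible from the printed counts under any of these
formulations; the module reports all variants and leaves the
discrepancy visible rather than matching those numbers.  Likewise the
published candidate-rate row (0.82 beside 131/168) does not re-divide;
the fraction governs, surfacing as 0.78.  The published gene-count
discrepancy for the mining strategy (158 in text, 168 in the table) is
resolved in favor of the table for table-derived computations.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; every file and report
  is 1-based inclusive.
* Alignment ties: the aligner's first-reported optimal alignment is
  used; scoring is fixed, so results are reproducible.
* Columns implying > 2 alleles are flagged and excluded (bi-allelic
  model), never fatal.
* All-N consensus rows fail amplicon QC as quality failures; N calls
  are missing data, not alleles.
* `heterozygote_excess_exact` enumerates genotype tables directly with
  integer combinatorics (exact, no factorial overflow via
  `math.comb`); panels of the sizes involved (≤ tens) are far below
  any cost concern.
* Paralog divergence > 0.25 triggers a warning: the alignment-based
  mining assumptions (a single well-defined column homology) degrade.

## Known limitations

* The EPIC mode designs on transcript coordinates only; true
  intron-crossing design needs genomic sequence, which the data model
  does not include.
* The E-value surrogate (min aligned length) is equivalent to the
  original criterion only for transcript-scale alignments; for very
  short references both it and the identity floor weaken.
* VCF output anchors DIPs on the preceding reference base and therefore
  drops a deletion at column 0 of an amplicon without a reference row.
* The exact heterozygote-excess probability is reported but, by
  default, only total heterozygosity excludes a site.
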