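# orievolve

Simulation and analysis of directed-evolution screens for plasmid
copy-number variants.

Broad-host-range plasmid origins of replication (pVS1, RK2, pSa, BBR1 and
relatives) set their copy number through a replication-initiation protein,
RepA, whose monomer/dimer balance throttles replication. Random
substitutions in *repA* can raise or lower copy number, and a
growth-coupled selection makes those variants findable at scale: put a
salicylic-acid-inducible gentamicin-resistance gene on the plasmid, so that
resistance dose scales with copy number, and grow an error-prone-PCR mutant
library across an 8 x 12 antibiotic x inducer checkerboard. Wells lethal to
the wild type but permissive for the library enrich copy-up mutants, and
deep-sequencing the *repA* amplicon before and after selection turns each
mutation's allele-frequency fold change into a per-residue enrichment map.

`orievolve` implements that whole analysis as a reusable, tested library for
people designing or interpreting such screens: a synthetic-data generator
for every input (mutant libraries with known causal residues, selection,
paired-end reads, dPCR plates, growth curves), the read-to-counts stage
(gapless seed-and-extend mapper plus a mate-aware pileup, or a SAM reader
for externally aligned data), the enrichment statistic, and the downstream
quantifications and panel statistics.

## The central statistic

For every (position, alternate base) allele the screen computes

    FC = ((k_sel + 1/2) / (n_sel + 1)) / ((k_unsel + 1/2) / (n_unsel + 1))

where `k` is the alt-allele read count and `n` the usable depth
(Haldane-Anscombe pseudocount: FC stays finite and maps to its exact
reciprocal when the samples are swapped). A two-sided Fisher exact test per
allele with Benjamini-Hochberg correction flags significant enrichment;
nucleotide alleles are annotated with their codon consequence, each residue
is scored with the maximum FC over its nonsynonymous alleles, and the top-k
residues become candidates.

Supporting quantifications follow the field's standard forms: digital-PCR
copy number as `lambda = -ln(1 - k/n)` per channel and copies/cell as the
target:reference lambda ratio with a delta-method CI; growth as a
three-parameter logistic fit reported in doublings per hour (`r / ln 2`,
i.e. 60 divided by the doubling time in minutes); and panel statistics
(polynomial OLS with adjusted R^2 and F-test, Tukey HSD with compact letter
displays, Fisher/Welch count tests, Pearson + BH, interface-membership
enrichment).

## Worked example

`examples/sequencing_and_enrichment.py` runs a scaled-down screen — a
300 nt ORF, 2,000-clone epPCR library, three planted causal residues at a
x5 copy multiplier, 30,000 read pairs per population — and prints:

```
selection condition: well C12 (750 mg/L gentamicin, 5.00 uM salicylic acid)
planted causal residues: [21, 49, 97]

top candidate residues (fold change = selected/unselected allele-frequency ratio, max over nonsynonymous alleles):
  * residue  97  FC   35.21  (S97F, q = 0.00e+00)
  * residue  49  FC   28.95  (S49G, q = 0.00e+00)
  * residue  21  FC   27.30  (S21P, q = 0.00e+00)
    residue  74  FC   16.88  (A74P, q = 1.65e-125)
    ...

recall of planted residues in the top 10: 1.00; precision 0.30
```

The three planted residues (starred) rank first by fold change, cleanly
separated from passenger mutations that hitch-hiked in surviving clones.
The selection well was chosen automatically from the simulated
checkerboard as the strongest condition that kills the wild type but not
the library. The other examples cover the library generator, the
checkerboard surface, dPCR copy-number quantification, growth-rate fitting
and the panel statistics; each prints the numbers it computes and a line on
what they mean.

A thin CLI mirrors the library for shell use:

```bash
orievolve simulate --seed 1 --outdir screen/
orievolve count --ref screen/reference.fasta \
    --r1 screen/selected_R1.fastq.gz --r2 screen/selected_R2.fastq.gz \
    --out sel.tsv
orievolve enrich --ref screen/reference.fasta --sel sel.tsv --unsel unsel.tsv
orievolve dpcr --plate plate.csv
orievolve growth --table od.tsv
```

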