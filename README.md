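# edbsa

Bulked segregant analysis (BSA) for haplodiploid crosses: map a causal
locus from pooled sequencing of phenotype-sorted haploid drones with a
per-SNP Euclidean-distance (ED) genome scan, then narrow candidates by
variant consequence and per-individual allele frequencies.

The package contains six modules:

| module | what it does |
| --- | --- |
| `edbsa.simcross` | forward simulator: gametes of one heterozygous queen become haploid drones, a single causal locus sets the phenotype, pools are sequenced at finite depth with miscalls; emits VCF/GFF3/FASTA/genotype/truth files |
| `edbsa.formats_io` | VCF (per-pool AD), GFF3, FASTA, BED, TSV readers/writers plus the QD/FS/MQ variant hard filter |
| `edbsa.edscan` | per-SNP ED, the power-4 transform, per-chromosome Lowess smoothing, quantile threshold, candidate-region calling |
| `edbsa.annotate` | site classification (synonymous/nonsynonymous/stopgain/splicing/intronic/up/downstream/intergenic), the nonsynonymous-in-region candidate-SNP filter, and the per-individual allele-frequency gene filter (=1 in mutants, <0.1 in wild types) |
| `edbsa.consequence` | CDS editing, translation, frameshift / premature-stop detection, protein-domain disruption reporting |
| `edbsa.crossstats` | R×C Pearson chi-square (no continuity correction) with pairwise post hoc tests, 1:1 segregation check, rate summaries, 2^-dCt relative expression with one-way ANOVA |

## CLI

One console script, `edbsa`, with five subcommands:

```bash
# simulate a 15+15 drone cross (YAML config; see tests/test_cli.py for the schema)
edbsa simulate --config cross.yaml --out-dir sim/ --seed 7

# ED scan + candidate regions
edbsa edscan --vcf sim/pools.vcf --mut-sample MUT --wt-sample WT \
    --power 4 --quantile 0.995 --span 0.1 --min-snps 10 --out-prefix scan --plot

# classify every SNV against the gene models
edbsa annotate --vcf sim/pools.vcf --gff sim/genes.gff3 --fasta sim/genome.fa \
    --out annotations.tsv

# frameshift / premature-stop prediction for candidate variants
edbsa consequence --gff sim/genes.gff3 --fasta sim/genome.fa \
    --variants candidates.tsv --domains domains.tsv --out report.tsv

# contingency statistics
edbsa stats chisq --table table.tsv --posthoc
edbsa stats segregation --a 100 --b 110 --ratio 1:1
edbsa stats expression --matrix expr.tsv
```

### Threshold modes

The scan threshold is the genome-wide top-0.5% quantile of raw ED. For
region calling the smoothed ED⁴ curve is compared against a per-chromosome
threshold; by default (`--threshold-mode loco`) that reference quantile is
taken over the *other* chromosomes (a null-background reference), which is
equivalent to the global quantile when linked markers are a negligible
fraction of the genome and remains well defined for small synthetic scans
where the global quantile saturates at the ED maximum of √2. Use
`--threshold-mode global` for the single-threshold variant.

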