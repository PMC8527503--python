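# ctenokit

Genome analytics for highly heterozygous animal genomes — built around the
bespoke procedures used to characterize chromosome-scale ctenophore
assemblies, where SNP+indel heterozygosity of a few percent, genes nested
inside other genes' introns, trans-spliced leader sequences, and very small
TADs all complicate standard tooling.

It is aimed at genome-assembly and comparative-genomics practitioners who
have a composite (haplotype-collapsed) assembly, an annotation, read
pileups, protein hit tables, and TAD calls — and who need the downstream
numbers: how heterozygous is this individual, how many nested intronic
genes are there, which chromosomes are homologous between two species, how
common is the spliced leader, and do TAD boundaries track gene edges.

## What it computes

**Depth-conditioned heterozygosity** (`ctenokit.heterozygosity`). In a
collapsed diploid assembly, sites where reads from both haplotypes map
pile up at the modal mapping depth D\*, while collapsed single-haplotype
regions sit near D\*/2. Restricting to sites at exactly D\* and calling a
site heterozygous when its reference-allele fraction f = ref/depth falls
in a balance band (default 0.30 ≤ f ≤ 0.70, i.e. "about half the reads")
gives

&nbsp;&nbsp;&nbsp;&nbsp;ĥ = (het sites at D\*) / (all sites at D\*),

reported separately for SNP and indel alleles, per chromosome, and per
region class (exonic > intronic > intergenic precedence). This sidesteps
both assembly errors (wrong depth) and variant-caller artifacts.

**Nested intronic (NI) genes** (`ctenokit.nested`). A gene is NI when a
transcript lies within a single intron of another gene, allowing up to
15% of the transcript's length to overlap the host's flanking exons at
each end. The longest 0.5% of introns are excluded first (they are
largely artifacts of leader-sharing first exons). The census reports
doubly nested genes, the percent of exonic bp contributed by NI genes,
and TE-flanked NI genes.

**Microsynteny and macrosynteny** (`ctenokit.synteny`). Orthologs are
reciprocal best hits; collinear blocks are chains of orthologs in
conserved (forward or inverted) order requiring ≥ 3 genes, ≤ 5
intervening genes, and ≤ 30 kb to the next gene — enforced on both
genomes. Oxford dot-plot coordinates and per-chromosome plurality
partners summarize whole-chromosome homology.

**Trans-spliced leader** (`ctenokit.leader`). Scans a genome for the
44-bp leader motif at ≥ 90% identity over a 35–48 bp window (semi-global
alignment, both strands), measures the fraction of transcript reads
carrying the leader as a 5′ prefix, clusters genes sharing a leader-like
first exon, and tallies transcript start dinucleotides.

**TAD boundaries vs genes** (`ctenokit.tads`). Median distance from TAD
boundaries to the nearest gene, tested against a null built from 1000
size-preserving random placements; one-sided add-one p-value, so the
attainable minimum is 1/(n+1).

**Synthetic data** (`ctenokit.simulate`). Seeded generators for each
input type with planted, recorded ground truth — diploid pileups,
nested-gene annotations, rearranged ortholog tables, leader-bearing
sequences, TAD landscapes.

## Worked example

Estimate heterozygosity from a simulated 1-Mb diploid pileup at 178×
mean depth with 2% SNP and 1.2% indel heterozygosity:

```python
from ctenokit.simulate import SimulationConfig, simulate_diploid_pileup
from ctenokit.heterozygosity import build_depth_histogram, estimate_heterozygosity

cfg = SimulationConfig(seed=1, length=1_000_000)
truth, pileup = simulate_diploid_pileup(cfg)
hist = build_depth_histogram(pileup)
print("modal depth:", hist.modal_depth)
for cls in ("snp", "indel", "combined"):
    est = estimate_heterozygosity(pileup, hist.modal_depth, variant_class=cls)
    print(cls, round(est.heterozygosity, 5), "over", est.sites_total, "sites")
```

prints

```
modal depth: 177
snp 0.0203 over 30053 sites
indel 0.01274 over 30053 sites
combined 0.03304 over 30053 sites
```

— the modal depth lands within 1× of the Poisson mean, and the
estimates at that depth recover the planted 2.0% / 1.2% / 3.2% rates to
within binomial noise over the ~30,000 sites at the mode.

The same stages are available from the shell:

```sh
ctenokit --seed 5 --out-dir sim simulate tads --n-tads 50
ctenokit --seed 5 --out-dir out tadperm --tads sim/tads.bed --gff sim/tad_genes.gff3 -n 999
# -> observed median 0 bp, p = 0.001
```

Subcommands: `het`, `nested`, `synteny`, `leader`, `tadperm`, `coverage`,
`simulate {pileup,annotation,orthologs,leader,tads}`. Each writes TSV/JSON
results plus a `*.meta.json` recording parameters and seed.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions, and the limits of what the synthetic data can show.
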