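# somasim

Benchmarking somatic variant callers needs gold-standard tumoral
samples — genomes whose every mutation is known, with sequencing reads
whose noise looks like real data. Real gold standards cover only a
couple of cancer types, so `somasim` builds them in silico, for anyone
developing or tuning variant-calling pipelines:

1. **Defining variants.** A mutation catalogue (a COSMIC/TCGA-style
   export) is mined into cancer-specific *presets*: variant-type and
   zygosity proportions (pooled and per sample), and empirical
   distributions of per-sample totals, event lengths and inter-variant
   distances, each fitted to ten families (Weibull, lognormal, normal,
   negative binomial, exponential, logistic, Poisson, gamma, geometric,
   Cauchy) and scored by six goodness-of-fit metrics (AIC, BIC, KS, AD,
   CvM, χ²) with a majority-vote best family. A design procedure turns
   a preset into a concrete VAR file, optionally expanding a clonal
   tree (`parent child distance` edges) into one VAR file per clone.
2. **Editing the genome.** VAR lines are applied *sequentially* to both
   haplotype copies of a template genome through an explicit position
   map `j` over template coordinates `p`: an insertion of `L_ins` bases
   at `t` shifts `j[t:]` up by `L_ins`; a deletion of `L_del` bases
   marks `j[t:t+L_del]` deleted and shifts the rest down. Because
   insertion content can be extracted from the genome *currently being
   edited*, overlapping and order-sensitive complex events are
   first-class. Outputs: two haplotype FASTAs, the serialized maps, a
   ground-truth VCF (template coordinates, ref-equal SNPs flagged) and
   a BED of regions centered on the variants.
3. **Generating reads.** Coverage (RDM), base-quality (QM) and
   position-based error (PBEM) models are learned from real aligned
   BAMs, converted through the map into the mutated genome's
   coordinates, and used to generate paired-end FASTQ reads
   (`N = ceil(G·C/L)` for coverage `C` over `G` bases of interest at
   read length `L`). Mixing reads across clones and haplotypes realizes
   VAF and clonality targets exactly; read names
   (`{clone}|{hap}|{serial}/{mate}`) keep every read traceable.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

`somasim.fixtures` generates all inputs synthetically, so the whole
pipeline runs without downloads:

```python
from somasim.fixtures import make_catalogue, make_genome
make_catalogue(n_samples=40, zyg_props={"het": 0.9, "hom": 0.1}, mean_variants=80,
               chrom_lengths={"chr1": 60_000, "chr2": 30_000}, seed=7,
               tsv_path="catalogue.tsv")
make_genome({"chr1": 60_000, "chr2": 30_000}, seed=11, fasta_path="template.fa")
```

```console
$ somasim preset build --catalogue catalogue.tsv --cancer-type breast \
      --db-tag demo --out preset.json
{
 "cancer_type": "breast",
 "best_families": {
  "total_variants": "weibull",
  ...
  "distance_SNP": "geometric",
  ...
 }
}
$ somasim design --preset preset.json --fasta template.fa \
      --total 100 --het 0.9 --seed 5 --out design
wrote design/sample.var (110 lines)
$ head -4 design/sample.var
#VID	MID	HAP	CHR	POS	DEL	DEL_SPAN	INS	INS_SEQ
M00094_h0	M00094	0	chr2	5019	True	7	True	TCT
M00072_h0	M00072	0	chr2	19742	True	6	False	none
M00072_h1	M00072	1	chr2	19742	True	6	False	none
```

100 designed variants became 110 VAR lines: the 10 homozygous ones
(`--het 0.9`) occupy two lines sharing a MID, one per haplotype
(M00072 above); heterozygous variants sit on haplotype 0 only.

```console
$ somasim edit --var design/sample.var --fasta template.fa \
      --flank 200 --out edited --seed 5
edited 110 VAR lines -> 100 variants; outputs in edited
$ grep -v "^##" edited/truth.vcf | head -4
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	SAMPLE
chr2	5020	M00094	AGCGCCC	TCT	.	PASS	VID=M00094_h0;MID=M00094	GT	0/1
chr2	19742	M00072	GCTAAAG	G	.	PASS	VID=M00072_h0;MID=M00072	GT	1/1
chr1	22382	M00004	T	A	.	PASS	VID=M00004_h0;MID=M00004	GT	0/1
```

One VCF record per variant: the 7-bp deletion M00072 is left-anchored
and genotyped `1/1` (homozygous); the delins M00094 substitutes 7 bp
with `TCT` as `0/1` (heterozygous).

Reads for a targeted experiment over the variant regions, with the
coverage and error models disabled (flat starts, error-free reads):

```python
from somasim.genome_editor import HaplotypeGenome, PositionMap
from somasim.read_models import ModelBundle, read_bed
from somasim.read_generator import ReadRequest, compute_n_reads, generate_reads, write_fastq
import numpy as np

hap0 = HaplotypeGenome.from_fasta("edited/hap0.fa")
pmap = PositionMap.load("edited/map_hap0.txt")
regions = []                     # lift the template-space BED into hap0 coordinates
for chrom, s, e in read_bed("edited/regions.bed"):
    win = pmap[chrom][s:e]
    alive = np.nonzero(win != -1)[0]
    regions.append((chrom, int(win[alive[0]]), int(win[alive[-1]]) + 1))
G = sum(e - s for _, s, e in regions)
n = compute_n_reads(G, 100, 100, paired=True)      # C=100X, L=100
bundle = ModelBundle.uniform(regions)              # RDM and PBEM disabled
seqs = {c: hap0.sequence(c) for c in hap0.seqs}
res = generate_reads(seqs, bundle, ReadRequest(read_length=100, n_reads=n, paired=True, seed=5))
write_fastq(res.reads, "reads_R1.fastq", "reads_R2.fastq")
print(f"G = {G} bp  ->  {n} reads at 100X (L=100)")
```

```
G = 39916 bp  ->  39916 reads at 100X (L=100)
```

(39,916 rather than 100 × 400 bp because overlapping variant regions
were clipped at chromosome boundaries and some footprints merge in
coordinate space.) With the error model off, every one of those reads
is an exact substring of `hap0.fa` — the property the test suite
verifies.

To learn models from real data instead, use `somasim learn` (BAM +
reference + BED + optional known-sites VCF) and `somasim convert`
(models + map) before `somasim reads`; mixing clones and haplotypes to
hit VAF/clonality targets goes through `somasim.read_generator.mix`
with a `MixPlan`.

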