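# Methods

`somasim` simulates tumoral sequencing samples in three stages: it
*defines* somatic variants (optionally from data-driven presets and a
clonal tree), *edits* them into a template genome, and *generates*
paired-end reads whose technical characteristics are learned from real
aligned data. This note documents the models, the numerical choices,
and what the synthetic fixtures do and do not demonstrate.

## Sequential editing through a position map

Variants are applied in the order they appear in the VAR file, but each
variant's `POS` always refers to the *template* genome. The bridge is a
per-chromosome integer vector `j` over template coordinates
`p = 0..N-1`, initially the identity:

* **Insertion** of `L_ins` bases at template position `t` splices the
  new sequence immediately left of `j[t]` and increases `j[t:]` by
  `L_ins`.
* **Deletion** of span `L_del` at `t` removes the `L_del` mutated bases
  starting at `j[t]` (inclusive), marks `j[t : t+L_del]` with the
  sentinel `-1`, and decreases every later non-deleted entry by
  `L_del`.

Combined events execute as a deletion followed by an insertion. When
the deletion has consumed the anchor `j[t]`, the insertion attaches at
the first surviving template position ≥ `t` (appending at the
chromosome end if nothing survives); this keeps a delins contiguous.
Deleting a template position that an earlier deletion already consumed
has no defined meaning and is a hard error naming the variant.

Insertion content can be extracted from the genome *currently being
edited* (`self:CHR:START-END:xK:forward|reverse` in the `INS_SEQ`
field). The extraction takes the contiguous mutated slice between
`j[START]` and `j[END-1]`; only these two endpoint positions must be
alive. The interior may contain earlier edits — a substitution inside
the window is therefore carried into the inserted copy, which is what
makes order-sensitive overlapping events (SNP-then-duplication vs
duplication-then-SNP) expressible. A 1-bp delins whose inserted base
equals the template base is flagged (`REF_EQUAL` in the ground-truth
VCF) because no variant caller can detect it.

Zygosity is realized structurally: heterozygous variants are single VAR
lines on haplotype 0; homozygous variants are two lines sharing a MID
on haplotypes 0 and 1. The two haplotype genomes are edited
independently and each carries its own map. One VCF record is emitted
per MID (GT `0/1` or `1/1`), with positions in template coordinates,
left-anchored indel normalization (right-anchored at position 0).
Note that a hand-written `random N` insertion draws content
independently per line, so a homozygous pair written by hand may differ
between haplotypes; the designer avoids this by materializing random
content into literals at design time.

The map is serialized as a versioned plain-text archive of integer
vectors (`-1` = deleted) rather than a language-specific binary, so it
round-trips and diffs cleanly.

## Presets: mining a mutation catalogue

A catalogue is a TSV of records `(sample_id, cancer_type, vtype, chrom,
pos, zygosity, hgvs)` in the style of a COSMIC or TCGA export. Event
lengths come from the HGVS string: an SNV is (1,1); `del`/`ins`/`dup`
spans follow interval arithmetic (a duplication's length is the
duplicated span); a delins contributes a deleted (`DELins`) and an
inserted (`delINS`) component. Unsupported HGVS forms are skipped and
counted.

Per cancer type the builder computes:

* variant-type and zygosity proportions, pooled over every record
  (*all-sample*) and per individual sample (*one-sample*); records with
  unknown zygosity are excluded from zygosity proportions only, and a
  catalogue with no zygosity at all (TCGA-like) yields a preset flagged
  `has_zygosity=False`;
* empirical distributions of the total number of variants per sample,
  lengths per type (INS, DEL, DUP, delINS, DELins; SNP length is the
  constant 0 and is never fitted), and inter-variant distances (per
  sample and chromosome, positions sorted, successive differences
  pooled across samples).

Each distribution is cleaned by a **single-pass 1 % filter**: values
with relative frequency strictly below 1 % of the pre-filter total are
dropped; survivors keep their counts and a value exactly at 1 %
survives. The filter is applied once, not iterated after
renormalization. If it would empty a distribution the unfiltered table
is kept and flagged.

The filtered table is then fitted by maximum likelihood to ten
families — Weibull, lognormal, normal, negative binomial, exponential,
logistic, Poisson, gamma, geometric, Cauchy. Positive continuous
families are fitted with the location pinned at zero; the discrete
MLEs are closed-form (Poisson mean, geometric reciprocal-mean) except
the negative binomial, which uses a 1-D profile likelihood in `log r`
with `p = r/(r+mean)`. A support violation (zeros under lognormal,
non-integers under Poisson, a constant sample under any
scale family) or a non-finite likelihood is recorded as `fit_ok=False`,
never raised. Discrete data under a continuous family is fitted on the
raw values and compared through the continuous CDF.

Six goodness-of-fit metrics score every successful fit: AIC
(`2k − 2lnL`), BIC (`k·ln n − 2lnL`), and the Kolmogorov–Smirnov,
Anderson–Darling and Cramér–von Mises statistics between the empirical
and fitted CDFs at the observed values. The chi-square statistic bins
discrete families on their observed support and continuous families
into equiprobable bins with expected count ≥ 5 (`m = clamp(n/5, 2, 30)`
bins, so tails are merged by construction). The best family is chosen
by **majority vote**: each metric votes for its minimizer; ties on vote
count break by lowest AIC. Asymptotic standard errors (inverse numeric
Hessian of the negative log-likelihood at the MLE) are available for
parameter-recovery checks.

Presets serialize to a versioned, human-readable JSON (value–count
tables, fit parameter blocks, metric tables, vote results) and
round-trip losslessly.

## Designing VAR files

The automatic design procedure draws the total variant count from the
empirical total distribution (or a user override), splits it over the
five types and two zygosities by **largest-remainder rounding** of the
preset proportions — so 100 variants at 50/10/20/10/10 % and 90/10 %
give exactly 50/10/20/10/10 and 90 het / 10 hom — samples per-type
lengths (a delins draws its two components independently), and places
variants by a distance-driven walk: a chromosome is chosen
proportionally to its length, the walk starts one sampled distance from
zero, advances by sampled inter-variant distances, and restarts on a
fresh chromosome when it runs off the end. By default type and zygosity
proportions come from one randomly selected sample (*one-sample*
perspective, the same sample for both); the pooled *all-sample*
perspective is selectable. A zygosity-free preset requires an explicit
heterozygous fraction — there is no silent default.

Encodings: SNP = 1-bp deletion + 1-bp literal insertion (the alt base
avoids the reference when the template sequence is available at design
time, else it is uniform over four and flagged downstream if it matches
the reference); DUP = self-extract insertion of the span at its own
position (a tandem duplication); DELINS = deletion + literal insertion.
Random content is materialized into literals so homozygous pairs match.
Footprints that would collide with an earlier variant or overrun the
chromosome are re-drawn up to 100 times, then error — the designer must
not emit scripts the editor is guaranteed to reject. The finished list
is shuffled at MID level with the config seed; a fixed seed gives a
byte-identical VAR file.

A clonal tree is a text file of `parent child distance` edges with
exactly one root; `distance` is the number of new variants a child
acquires. Expansion is breadth-first: each child's VAR list is its
parent's list verbatim plus `distance` new variants (MIDs prefixed with
the clone name), so variant sets are monotone along root-to-leaf paths.

## Read models

Three models are learned from aligned BAMs over BED regions of the
reference the reads were mapped to:

* **RDM** (read depth): per region, the total number of reads whose
  alignment starts inside it plus a per-position vector of start
  counts; the total always equals the vector sum.
* **QM** (qualities): per machine-cycle histograms of Phred scores
  (reverse-strand reads are flipped before counting).
* **PBEM** (position-based errors): per covered position, `(pos, depth,
  #A, #C, #G, #T)`; positions listed in a known-variants VCF are
  excluded by contig+position so real polymorphism is not learned as
  error.

Models are learned in template (`p`) coordinates. The **converter**
lifts them through a haplotype's position map into mutated-genome (`j`)
coordinates: counts are moved, never changed; entries at deleted
positions are dropped; positions created by insertions get zero counts;
region boundaries that map to deleted positions shrink inward to the
nearest survivor, and a fully deleted region is an error. Region totals
are recomputed as the sum of the converted vector.

Disabling the RDM replaces every region's weights with a flat profile
(region weight ∝ length, every position equal), so every position of
every region is equally likely to start a read. Disabling the PBEM
turns off error injection entirely: every generated read is an exact
substring of its source genome (or its reverse complement).

## Read generation and mixing

A coverage target `C` over a genome of interest of `G` bases (summed
BED lengths) at read length `L` requires `N = ceil(G·C/L)` reads,
counted in single reads; paired mode rounds up to an even count. Reads
start inside regions — region ∝ RDM total, position ∝ RDM vector — and
may run past the region end (clamped to the chromosome). Fragment
lengths are normal (default mean 300, sd 50) truncated below at `L`;
the forward/reverse role of the first mate is a fair coin. Qualities
are drawn per cycle from the QM (constant Q30 beyond the learned read
length); when the PBEM is enabled, each base covering a modelled
position is substituted with probability `nonref/depth`, the substitute
drawn proportionally to the stored non-reference counts, with its
quality drawn from the QM like any other base (errors and qualities are
sampled independently). Read names follow `{clone}|{hap}|{serial}/{mate}`
so every read traces to its origin.

Mixing realizes coverage, VAF and clonality jointly: reads per
(clone, haplotype) are `N × clone_prop × hap_prop`, largest-remainder
corrected so the grand total is exact, generated per combination with
seeds derived from the plan seed, merged, and shuffled with mate pairs
kept adjacent. A heterozygous variant private to a clone at proportion
`q` therefore surfaces at VAF `q × h0`; a homozygous one at `q`. The
haplotype proportions are exposed exactly as the strand-bias knob they
are documented to be, without reinterpretation.

## Synthetic fixtures and what the tests show

`somasim.fixtures` builds every test input programmatically: random
genomes (requested lengths, GC fraction, seed), genuinely aligned,
coordinate-sorted and indexed BAMs (all-match CIGARs, uniform or
spiked starts, i.i.d. substitution errors at a stated rate, per-cycle
quality means, optional planted alleles for VCF-exclusion tests), and
catalogues with known type/zygosity proportions, Poisson per-sample
totals and 1+Poisson event lengths. Every fixture is a pure function of
its arguments, seed included.

The test suite checks *parameter recovery* end to end: the preset
builder recovers catalogue proportions within multinomial 99 %
confidence intervals; each of the ten families refits 5,000 of its own
draws to within three asymptotic standard errors; the model learner
recovers the fixture BAM's coverage, error rate and quality means
within 10 %; and a mixed heterozygous variant at clone proportion 0.4
with h0 = 0.5 shows a pileup VAF within the binomial 99 % interval of
0.2 at 100×. The editing engine is validated against an independent
splice-replay oracle (a tagged token list spliced naively) over 1,000
random edit scripts, and RDM conservation is checked across 1,000
random maps. The targeted-sequencing scenario — eleven homozygous
variants, 400-bp regions (G = 4,400 bp), C = 100×, L = 100, both models
disabled — yields exactly 4,400 reads, all exact substrings, with
chi-square-flat start positions.

What the fixtures do **not** emulate: real human genome structure
(repeats, segmental duplications, centromeres), GC-dependent coverage
bias, indel sequencing errors, platform-specific quality binning, or
mapping ambiguity. Passing tests therefore demonstrate correctness of
the bookkeeping and the statistical machinery under clean conditions,
not calling performance on real tumors.

## Problem sizes and other fixed choices

Tests run on kilobase-scale chromosomes (250 bp – 60 kb), catalogues of
40–60 samples × ~80 variants, fixture BAMs at 30–60×, and
distribution fits at n ≤ 5,000 — sizes at which every estimator under
test has comfortable power while the whole suite stays fast. Genomes
are held in memory per chromosome as mutable byte arrays with
incremental splicing; maps are int64 vectors. Chromosome names are
matched exactly (no `chr` normalization) with near-miss suggestions in
the validator. Ploidy is fixed at 2; BAM output of simulated reads,
long-read error profiles and duplicate artifacts are out of scope.

## Known limitations

* The deletion rule counts `L_del` in *mutated* bases starting at
  `j[t]` while marking template positions `t..t+L_del-1`; if an earlier
  insertion landed strictly inside the deleted span, the marked
  template range and the physically removed bases can diverge. This is
  inherent to the two update rules; the editor and the oracle agree by
  construction, and such scripts are unusual in practice.
* Inversions and translocations have no dedicated VAR fields; they are
  expressed as documented DEL + self-extract-INS recipes
  (reverse-orientation extraction for inversions).
* The interactive (prompt-driven) design mode is a thin front end over
  the same operations and prints GOF tables rather than CDF plots.
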