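# Methods

## The trait model

Red leaf colour is modelled with four biallelic loci acting on one
integer latent anthocyanin score *s*:

* **RLL1** (bHLH activator, chromosome 5): the null allele *rll1* is
  epistatic over everything. `RLL1 dosage = 0` forces *s* = 0 (green).
* **RLL2** (MYB activator, chromosome 5): fully dominant; one functional
  copy adds 2.
* **RLL3** (R3-MYB repressor, chromosome 4) and **RLL4** (RUP-like WD40
  repressor, chromosome 9): dominant suppressors; only the homozygous
  null (`dosage = 0`) adds 1 each (recessive intensifiers).
* An optional stress bonus (+1, applied only when RLL1 is functional)
  models stress-induced reddening of wild material.

So `s = 0` if `d1 = 0`, else `s = 2·[d2 ≥ 1] + [d3 = 0] + [d4 = 0]
(+ stress)`. Thresholds (1, 2, 3) map *s* to the ordinal classes
green < light_red < red < dark_red. Dosages count *functional* alleles;
the activators' functional alleles come from the red parent and the
suppressors' from the green parent. The weights are a choice — the
field data are ordinal, not metric — fixed so that the observed family
contrasts fall in distinct classes. One consequence worth noting: a
family fixed for the red activators and segregating only RLL4 splits
into absolute classes red vs dark_red; the corresponding real family
was described as light red vs dark red, i.e. within-family colour labels
are relative. For the same reason the RLL4-segregating family background
must carry the *functional* RLL3 allele: with both suppressors lost, the
two segregating classes would collapse into dark_red and nothing would
visibly segregate.

`classify_colour` accepts a Gaussian noise term on the latent score
(default 0, i.e. fully penetrant classes). An unexplained green excess
in the original F2 (113/218 observed vs 0.355 expected) would require a
penetrance parameter the data cannot calibrate; it is exposed, not
fitted.

## The pedigree simulator

Genomes are phased 0/1 arrays (1 = red-parent allele) over a genome-wide
marker map: nine chromosomes sized on the scale of the reference
assembly (185–370 Mb), 0.6 cM/Mb, 200 evenly spaced markers per
chromosome by default, with the causal loci inserted as named markers.
Gametes follow a Markov walk along each chromosome with Haldane
recombination fractions `r = (1 − e^(−2d/100))/2` between adjacent
markers (Kosambi available); chromosome boundaries recombine at r = ½.
Note that because both qualitative loci sit on chromosome 5 (~106 cM
apart, r ≈ 0.44), F2 class frequencies deviate slightly from the
independence expectation — this linkage is real and is retained.

Pooled sequencing is emulated per SNP and pool: depth ~ negative
binomial with mean λ (Poisson when the dispersion is unset, the
default), alternate reads ~ Binomial(depth, p(1−ε) + (1−p)ε) around the
pool allele frequency p, with base error ε (default 0.001). Not
modelled: allele-specific expression (the real pools were RNA-seq, so
indices can be biased toward the expressed allele), unequal tissue
contributions per plant, mapping bias, and crossover interference
(Haldane implies none, which makes close double crossovers more common
than in real meiosis — see fine mapping below). Passing tests therefore
certify the statistics under idealized sampling, not those artefacts.

Pool construction supports three designs: `extreme_vs_random` (the F2
experiment: the 50 most intense red plants against 50 random greens),
`extreme_vs_extreme`, and `class_vs_class` (within-family scans: random
draws from the two segregating colour classes, which is how the family
pools were actually formed). Ranking the "most intense" plants uses the
latent score plus optional Gaussian ranking noise; the study scenario
sets this to 0.75 score units, reflecting that visual ranking of red
intensity across hundreds of plants cannot reliably separate plants one
score class apart. With noiseless ranking the red pool would be exactly
the score ≥ 3 class — maximally enriched for intensifier homozygotes —
and the epistatic masking of the intensifier loci would disappear from
the simulation entirely, contrary to the observed study outcome.

All randomness flows from one master seed; each pipeline stage draws
from a substream keyed by the CRC-32 of its stage name, so every run is
bit-reproducible.

## The delta-index scan

Per SNP and pool, the SNP-index is alt reads / depth (SNPs under
`min_depth` = 10 are dropped); the delta-index is signed, high (red)
pool minus low (green) pool, with the red-parent allele as ALT. Windows
average the per-SNP delta; the module defaults (2 Mb window, 500 kb
step, ≥ 5 SNPs) suit dense RNA-seq SNP catalogues, while the simulation
analyses use 10 Mb / 2.5 Mb / ≥ 3 SNPs to match the sparser simulated
grid (~1 marker per 1–2 Mb).

Null confidence bands follow the QTL-seq resampling construction: for
each replicate, each pooled individual's dosage at a locus with no
effect is drawn from the generation's Mendelian distribution (F2 1:2:1;
or an F2:3 family whose parent is drawn first, which roughly doubles the
band width), reads are drawn binomially at the scheduled depth, and the
bands are the empirical two-sided `level/2` quantiles per depth,
interpolated across a schedule spanning the Poisson depth spread (10,000
replicates by default). At depth → ∞ the 95 % half-width approaches
`1.96·sqrt(2/(8n))` ≈ 0.139 for n = 50/50 pools, which the tests verify.

Region calling takes maximal runs of ≥ `min_consecutive` (default 3)
consecutive windows outside the band, using |delta|. A `merge_gap`
option (default off) joins runs on the same chromosome separated by at
most that many sub-band windows: at a qualitative-locus contrast of 2/3
the expected windowed delta exceeds the 0.01 band for ~±38 cM (~63 Mb
here) around the locus, so band-crossing flicker along that shoulder
would otherwise fragment one locus into several reported regions. The
simulation analyses use merge_gap = 25 windows (62.5 Mb), sized to that
shoulder and safely below the 70-window separation of the two linked
qualitative loci.

### Detectability of the four loci under the study design

With 50/50 F2 pools at mean depth 50, the per-SNP null SD of the delta
is ≈ 0.12 (band 0.01 ≈ ±0.315). The attainable contrasts are: RLL1
≈ 0.47 (always detected); RLL2 at most 2/3 − 32/91 ≈ 0.315 under
independence — right at the band — lifted to ≈ 0.36 by its linkage to
RLL1, hence usually but not always detected; RLL3/RLL4 ≈ 0 under
class-random red pools but up to ≈ 0.27 when the red pool over-samples
score ≥ 3 plants. There is a structural trade-off: any red-pool
selection sharp enough to guarantee the RLL2 detection also enriches
intensifier homozygotes and un-masks RLL3/RLL4. Replayed end to end,
the individual study outcomes (qualitative loci detected, intensifiers
masked, every locus recovered by its fixed-background family round) each
reproduce in most replicates, but their conjunction holds in roughly a
quarter to a half of replicates rather than consistently — the single
observed trajectory of the study was, on this model, partly fortunate.
The acceptance suite measures and reports exactly this.

## Segregation statistics and fine mapping

Goodness of fit uses Pearson's chi-square against the hypothesized
ratio, df = classes − 1, no continuity correction by default (the
printed counts are large; a Yates flag exists). Association tests are
chi-square independence on the genotype × phenotype table. A family is
called segregating when ≥ 2 classes each have ≥ 3 plants and ≥ 5 % of
the family — thresholds chosen for robustness to single misphenotyped
plants, not taken from the study.

Recessive-class fine mapping counts, per ordered marker, the individuals
not homozygous for the donor (recessive-parent) allele; the interval is
the longest run of markers with ≤ `max_errors` recombinants (ties:
fewest recombinants, then leftmost), extended to the innermost flanking
markers that exceed the tolerance (the locus cannot lie beyond them when
phenotyping is error-free). `max_errors` defaults to 0; a tolerance
exists because late-onset light-red phenotypes carry classification
risk. Caveat: with no crossover interference and a sparse marker grid,
double crossovers can create disconnected zero-recombinant runs at small
sample sizes, making the longest-run choice ambiguous; with a dense grid
(the analyses use 2000 markers on the causal chromosome) the causal run
dominates and coverage is structurally guaranteed. Interval width falls
from ~3 Mb at 50 recessive individuals to ~0.4 Mb at 864, the scale of
the printed intervals.

## Variant annotation

Single-transcript gene models (exons + CDS on a reference sequence)
validate that the spliced CDS is whole-codon, ATG-initiated and
stop-terminated. Variants are VCF-style (1-based, anchored indels),
checked against the reference and left-aligned through repeats before
classification. CDS SNVs are translated (standard code, via Biopython)
and reported as residue-numbered substitutions or synonymous; CDS indels
classify by length mod 3 (frameshift vs in-frame) with a
`<refAA><pos>fs` descriptor; indels within 2 kb 5′ of the start codon
are promoter indels with the offset measured from the A of ATG (the base
immediately 5′ is −1 — the reference point for the printed −411 is
unstated, so this convention is documented rather than inferred);
variants within 2 bases of an exon boundary are splice-adjacent.
Haplotype grouping is exact-identity after uppercasing; any IUPAC
ambiguity code flags the genotype as carrying multiple homologs
(double peaks in directly sequenced PCR products). No alignment is
attempted, so only same-length comparable amplicons group meaningfully.

## Problem sizes in the shipped analyses

The analyses and acceptance checks run at the study's own scales (F2 of
218, pools of 50, depth 50, families of 600, 864 recessive individuals,
5,430-plant count reproduction) with 20–100 replicates where a rate is
estimated, and 10,000 replicates for null bands and calibration checks.
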