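# Methods

## Scope and data model

The package implements the computational core of a rapid trio-WES diagnostic
workflow for infantile cardiomyopathy: CNV detection from alignment fields,
a two-caller CNV consensus, sequential trio variant prioritization, and
cohort statistics. It consumes standard formats (SAM/BAM, VCF 4.x, BED, a
6-column PED) through pysam and exposes plain dataclasses. All coordinates
are 1-based inclusive internally; conversion to BED's 0-based half-open
convention happens only at the output boundary.

Alignment and variant calling themselves are out of scope — the pipeline
starts from aligned reads and an annotated trio VCF. Variant classification
(pathogenic / likely pathogenic / VUS) is consumed as an annotation
(ClinVar-style INFO key by default, configurable); the only
classification-adjacent logic implemented is the per-gene mechanism check.

## Discordant-pair CNV caller

A template spanning a copy-number breakpoint produces a read pair whose
observed template length (TLEN) or orientation is inconsistent with the
sequencing library. The caller:

1. **Filter.** Keep records with `MAPQ == mapq_required` (default 60 — the
   short-read aligners' unique-mapping cap, read as equality, not a lower
   bound; relaxable in config) and `tlen_min <= |TLEN| <= tlen_max`
   (defaults 2500 and 350 000, bounds inclusive; inclusivity only matters
   for spans exactly at the bounds). Records with `TLEN == 0` (unpaired or
   unmapped mate) are excluded and tallied. Exactly one record per template
   is kept — the leftmost mate when both pass — so support counts physical
   templates, not alignment lines; a lone rightmost mate is kept and its
   footprint estimated as `[POS + TLEN + 1, POS]`, an approximation off by
   at most one read length, inside the clustering tolerance for spans in
   the SV window.
2. **Implied footprint.** `[POS, POS + TLEN - 1]` for the canonical mate:
   the genomic interval the template spans.
3. **Cluster.** Single-linkage over footprints on the same chromosome. Two
   footprints link iff `|start1 - start2|` and `|end1 - end2|` are both
   ≤ `tolerance x mean(span1, span2)` (default tolerance 0.05). The ±5%
   band is applied endpoint-wise against the mean span of the two intervals
   being compared — the natural reading when neither interval is privileged;
   an exhaustive transitive-closure oracle pins this choice in the tests.
   The representative interval takes the low median of member starts and
   the high median of member ends (integer medians; clamped so end ≥ start).
4. **Prioritize.** Clusters with support ≥ `min_support` (default 3; the
   threshold is a package choice exposed in config) become calls, ranked by
   support descending, ties by span descending then coordinate. Orientation
   types the call: everted (RF) majority → duplication, FR majority →
   deletion, tie → unknown. Typing by orientation is an extension beyond
   the MAPQ/TLEN rules; `unknown` is legal output.

Properties verified in tests: the filter is a pure, idempotent,
order-insensitive predicate; cluster supports sum to the retained-template
count; clustering equals the brute-force transitive closure on instances up
to 200 pairs; widening the TLEN window never drops retained pairs and
raising `min_support` never adds calls.

## Depth-ratio stand-in and consensus

The second CNV pipeline is deliberately a simple stand-in for a full
statistical exome-depth model: per target, case and reference counts are
normalized by their library totals over the targets; the depth ratio is the
normalized case count over the mean normalized reference; runs of
≥ `min_consecutive_targets` (default 2) consecutive targets with ratio
≥ 1.3 (duplication) or ≤ 0.7 (deletion) and |z| ≥ 3 merge into one call.

The z-score is robust by construction: with a handful of reference samples
a per-target standard deviation is hopeless, so leave-one-out reference
residuals are pooled across all targets under a variance-proportional-
to-mean model and a single MAD-based scale `sigma0` is taken;
`sd(target) = sigma0 * sqrt(reference mean)`.

These fixed ratio gates presume a well-matched reference batch: the
count generator's defaults (mean depth 500x, negative-binomial dispersion
2500, i.e. a ~2% technical CV floor and ~4.5% total per-target CV) emulate
that regime. With poorly matched references (per-target CV ≳ 8%) a plain
per-target ratio gate at 1.3/0.7 drops individual targets too often, which
is precisely why production tools use likelihood models over target runs —
a fidelity this stand-in does not attempt.

**Consensus.** A call survives iff a discordant-pair call and a depth call
on the same chromosome share ≥ `reciprocal_overlap` (default 0.5) of each
interval's own span. The consensus interval is the intersection; the
sv-type is kept when the parents agree, `unknown` otherwise; support is the
smaller parent support. The overlap rule and threshold are package choices
made explicit in config — the upstream workflow states only that calls must
be detected by both pipelines. Gene annotation attaches every gene interval
overlapping a call by ≥ 1 base, in genomic order (interval tree).

## Trio prioritization cascade

**Inheritance resolution** per variant, with sites missing any genotype
unresolved:

- autosomes, PAR, and chrX in a female proband: proband het with hom-ref
  parents → de novo; het with exactly one carrier parent → inherited
  (maternal/paternal); hom-alt with two het parents → autosomal-recessive
  homozygous; hom-alt with a hom-ref parent → unresolved with a
  Mendelian-error flag (flagged, never an exception);
- non-PAR chrX in a male proband: haploid alt with carrier mother and
  hemizygous-reference father → X-linked hemizygous; a diploid het call
  there is kept as het but flagged `male_x_het`, never silently converted;
- per gene, one maternally and one paternally inherited het combine into a
  single compound-het call replacing the two singletons (first of each in
  position order when several exist). Two heterozygous variants in two
  *different* genes, one per parent, remain two independent dominant calls
  — the double-heterozygote configuration is not a compound heterozygote.

PAR boundaries default to the GRCh37 convention (chrX 60 001–2 699 520 and
154 931 044–155 260 560), matching the hg19 coordinates of the packaged
cohort.

**Frequency gate.** Dominant-acting models (de novo, inherited dominant,
X-linked) require every allele's population frequency ≤ 1e-4; recessive
models (homozygous, compound het) allow carrier-level alleles ≤ 5e-3.
An absent frequency is treated as novel (0). The thresholds are package
defaults exposed in config — chosen to be consistent with the prevalence of
severe infantile cardiomyopathy (dominant causal alleles effectively absent
from population databases; recessive carrier alleles can segregate at low
frequency) — not inferences of any laboratory's internal values.

**Panel / mechanism gate.** The gene must be on the cardiomyopathy panel
(waivable), the resolved model must match a panel inheritance mode (de
novo/inherited → AD, homozygous/compound het → AR, hemizygous → XL), and
each variant's consequence must fit the gene's expected pathogenic
mechanism: `lof` genes demand loss-of-function consequences, `non_lof`
genes (e.g. activating RASopathy missense) reject them, `either` accepts
both.

**Reporting gate.** Only pathogenic and likely-pathogenic variants are
reportable; VUS and below are suppressed. Survivors are scored —
clinical-class weight first, then model specificity (de novo and recessive
over inherited dominant), then rarity (−log10 of frequency, capped) — and
returned ranked with the ordered list of passed filters for audit. The
filters are conjunctive, so the survivor set is order-independent; tests
assert this directly.

## Synthetic data generators

All generators are deterministic (same seed and parameters → byte-identical
output) and emit a machine-readable truth manifest.

**Read pairs.** One toy chromosome (`chrS`, 2 Mb default) keeps every
experiment at sub-second scale. Background pairs are proper FR pairs with
template length ~ Normal(350, 50) truncated positive, MAPQ 60, 150 bp
reads — a standard short-insert exome library. Each planted event emits its
supporting pairs anchored in the immediate flanks, so the implied footprint
matches the truth interval within one read length; deletions produce FR
pairs with `|TLEN| = span + flanking gap`, tandem duplications everted RF
pairs with `|TLEN| ~ span`. The orientation convention is recorded in the
manifest so sv-typing is testable against it. A configurable fraction of
low-MAPQ decoy pairs with CNV-scale TLEN (1% of background by default)
exercises the MAPQ filter. Reads are emitted as already-aligned SAM with
placeholder SEQ/QUAL, because the caller consumes MAPQ, TLEN, position and
orientation only.

**Trio VCFs.** Each panel gene gets a deterministic toy locus (X-linked
genes on non-PAR chrX, others round-robin over five autosomes). Causal
configurations follow the declared model exactly; causal alleles are novel
with probability 0.5, otherwise log-uniform below 1e-5, and labelled
pathogenic or likely pathogenic. Noise variants (default 200 per trio) are
autosomal Mendelian-consistent transmissions drawn from Hardy–Weinberg
genotypes with a gnomAD-like spectrum — 60% common (uniform 0.01–0.5), 40%
rare (log-uniform 1e-6–1e-2) — and are never labelled pathogenic:
population-scale noise does not carry curated pathogenic assertions, so
recovery experiments measure the cascade's inheritance/frequency/panel
logic together with the reporting policy, not classification itself.

**Depth counts.** Negative-binomial counts per target (variance
mu + mu²/dispersion) with case expectations scaled x1.5 on duplicated and
x0.5 on deleted targets; reference samples carry no events.

What the generators do **not** emulate: base-level errors, GC bias,
mappability structure, segmental duplications, real exome target geometry,
population linkage, or annotation noise (mislabelled classifications,
wrong gene assignments). Passing recovery tests therefore shows the logic
is implemented correctly under clean Mendelian signals, not that real-data
sensitivity or specificity would match.

## Packaged cohort fixture

The 42-case table transcribes a published infantile-cardiomyopathy trio-WES
cohort: 29 diagnosed cases with their per-allele variant table (gene, hg19
position, consequence class, zygosity, parental origin, classification) and
13 undiagnosed cases carrying the patient IDs absent from the published
per-patient table. Undiagnosed cases' sex/age/type/class cells are a
synthetic assignment — the stratum totals they must jointly satisfy (by
setting: sex, HCM/DCM, isolated/syndromic/metabolic) are published, the
individual rows are not; the same holds for the family-history and
prenatal-detection booleans. Ages were chosen so cohort mean/median ages
round to the published summaries. The loader verifies every published
margin at load time and fails loudly rather than repairing. Per-patient
turnaround times are not published, so `t1_days`/`t2_days` stay absent and
turnaround statistics are validated on synthetic cases only.

The transmission-mode breakdown is computed two independent ways — mapping
the table's zygosity/origin columns directly, and reconstructing each
diagnosed case's trio genotypes from its printed zygosity/origin and
replaying them through the inheritance resolver — and both must agree:
13 de novo, 10 autosomal recessive (7 homozygous + 3 compound het),
2 X-linked, 4 inherited dominant, over 29 diagnosed.

## Numerical and policy choices

- Fractions in cohort reports are exact `Fraction`s; percentages round to
  one decimal only at rendering.
- Cluster-representative intervals use integer medians (low for starts,
  high for ends) to avoid fractional coordinates.
- Ties in CNV ranking break by span (larger first), then coordinate; ties
  in candidate ranking break by gene symbol, then variant key.
- The depth caller floors the pooled MAD scale at 1e-12 and skips
  zero-coverage targets.
- A region query on a chromosome absent from a SAM header yields an empty
  stream rather than an error — the streaming-friendly behaviour.
- Problem sizes in the acceptance script (200 CNV replicates of 800
  background pairs; 500 trios of 150 noise variants) are the package's
  standing experiment sizes; they complete in seconds while giving
  percent-level resolution on the recovery rates.

## Known limitations

- The discordant caller does not refine breakpoints (no split reads), does
  not genotype events, and ignores inter-chromosomal signals.
- The depth stand-in is not a reimplementation of any published
  likelihood-based exome-depth model and should not be benchmarked as one.
- Compound-het pairing is greedy (first maternal with first paternal per
  gene); with more than two candidate hets per gene the pairing is a
  convention, not an inference.
- The mechanism check is binary per gene; real curation weighs mechanism
  per variant class and disease.
- Multi-allelic records are split per ALT but not left-normalized.
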