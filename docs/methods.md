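# Methods

`xenovar` implements the genomic analysis of matched primary-tumor /
patient-derived-xenograft (PDX) pairs sequenced on a targeted cancer panel,
together with a synthetic cohort generator that supplies exact ground truth
for every stage. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic results do and do not show.

## The analysis problem

A xenograft sample contains human tumor DNA mixed with mouse stromal DNA.
When its reads are aligned to the human reference, mouse reads from regions
conserved between the genomes align convincingly and their residual
human/mouse differences masquerade as recurrent somatic variants. The
pipeline handles this with a dual-alignment strategy followed by a hard
filter cascade and two cohort-level exclusions.

### Read partitioning

Every read is aligned (here: simulated) against both genomes. Two datasets
are built per sample:

* **relaxed** — human MAPQ >= 30, regardless of mouse mapping;
* **strict** — relaxed reads that do not also map to mouse with MAPQ >= 17
  (absence from the mouse alignments counts as not mapping).

Strict ⊆ relaxed always. The strict set is mouse-depleted but blind in
conserved regions; the relaxed set keeps those regions at the cost of host
contamination. Both are carried through calling and filtering and merged at
the end (union per sample; the strict record's metrics win on overlap).
Only the primary alignment record per read and genome is used.

### Candidate calling

A transparent pileup caller replaces the vendor (flow-space) caller. Per
target base it tabulates allele counts by strand plus per-allele mean MAPQ,
mean read length, and mean mismatch-quality sum (MMQS: the sum of base
qualities at a read's mismatches, attributed to every allele the read
supports). Any non-reference allele with >= 3 supporting reads becomes a
candidate. Indels are registered at their left-anchored VCF position.
Because no flow-space signal exists outside the vendor stack, the
flow-corrected depth and alternate counts (FDP, FAO) are equated with plain
depth and alternate observations; the downstream thresholds keep their
meaning under this equivalence.

Two derived qualities use a binomial error model with fixed per-base error
rate `e` (default 0.01, matching the simulated error rate and base quality
20 = −10·log10(0.01)):

* `QUAL` — Phred-scaled likelihood ratio of "alt present at its observed
  fraction" vs "all alternate reads are errors at rate e";
* `GQ` — Phred gap between the best and second-best of the hom-ref
  (f = e), het (f = 0.5), hom-alt (f = 1 − e) binomial likelihoods.

`STB` is the majority-strand share of alternate reads, in [0.5, 1].
`HRUN` is the reference homopolymer-run length at the variant context: the
run containing a SNP's base; for indels the longest run containing or
immediately abutting the inserted/deleted bases (ties resolve to the longer
adjacent run). Long reference runs drive indel errors on semiconductor
sequencers, which is what the indel HRUN filter polices.

### Filter cascade

Applied per call, evaluated in full so the filter trail names every rule:

1. `DP >= 20`, `QUAL >= 20`, `GQ > 5` for all variants; `FDP > 6`,
   `FAO > 2`, `STB < 0.9` for SNPs; `FDP > 10`, `HRUN < 6`, `FAO > 4` for
   indels. Inequality strictness is exactly as written.
2. fpfilter-style comparisons: minority-strand share >= 0.05; |ΔMAPQ| <= 10
   and |Δread length| <= 10 between reference and alternate reads;
   MMQS(alt) − MMQS(ref) <= 50 (one-sided: a cleaner alternate allele is
   never penalized). With zero reference reads the comparisons are vacuous
   and pass — a fail-closed reading would delete exactly the homozygous /
   100%-AF calls that real xenografts produce; fail-closed is reserved for
   calls whose metric fields are absent. Only these four printed rules are
   implemented; unprinted tool defaults are not replicated.
3. Support: >= 5 alternate reads on each strand and alternate fraction
   >= 10%.

Cohort exclusions, computed independently on the pre-exclusion data (they
commute) and applied together, cohort-wide:

* **Xenograft enrichment** — a key whose relaxed-dataset alternate fraction
  is higher in the xenograft than in its matched source sample in more than
  3 pairs is removed. The comparison uses candidate-level alternate
  fractions (absence = 0) with an evidence floor of 0.05: fractions at the
  sequencing-error scale (~0.01) are treated as absence, because otherwise
  error fluctuations in unrelated xenografts count as "enrichment" and the
  rule removes genuine case-private truncal variants. The floor is half the
  10% support threshold and five times the base-error rate. Using
  candidate-level rather than post-filter fractions makes the rule
  deterministic for its actual target: conserved-region mouse alleles whose
  AF hovers at the 10% support boundary.
* **Prevalence** — a key detected (post per-call filters) in more than 25%
  of samples in the relaxed or the strict dataset is removed. Denominators
  are all samples present in the given dataset, cell lines included. This
  rule presumes a cohort of unrelated cases; in cohorts of fewer than ~5
  cases a genuine private variant already exceeds 25% prevalence, so the
  simulator's study conditions use 10 pairs.

Finally the datasets are merged and keys with population allele frequency
above 0.1% in a user-supplied table are dropped as presumed germline; keys
absent from the table are retained. Variant keys are normalized
(suffix/prefix trim, left-alignment through repeated context) before any
cohort operation.

### Cohort statistics

Deterministic arithmetic over final calls: per-pair shared/private
partitions with retention = 100·|shared|/|union| (rounded to the nearest
integer); allele-fraction deltas of shared variants with the fraction
elevated and the count reaching 100%; mutations per megabase against the
assayed panel length (one decimal); variants per gene per sample =
total / (panel gene count × sample count) (two decimals — the panel gene
count, not the smaller number of variant-bearing genes, is the denominator
convention, and both counts are available to report); the waterfall matrix
restricted to genes mutated in strictly more than 10% of samples, ordered
by descending frequency with ties broken by name; the pathway × sample
matrix of maximal zygosity; and subtype match rates over externally
supplied labels. Zygosity calls a variant homozygous at alternate fraction
>= 0.8 (configurable) — heterozygous calls below that may reflect cell
mixtures, so the cutoff is a reporting convention, not a genotype claim.

## The simulator

### What it emulates

* **References.** A coordinate-aligned toy genome pair: the mouse-like
  sequence differs from the human-like one by independent substitutions at
  rate 0.10, except in two 600 bp conserved windows at rate 0.0035 whose
  few residual differences become the planted mouse-homology artifact
  alleles. Homopolymer runs (4–8 bp) are planted at ~1/kb to give indel
  context. Because coordinates align, every artifact is exactly traceable.
* **Panel.** 24 genes × 500 bp (12 kb assayed) on a 12.8 kb genome; the
  first 8 genes are designated drivers and mapped to five named signaling
  pathways (Wnt, MAPK, PI3K-Akt, VEGF, TGF-beta).
* **Clonal architecture.** Three clones per case — truncal (all clones)
  plus two subclones — with primary fractions (0.5, 0.3, 0.2). Per case:
  6 truncal SNVs (2 forced into driver genes), 1 truncal 1 bp deletion at a
  short homopolymer run (run length 3–4, so HRUN <= 5 and the variant is
  recoverable), 3 private SNVs per subclone, and 3 heterozygous germline
  SNVs listed at 5% population AF. All variants are heterozygous diploid
  (AF factor 0.5) unless configured homozygous; positions are unique across
  the cohort, mirroring the overwhelmingly private mutations of real
  cohorts.
* **Passage.** Engraftment and each passage draw 1e5 cells multinomially
  with probabilities ∝ fraction × selection weight; weights are log-normal
  (σ = 0.5) at engraftment and neutral afterwards, through stages
  P0 → P1 → P2.
* **Composition.** Primary: 60% tumor reads, 40% human stroma, no mouse.
  Xenograft stages: 90% tumor, 10% mouse stroma, no human stroma (the
  engrafted tumor replaces human stroma with host stroma). These fractions
  are configurable; the purity contrast (0.6 vs 0.9) is the
  default study condition.
* **Sequencing.** Single-end 100 bp reads at mean depth 500×, uniform
  substitution errors at 1% with constant base quality 20.
* **Alignment model.** Alignment is simulated, not performed. Own-genome
  MAPQ is 60 minus small noise. Cross-genome MAPQ is
  `round(60·max(0, 1 − k·d_local))` with k = 10 and `d_local` the
  human/mouse divergence within the read footprint; a zero score is
  reported unmapped. At divergence 0.10 mouse reads are invisible to the
  human reference except in conserved windows, where they enter the relaxed
  dataset with MAPQ ≈ 54 — exactly the artifact mechanism the MAPQ
  thresholds police.

### The two study conditions

* **Purity contrast (default).** Primary purity 0.6 vs xenograft 0.9 with
  selection at engraftment. Expected truncal AF rises from 0.30 to 0.45;
  because mouse reads contribute no human-reference depth outside conserved
  windows, the observed xenograft AF is ≈ 0.50, so the median truncal shift
  is ≈ +0.20 and essentially all shared variants are elevated in the
  xenograft.
* **Neutral control.** Selection off and equal purity of the *human* DNA
  compartment (primary 100% tumor; xenograft 90% tumor + 10% mouse). The
  mouse compartment is kept so host-contamination machinery stays
  exercised. Median truncal AF shift is ≈ 0. Equalizing raw tumor fractions
  instead would build a spurious +0.05 shift into the control, for the
  depth-dropout reason above.

### What the simulator does not model

No real aligner (mapping ambiguity beyond the divergence-decay model), no
flow-space signal or homopolymer-length miscalls (indel errors enter only
through planted indels and uniform substitution errors), no structural or
copy-number variation, no read-length variation or quality decay along the
read, no phase linkage between nearby heterozygous variants, and no shared
mutation hotspots between cases. Passing the synthetic suite therefore
shows the pipeline's rules behave as specified under controlled
contamination and clonal dynamics; it does not certify performance on real
semiconductor-sequencer error profiles.

## Numerical and design choices

* Problem sizes (12 kb genome, 10 pairs, depth 500) were chosen so a full
  cohort simulates and analyzes in seconds while every rule still has
  non-trivial work to do; all sizes are configuration, not constants.
* All randomness flows from explicit seeds (one generator per operation;
  per-sample seeds derived from the cohort seed), and reruns are
  byte-identical at the file level.
* The minimum alternate-observation count for candidate emission is 3; all
  hard filtering is deferred to the cascade so each rule's effect is
  attributable in the filter trail.
* Reads unmapped against the human frame contribute no pileup. Reference
  means over zero reads are reported as equal to the alternate means
  (vacuous comparisons, see above).
* Degenerate inputs fail loudly: divergence outside [0, 0.5], fractions not
  summing to one, variants outside the reference or targets, conflicting
  duplicate read records, conflicting reference alleles at one site after
  normalization, empty cohorts in prevalence computations.
* The per-gene rate and prevalence denominators, the union-based retention
  denominator, and integer/one-decimal/two-decimal rounding follow the
  conventions of targeted-panel cohort reports.

## Known limitations

* The enrichment-rule evidence floor (0.05) is a pragmatic noise gate; a
  likelihood-based test of AF difference would be principled but is beyond
  the printed rule being reproduced.
* With fewer than ~5 cases the prevalence exclusion removes genuine private
  variants (see above); the pipeline does not warn about small cohorts
  beyond documentation.
* Subtype labels are inputs; no expression-based classification is
  performed or validated here.
* The caller reports the best description of each non-reference allele
  independently; it does not genotype multi-allelic sites jointly.
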