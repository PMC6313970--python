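"""The hard-filter cascade and cohort-level artifact exclusions.

Per-call stages (pure predicates, evaluated in full so the filter trail
records every rule):

1. primary filters — DP >= 20, QUAL >= 20 and GQ > 5 for all variants;
   FDP > 6, FAO > 2 and STB < 0.9 for SNPs; FDP > 10, HRUN < 6 and FAO > 4
   for indels. Inequality strictness follows these statements exactly.
2. false-positive filters — minority-strand share of alternate reads
   >= 0.05; |mean MAPQ(ref) - mean MAPQ(alt)| <= 10; |mean read length
   difference| <= 10; MMQS(alt) - MMQS(ref) <= 50. When a site has zero
   reference reads the ref-vs-alt comparisons are vacuous and pass; a call
   whose metric fields are absent fails closed with reason
   ``metric_missing``.
3. support filters — at least five alternate reads from each strand and an
   alternate-read fraction of at least 10%.

Cohort-level exclusions (computed independently, then applied together):

* PDX-enrichment — a variant whose relaxed-dataset alternate fraction is
  higher in the xenograft than in its matched source sample (absence
  counting as zero) in more than ``pdx_enrichment_pair_count`` pairs is
  removed cohort-wide; this targets artifacts from homologous mapping of
  mouse DNA to the human reference, which recur across xenografts.
* prevalence — a variant detected in more than 25% of samples in the
  relaxed or the strict dataset is removed (panel-wide recurrent artifacts).

Finally the strict and relaxed call sets are merged per sample (union;
where both carry a call the strict record's metrics win) and variants with
population allele frequency above 0.1% are dropped as presumed germline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

from .pileup import CandidateVariant

DATASET_STRICT = "strict"
DATASET_RELAXED = "relaxed"


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults per the published values)."""

    dp_min: int = 20
    qual_min: float = 20.0
    gq_min_exclusive: float = 5.0
    snp_fdp_min_exclusive: int = 6
    snp_fao_min_exclusive: int = 2
    snp_stb_max_exclusive: float = 0.9
    indel_fdp_min_exclusive: int = 10
    indel_hrun_max_exclusive: int = 6
    indel_fao_min_exclusive: int = 4
    min_strandedness: float = 0.05
    max_mapqual_diff: float = 10.0
    max_readlen_diff: float = 10.0
    max_mm_qualsum_diff: float = 50.0
    min_alt_per_strand: int = 5
    min_alt_fraction: float = 0.10
    pdx_enrichment_pair_count: int = 3
    pdx_enrichment_min_af: float = 0.05
    prevalence_max: float = 0.25
    population_af_max: float = 0.001

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
        for name in ("min_strandedness", "min_alt_fraction", "prevalence_max", "population_af_max"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


Trail = list[tuple[str, bool]]


def apply_primary_filters(call: CandidateVariant, cfg: FilterConfig | None = None) -> tuple[bool, Trail]:
    """Depth/quality rules plus the SNP- or indel-specific rules."""
    cfg = cfg or FilterConfig()
    trail: Trail = [
        ("DP", call.DP >= cfg.dp_min),
        ("QUAL", call.QUAL >= cfg.qual_min),
        ("GQ", call.GQ > cfg.gq_min_exclusive),
    ]
    if call.vtype == "SNP":
        trail += [
            ("FDP", call.FDP > cfg.snp_fdp_min_exclusive),
            ("FAO", call.FAO > cfg.snp_fao_min_exclusive),
            ("STB", call.STB < cfg.snp_stb_max_exclusive),
        ]
    elif call.vtype == "indel":
        trail += [
            ("FDP", call.FDP > cfg.indel_fdp_min_exclusive),
            ("HRUN", call.HRUN < cfg.indel_hrun_max_exclusive),
            ("FAO", call.FAO > cfg.indel_fao_min_exclusive),
        ]
    else:
        raise ValueError(f"unknown variant type {call.vtype!r}")
    return all(ok for _, ok in trail), trail


def apply_fpfilter(call: CandidateVariant, cfg: FilterConfig | None = None) -> tuple[bool, Trail]:
    """Strandedness and ref-vs-alt profile comparisons (fpfilter-style)."""
    cfg = cfg or FilterConfig()
    trail: Trail = []
    if call.FAO > 0:
        minority = min(call.alt_fwd, call.alt_rev) / call.FAO
        trail.append(("strandedness", minority >= cfg.min_strandedness))
    else:
        trail.append(("strandedness", False))

    comparisons = (
        ("mapqual_diff", call.mapq_ref_mean, call.mapq_alt_mean, cfg.max_mapqual_diff, True),
        ("readlen_diff", call.readlen_ref_mean, call.readlen_alt_mean, cfg.max_readlen_diff, True),
        ("mm_qualsum_diff", call.mmqs_ref_mean, call.mmqs_alt_mean, cfg.max_mm_qualsum_diff, False),
    )
    for rule, ref_val, alt_val, limit, absolute in comparisons:
        if ref_val is None or alt_val is None:
            trail.append((f"{rule}:metric_missing", False))
            continue
        if call.RO == 0:
            trail.append((rule, True))  # no reference reads: comparison vacuous
            continue
        diff = abs(ref_val - alt_val) if absolute else (alt_val - ref_val)
        trail.append((rule, diff <= limit))
    return all(ok for _, ok in trail), trail


def apply_support_filters(call: CandidateVariant, cfg: FilterConfig | None = None) -> tuple[bool, Trail]:
    """Per-strand alternate support and minimum alternate fraction."""
    cfg = cfg or FilterConfig()
    trail: Trail = [
        ("alt_per_strand", call.alt_fwd >= cfg.min_alt_per_strand and call.alt_rev >= cfg.min_alt_per_strand),
        ("alt_fraction", call.alt_fraction >= cfg.min_alt_fraction),
    ]
    return all(ok for _, ok in trail), trail


@dataclass
class VariantCall:
    """A candidate bound to a sample and dataset, with its filter trail."""

    candidate: CandidateVariant
    sample_id: str
    dataset: str  # "strict" | "relaxed"
    filter_trail: Trail = field(default_factory=list)
    provenance: str = ""
    gene: str | None = None
    genes: tuple[str, ...] = ()
    is_driver: bool = False
    pathways: tuple[str, ...] = ()

    @property
    def key(self):
        return self.candidate.key

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.filter_trail)

    @property
    def failed_rules(self) -> list[str]:
        return [rule for rule, ok in self.filter_trail if not ok]

    @property
    def af(self) -> float:
        return self.candidate.alt_fraction

    @property
    def zygosity_hom(self) -> bool:
        return self.candidate.alt_fraction >= 0.8


def run_call_filters(
    candidate: CandidateVariant,
    sample_id: str,
    dataset: str,
    cfg: FilterConfig | None = None,
) -> VariantCall:
    """Evaluate the three per-call stages; every rule lands in the trail."""
    cfg = cfg or FilterConfig()
    _, t1 = apply_primary_filters(candidate, cfg)
    _, t2 = apply_fpfilter(candidate, cfg)
    _, t3 = apply_support_filters(candidate, cfg)
    return VariantCall(candidate, sample_id, dataset, filter_trail=t1 + t2 + t3)


# --------------------------------------------------------------- cohort rules


def exclude_pdx_enriched_artifacts(
    relaxed_af_by_sample: dict[str, dict],
    pairing: list[tuple[str, str]],
    cfg: FilterConfig | None = None,
) -> dict[tuple, int]:
    """Variant keys enriched in the xenograft in more than N pairs.

    ``relaxed_af_by_sample`` maps sample id to {variant key: alt fraction}
    in the relaxed dataset; a key absent from a sample has fraction zero,
    and fractions below ``cfg.pdx_enrichment_min_af`` are treated as
    absence — alternate fractions at the sequencing-error scale carry no
    evidence of mouse-homology enrichment and would otherwise let noise
    inflate the pair count. Returns {key: enriched pairs} for removed keys.
    """
    cfg = cfg or FilterConfig()
    for source_id, xeno_id in pairing:
        if source_id not in relaxed_af_by_sample or xeno_id not in relaxed_af_by_sample:
            raise ValueError(f"pairing references missing sample(s): {source_id}, {xeno_id}")
    floor = cfg.pdx_enrichment_min_af

    def _af(sample_id, key):
        af = relaxed_af_by_sample[sample_id].get(key, 0.0)
        return af if af >= floor else 0.0

    keys: set = set()
    for afs in relaxed_af_by_sample.values():
        keys.update(afs)
    removed: dict[tuple, int] = {}
    for key in keys:
        n_enriched = sum(
            1 for source_id, xeno_id in pairing if _af(xeno_id, key) > _af(source_id, key)
        )
        if n_enriched > cfg.pdx_enrichment_pair_count:
            removed[key] = n_enriched
    return removed


def exclude_high_prevalence(
    keys_by_sample_by_dataset: dict[str, dict[str, set]],
    cfg: FilterConfig | None = None,
) -> dict[tuple, float]:
    """Variant keys present in more than 25% of samples in either dataset.

    ``keys_by_sample_by_dataset[dataset][sample_id]`` is the set of variant
    keys detected in that sample/dataset. The denominator is all samples
    present in the given dataset. Returns {key: worst prevalence} removed.
    """
    cfg = cfg or FilterConfig()
    removed: dict[tuple, float] = {}
    for dataset, by_sample in keys_by_sample_by_dataset.items():
        n_samples = len(by_sample)
        if n_samples == 0:
            raise ValueError(f"empty cohort for dataset {dataset!r}")
        tally: dict[tuple, int] = {}
        for sample_keys in by_sample.values():
            for key in sample_keys:
                tally[key] = tally.get(key, 0) + 1
        for key, n in tally.items():
            prevalence = n / n_samples
            if prevalence > cfg.prevalence_max:
                removed[key] = max(prevalence, removed.get(key, 0.0))
    return removed


def merge_datasets(
    strict_calls: list[VariantCall],
    relaxed_calls: list[VariantCall],
) -> list[VariantCall]:
    """Union of strict and relaxed calls per (variant key, sample).

    Where both datasets carry the call, the strict record's metrics are kept
    and provenance is ``"both"``. Conflicting reference alleles at one site
    indicate a normalization bug and raise.
    """
    merged: dict[tuple, VariantCall] = {}
    for call in strict_calls:
        call.provenance = DATASET_STRICT
        merged[(call.sample_id, call.key)] = call
    for call in relaxed_calls:
        k = (call.sample_id, call.key)
        site = (call.sample_id, call.candidate.contig, call.candidate.pos)
        if k in merged:
            merged[k].provenance = "both"
        else:
            for (s_id, other_key), other in merged.items():
                if (s_id, other.candidate.contig, other.candidate.pos) == site and other_key[2] != call.key[2]:
                    raise ValueError(
                        f"conflicting reference alleles at {site}: {other_key[2]!r} vs {call.key[2]!r}"
                    )
            call.provenance = DATASET_RELAXED
            merged[k] = call
    return sorted(merged.values(), key=lambda c: (c.sample_id, c.key))


def filter_population(
    calls: list[VariantCall],
    af_table: dict,
    cfg: FilterConfig | None = None,
) -> list[VariantCall]:
    """Drop presumed-germline keys with population AF above the cutoff.

    ``af_table`` maps variant key -> maximum population allele frequency;
    keys absent from the table are retained as somatic candidates.
    """
    cfg = cfg or FilterConfig()
    kept = []
    for call in calls:
        af = af_table.get(call.key)
        if af is not None:
            af = float(af)
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"malformed population AF {af!r} for {call.key}")
            if af > cfg.population_af_max:
                continue
        kept.append(call)
    return kept


def normalize_variant(reference: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and trim a variant to its canonical VCF representation.

    ``pos`` is 1-based. Keeps indel identities consistent across samples so
    cohort operations compare like with like.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-shift pure indels through repeated context: while both alleles end
    # with the same base, trim it and prepend the preceding reference base
    while len(ref) != len(alt) and ref[-1] == alt[-1] and pos > 1:
        prev = reference[pos - 2]
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return pos, ref, alt
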