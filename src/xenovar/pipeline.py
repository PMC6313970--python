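"""End-to-end pipeline: reads -> partition -> pileup -> cascade -> statistics.

`run_pipeline` drives a simulated cohort through the exact analysis applied
to real dual-aligned data: per sample, reads are split into relaxed and
strict datasets by MAPQ, each dataset is piled up and candidate variants are
emitted, the per-call hard filters run, the two cohort exclusions
(xenograft-enrichment and prevalence) are computed and applied cohort-wide,
the datasets are merged per sample, population-frequent variants are
dropped, and the survivors are annotated with genes, driver flags and
pathways. `TruthEvaluation` then scores the outcome against the simulator's
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import annotate_genes
from .cohort import Cohort, CohortConfig, simulate_cohort
from .filters import (
    DATASET_RELAXED,
    DATASET_STRICT,
    FilterConfig,
    VariantCall,
    exclude_high_prevalence,
    exclude_pdx_enriched_artifacts,
    filter_population,
    merge_datasets,
    run_call_filters,
)
from .partition import partition_readset
from .pileup import Pileup, call_candidates
from .stats import PairConcordance, af_shift, cohort_concordance, pair_concordance


@dataclass
class SampleCallData:
    """Per-sample intermediate products the cohort stages need."""

    sample_id: str
    partition_counts: dict[str, int]
    relaxed_af: dict  # candidate-level {variant key: alt fraction}, relaxed
    survivors: dict[str, list[VariantCall]]  # dataset -> filtered calls
    n_candidates: dict[str, int]
    fail_tally: dict[str, int]


@dataclass
class PipelineResult:
    cohort: Cohort
    filter_cfg: FilterConfig
    samples: dict[str, SampleCallData]
    removed_pdx_enriched: dict
    removed_prevalent: dict
    final_calls: dict[str, list[VariantCall]]

    def final_keys(self, sample_id: str) -> set:
        return {c.key for c in self.final_calls[sample_id]}

    def concordance_reports(self, driver_only: bool = False) -> list[PairConcordance]:
        return [
            pair_concordance(
                self.final_calls[primary_id], self.final_calls[pdx_id],
                driver_only=driver_only, pair_id=primary_id.rsplit("_", 1)[0],
            )
            for primary_id, pdx_id in self.cohort.pairing
        ]


def process_sample(
    readset,
    cohort: Cohort,
    cfg: FilterConfig,
    min_alt_obs: int = 3,
) -> SampleCallData:
    """Partition, pile up and hard-filter one sample's two datasets."""
    masks = partition_readset(readset)
    targets = [(s, e) for s, e, _ in cohort.panel.target_regions]
    ref_codes = cohort.genomes.human_codes
    contig = cohort.genomes.contig_name_human
    error_rate = max(cohort.config.base_error_rate, 1e-4)

    survivors: dict[str, list[VariantCall]] = {}
    n_candidates: dict[str, int] = {}
    fail_tally: dict[str, int] = {}
    relaxed_af: dict = {}
    for dataset, mask in ((DATASET_RELAXED, masks.relaxed), (DATASET_STRICT, masks.strict)):
        pileup = Pileup.from_readset(readset, ref_codes, targets, read_mask=mask, contig=contig)
        candidates = call_candidates(pileup, min_alt_obs=min_alt_obs, error_rate=error_rate)
        n_candidates[dataset] = len(candidates)
        if dataset == DATASET_RELAXED:
            relaxed_af = {c.key: c.alt_fraction for c in candidates}
        kept: list[VariantCall] = []
        for cand in candidates:
            call = run_call_filters(cand, readset.sample_id, dataset, cfg)
            if call.passed:
                kept.append(call)
            else:
                for rule in call.failed_rules:
                    fail_tally[rule] = fail_tally.get(rule, 0) + 1
        survivors[dataset] = kept
    return SampleCallData(
        sample_id=readset.sample_id,
        partition_counts=masks.counts,
        relaxed_af=relaxed_af,
        survivors=survivors,
        n_candidates=n_candidates,
        fail_tally=fail_tally,
    )


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    filter_cfg: FilterConfig | None = None,
    cohort: Cohort | None = None,
) -> PipelineResult:
    """Simulate (or accept) a cohort and run the full analysis over it."""
    cfg = filter_cfg or FilterConfig()
    cohort = cohort or simulate_cohort(config, seed)

    samples = {
        sample_id: process_sample(cohort.readsets[sample_id], cohort, cfg)
        for sample_id in cohort.sample_ids
    }

    removed_pdx = exclude_pdx_enriched_artifacts(
        {s: d.relaxed_af for s, d in samples.items()}, cohort.pairing, cfg
    )
    removed_prev = exclude_high_prevalence(
        {
            dataset: {s: {c.key for c in d.survivors[dataset]} for s, d in samples.items()}
            for dataset in (DATASET_RELAXED, DATASET_STRICT)
        },
        cfg,
    )
    removed = set(removed_pdx) | set(removed_prev)

    final: dict[str, list[VariantCall]] = {}
    for sample_id, data in samples.items():
        strict = [c for c in data.survivors[DATASET_STRICT] if c.key not in removed]
        relaxed = [c for c in data.survivors[DATASET_RELAXED] if c.key not in removed]
        merged = merge_datasets(strict, relaxed)
        kept = filter_population(merged, cohort.pop_af_table, cfg)
        annotate_genes(kept, cohort.gene_models, cohort.driver_genes, cohort.pathway_map)
        final[sample_id] = kept

    return PipelineResult(
        cohort=cohort,
        filter_cfg=cfg,
        samples=samples,
        removed_pdx_enriched=removed_pdx,
        removed_prevalent=removed_prev,
        final_calls=final,
    )


# ------------------------------------------------------------------ scoring


@dataclass
class TruthEvaluation:
    """The pipeline outcome scored against simulator ground truth."""

    truncal_expected: int
    truncal_recovered: int
    artifact_candidates: int
    artifact_in_final: int
    germline_candidates: int
    germline_in_final: int
    median_af_shift_truncal: float
    median_af_shift_shared: float
    frac_shared_elevated: float

    @property
    def truncal_recovery_pct(self) -> float:
        if self.truncal_expected == 0:
            return 100.0
        return 100.0 * self.truncal_recovered / self.truncal_expected

    @property
    def artifact_removal_pct(self) -> float:
        if self.artifact_candidates == 0:
            return 100.0
        return 100.0 * (1.0 - self.artifact_in_final / self.artifact_candidates)

    @property
    def germline_removal_pct(self) -> float:
        if self.germline_candidates == 0:
            return 100.0
        return 100.0 * (1.0 - self.germline_in_final / self.germline_candidates)


def evaluate_against_truth(result: PipelineResult, min_expected_af: float = 0.2) -> TruthEvaluation:
    """Score recovery, artifact/germline removal and AF shifts."""
    cohort = result.cohort

    truncal_expected = 0
    truncal_recovered = 0
    truncal_keys: set = set()
    for case in cohort.cases:
        ids = set(cohort.truncal_variant_ids(case))
        for sample_id, truth in cohort.truths.items():
            if truth.case_id != case.case_id:
                continue
            final_keys = result.final_keys(sample_id)
            for v in truth.variants:
                if v.variant_id not in ids:
                    continue
                truncal_keys.add(v.key)
                if truth.expected_af[v.variant_id][truth.stage] >= min_expected_af:
                    truncal_expected += 1
                    truncal_recovered += int(v.key in final_keys)

    candidate_keys: set = set()
    for data in result.samples.values():
        candidate_keys.update(data.relaxed_af)
    final_all: set = set()
    for calls in result.final_calls.values():
        final_all.update(c.key for c in calls)

    artifacts_seen = cohort.artifact_keys & candidate_keys
    germline_seen = cohort.germline_keys() & candidate_keys

    reports = result.concordance_reports()
    shift_all = af_shift(reports)
    truncal_deltas = [
        d for (pair, key), d in shift_all.deltas.items() if key in truncal_keys
    ]
    return TruthEvaluation(
        truncal_expected=truncal_expected,
        truncal_recovered=truncal_recovered,
        artifact_candidates=len(artifacts_seen),
        artifact_in_final=len(cohort.artifact_keys & final_all),
        germline_candidates=len(germline_seen),
        germline_in_final=len(cohort.germline_keys() & final_all),
        median_af_shift_truncal=float(np.median(truncal_deltas)) if truncal_deltas else 0.0,
        median_af_shift_shared=shift_all.median_delta,
        frac_shared_elevated=shift_all.frac_elevated,
    )
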