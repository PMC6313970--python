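"""Cohort-level concordance and burden statistics.

Everything here is deterministic arithmetic over final (filtered, merged,
annotated) call sets: per-pair shared/private partitions and retention,
allele-fraction shifts between source tumor and xenograft, mutations per
megabase against the assayed panel length, per-gene mutation rates, the
waterfall (gene x sample) and pathway x sample matrices, and molecular
subtype match-rate summaries where the subtype labels themselves are inputs.

Rounding follows the conventions of targeted-panel reports: percentages to
the nearest integer, mutations/Mb to one decimal, per-gene rates to two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import VariantCall


@dataclass
class PanelDefinition:
    """The assayed panel: target regions, assayed length, gene count.

    Defaults describe a comprehensive cancer panel covering the coding
    regions of 409 cancer genes over 1.29 Mb; synthetic panels are built
    with :meth:`from_regions`.
    """

    target_regions: list[tuple[int, int, str]] = field(default_factory=list)
    assayed_mb: float = 1.29
    gene_count: int = 409

    def __post_init__(self):
        if self.assayed_mb <= 0:
            raise ValueError("assayed_mb must be positive")
        if self.gene_count < 1:
            raise ValueError("gene_count must be >= 1")

    @classmethod
    def from_regions(cls, regions: list[tuple[int, int, str]]) -> "PanelDefinition":
        bp = sum(end - start for start, end, _ in regions)
        genes = {name for _, _, name in regions}
        return cls(target_regions=list(regions), assayed_mb=bp / 1e6, gene_count=len(genes))


def engraftment_rate(engrafted: int, implanted: int) -> int:
    """Percentage of implanted tumors that grew into xenografts."""
    if implanted < 1 or engrafted < 0 or engrafted > implanted:
        raise ValueError("need 0 <= engrafted <= implanted, implanted >= 1")
    return round(100.0 * engrafted / implanted)


def retention_pct(shared: int, source_only: int, xeno_only: int) -> int:
    """Percent of the union of a pair's variants retained in the xenograft."""
    union = shared + source_only + xeno_only
    if union == 0:
        raise ValueError("empty union")
    return round(100.0 * shared / union)


@dataclass
class PairConcordance:
    """Shared/private variant partition for one source/xenograft pair."""

    pair_id: str
    shared_keys: set
    primary_only_keys: set
    pdx_only_keys: set
    af_primary: dict
    af_pdx: dict

    @property
    def union_size(self) -> int:
        return len(self.shared_keys) + len(self.primary_only_keys) + len(self.pdx_only_keys)

    @property
    def retention_pct(self) -> int:
        return retention_pct(len(self.shared_keys), len(self.primary_only_keys), len(self.pdx_only_keys))


def pair_concordance(
    primary_calls: list[VariantCall],
    pdx_calls: list[VariantCall],
    driver_only: bool = False,
    pair_id: str = "pair",
) -> PairConcordance:
    """Partition a pair's variant keys into shared and private sets."""
    if driver_only:
        primary_calls = [c for c in primary_calls if c.is_driver]
        pdx_calls = [c for c in pdx_calls if c.is_driver]
    af_p = {c.key: c.af for c in primary_calls}
    af_x = {c.key: c.af for c in pdx_calls}
    shared = set(af_p) & set(af_x)
    return PairConcordance(
        pair_id=pair_id,
        shared_keys=shared,
        primary_only_keys=set(af_p) - shared,
        pdx_only_keys=set(af_x) - shared,
        af_primary=af_p,
        af_pdx=af_x,
    )


@dataclass
class CohortConcordance:
    """Cohort roll-up of per-pair concordance partitions."""

    shared_total: int
    primary_only_total: int
    pdx_only_total: int

    @property
    def union_total(self) -> int:
        return self.shared_total + self.primary_only_total + self.pdx_only_total

    @property
    def retention_pct(self) -> int:
        return retention_pct(self.shared_total, self.primary_only_total, self.pdx_only_total)


def cohort_concordance(reports: list[PairConcordance]) -> CohortConcordance:
    return CohortConcordance(
        shared_total=sum(len(r.shared_keys) for r in reports),
        primary_only_total=sum(len(r.primary_only_keys) for r in reports),
        pdx_only_total=sum(len(r.pdx_only_keys) for r in reports),
    )


@dataclass
class AfShiftSummary:
    """Allele-fraction shifts of shared variants, source tumor vs xenograft."""

    deltas: dict
    frac_elevated: float
    n_reached_full: int  # xenograft AF at 100%
    median_delta: float


def af_shift(report: PairConcordance | list[PairConcordance], full_af: float = 1.0) -> AfShiftSummary:
    """Per-variant AF deltas over shared variants, plus elevation summary."""
    reports = report if isinstance(report, list) else [report]
    deltas: dict = {}
    n_full = 0
    for r in reports:
        for key in r.shared_keys:
            deltas[(r.pair_id, key)] = r.af_pdx[key] - r.af_primary[key]
            if r.af_pdx[key] >= full_af:
                n_full += 1
    values = np.array(list(deltas.values())) if deltas else np.array([0.0])
    frac_elev = float((values > 0).mean()) if deltas else 0.0
    return AfShiftSummary(
        deltas=deltas,
        frac_elevated=frac_elev,
        n_reached_full=n_full,
        median_delta=float(np.median(values)) if deltas else 0.0,
    )


def mutations_per_mb(
    counts_by_sample: dict[str, int],
    panel: PanelDefinition,
    classes: dict[str, str] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Tumor mutational burden per sample and median per sample class.

    TMB = variant count / assayed megabases, reported to one decimal.
    """
    tmb = {s: round(n / panel.assayed_mb, 1) for s, n in counts_by_sample.items()}
    medians: dict[str, float] = {}
    if classes:
        by_class: dict[str, list[float]] = {}
        for s, value in tmb.items():
            by_class.setdefault(classes.get(s, "unknown"), []).append(value)
        medians = {c: round(float(np.median(v)), 1) for c, v in by_class.items()}
    return tmb, medians


def variants_per_gene_per_sample(total_calls: int, gene_count: int, n_samples: int) -> float:
    """Average variants per panel gene per sample, to two decimals."""
    if gene_count < 1 or n_samples < 1:
        raise ValueError("gene_count and n_samples must be >= 1")
    return round(total_calls / (gene_count * n_samples), 2)


def _zygosity(call: VariantCall, hom_threshold: float) -> int:
    return 2 if call.af >= hom_threshold else 1


def waterfall_matrix(
    calls_by_sample: dict[str, list[VariantCall]],
    min_sample_frac: float = 0.10,
    hom_threshold: float = 0.8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x sample mutation matrix for genes mutated in > 10% of samples.

    Cell values: 0 unmutated, 1 heterozygous, 2 homozygous (max over the
    sample's calls in that gene). Genes are ordered by descending mutation
    frequency, ties broken by name; frequencies are returned alongside.
    """
    samples = sorted(calls_by_sample)
    n_samples = len(samples)
    if n_samples == 0:
        return pd.DataFrame(), pd.Series(dtype=float)
    zyg: dict[str, dict[str, int]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            for gene in call.genes:
                row = zyg.setdefault(gene, {})
                row[sample] = max(row.get(sample, 0), _zygosity(call, hom_threshold))
    freqs = {g: len(row) / n_samples for g, row in zyg.items()}
    keep = sorted(
        (g for g, f in freqs.items() if f > min_sample_frac),
        key=lambda g: (-freqs[g], g),
    )
    matrix = pd.DataFrame(0, index=keep, columns=samples, dtype=int)
    for g in keep:
        for sample, z in zyg[g].items():
            matrix.loc[g, sample] = z
    freq_series = pd.Series({g: round(100 * freqs[g]) for g in keep}, dtype=int)
    return matrix, freq_series


def pathway_overlap(
    calls_by_sample: dict[str, list[VariantCall]],
    pathway_map: dict[str, list[str]],
    hom_threshold: float = 0.8,
) -> pd.DataFrame:
    """Pathway x sample matrix of max-zygosity mutation status.

    A sample's entry for a pathway is the maximum zygosity (0/1/2) over its
    calls in genes mapped to that pathway. Pathways with no mapped genes
    yield an all-zero row.
    """
    samples = sorted(calls_by_sample)
    pathways = sorted({pw for pws in pathway_map.values() for pw in pws})
    matrix = pd.DataFrame(0, index=pathways, columns=samples, dtype=int)
    for sample, calls in calls_by_sample.items():
        for call in calls:
            z = _zygosity(call, hom_threshold)
            for gene in call.genes:
                for pw in pathway_map.get(gene, []):
                    matrix.loc[pw, sample] = max(matrix.loc[pw, sample], z)
    return matrix


@dataclass
class MatchRate:
    matched: int
    total: int
    percent: int
    excluded: int = 0


def subtype_match_rate(table: pd.DataFrame, classifier_name: str) -> MatchRate:
    """Fraction of pairs whose xenograft label matches the source label.

    ``table`` is long-form with columns ``case``, ``classifier``,
    ``primary_label``, ``pdx_label``; labels are external inputs. Pairs with
    a missing label are excluded and counted in ``excluded``.
    """
    sub = table[table["classifier"] == classifier_name]
    if sub.empty:
        raise ValueError(f"no rows for classifier {classifier_name!r}")
    present = sub.dropna(subset=["primary_label", "pdx_label"])
    excluded = len(sub) - len(present)
    total = len(present)
    matched = int((present["primary_label"] == present["pdx_label"]).sum())
    percent = round(100.0 * matched / total) if total else 0
    return MatchRate(matched=matched, total=total, percent=percent, excluded=excluded)
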