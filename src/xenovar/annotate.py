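"""Gene, driver and pathway annotation of variant calls.

Annotation is deliberately simple: interval overlap against gene models
(BED-style intervals with names), membership in a user-supplied driver gene
list (a stand-in for a cancer gene census), and a gene-to-pathway map.
Consequence prediction and deleteriousness scoring are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .filters import VariantCall


@dataclass(frozen=True)
class GeneModel:
    """One gene interval: 0-based half-open on the shared contig."""

    name: str
    start: int
    end: int

    def overlaps(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


def annotate_genes(
    calls: list[VariantCall],
    gene_models: list[GeneModel],
    driver_list: set[str] | None = None,
    pathway_map: dict[str, list[str]] | None = None,
) -> list[VariantCall]:
    """Attach gene ids, driver flags and pathway tags to calls, in place.

    A call overlapping several gene intervals is assigned all of them (the
    first is the primary ``gene``); an intergenic call gets ``gene=None`` and
    is excluded from per-gene statistics downstream.
    """
    driver_list = driver_list or set()
    pathway_map = pathway_map or {}
    for call in calls:
        pos0 = call.candidate.pos - 1
        hits = tuple(g.name for g in gene_models if g.overlaps(pos0))
        call.genes = hits
        call.gene = hits[0] if hits else None
        call.is_driver = any(g in driver_list for g in hits)
        tags: list[str] = []
        for g in hits:
            for pw in pathway_map.get(g, []):
                if pw not in tags:
                    tags.append(pw)
        call.pathways = tuple(tags)
    return calls
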