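"""Relaxed/strict read partitioning from dual-genome alignments.

Reads aligned to both the human and the mouse reference are split into two
per-sample datasets by mapping quality:

* relaxed — reads mapping to the human genome with MAPQ >= 30, regardless of
  how well they map to mouse;
* strict — relaxed reads that additionally do **not** map to the mouse genome
  with MAPQ >= 17 (unmapped against mouse counts as not mapping).

The strict set is mouse-depleted but loses human reads from regions conserved
between the genomes; the relaxed set keeps those regions at the price of
residual mouse contamination, which downstream cohort-level exclusions mop
up. By construction strict is a subset of relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .reads import MAPQ_UNMAPPED, ReadSet

CLASS_NONE = "none"
CLASS_RELAXED_ONLY = "relaxed_only"
CLASS_STRICT = "strict"

DEFAULT_MIN_HUMAN_MAPQ = 30
DEFAULT_MOUSE_MAPQ_CUTOFF = 17


def classify_read(
    human_mapq: int | None,
    mouse_mapq: int | None,
    min_human_mapq: int = DEFAULT_MIN_HUMAN_MAPQ,
    mouse_mapq_cutoff: int = DEFAULT_MOUSE_MAPQ_CUTOFF,
) -> str:
    """Classify one read from its dual MAPQs.

    ``None`` (or -1) denotes unmapped. Returns ``"strict"`` (in both
    datasets), ``"relaxed_only"`` (relaxed but not strict) or ``"none"``.
    """
    h = None if human_mapq is None or human_mapq == MAPQ_UNMAPPED else int(human_mapq)
    m = None if mouse_mapq is None or mouse_mapq == MAPQ_UNMAPPED else int(mouse_mapq)
    if (h is not None and h < 0) or (m is not None and m < 0):
        raise ValueError("MAPQ must be non-negative (or None for unmapped)")
    if h is None or h < min_human_mapq:
        return CLASS_NONE
    if m is None or m < mouse_mapq_cutoff:
        return CLASS_STRICT
    return CLASS_RELAXED_ONLY


@dataclass
class PartitionedReads:
    """Relaxed/strict read-name sets for one sample, plus summary counts."""

    sample_id: str
    relaxed_ids: set[str]
    strict_ids: set[str]
    n_total: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.strict_ids <= self.relaxed_ids:
            raise ValueError("strict set must be a subset of the relaxed set")
        self.counts = {
            "relaxed": len(self.relaxed_ids),
            "strict": len(self.strict_ids),
            "relaxed_only": len(self.relaxed_ids) - len(self.strict_ids),
            "none": self.n_total - len(self.relaxed_ids),
        }


def _as_mapq_map(alignments) -> dict[str, int | None]:
    """Normalize alignment input to {read_id: mapq-or-None}.

    Accepts a mapping or an iterable of (read_id, mapq) records. Duplicate
    read ids with conflicting MAPQs are an error (secondary records should
    have been dropped upstream).
    """
    if isinstance(alignments, Mapping):
        return dict(alignments)
    out: dict[str, int | None] = {}
    for read_id, mapq in alignments:
        if read_id in out and out[read_id] != mapq:
            raise ValueError(f"conflicting alignment records for read {read_id!r}")
        out[read_id] = mapq
    return out


def partition_sample(
    human_alignments,
    mouse_alignments,
    sample_id: str = "sample",
    min_human_mapq: int = DEFAULT_MIN_HUMAN_MAPQ,
    mouse_mapq_cutoff: int = DEFAULT_MOUSE_MAPQ_CUTOFF,
) -> PartitionedReads:
    """Build relaxed and strict read sets from per-genome MAPQ records.

    A read absent from the mouse records counts as not mapping to mouse;
    a read absent from the human records is discarded. Idempotent.
    """
    human = _as_mapq_map(human_alignments)
    mouse = _as_mapq_map(mouse_alignments)
    relaxed: set[str] = set()
    strict: set[str] = set()
    for read_id, h in human.items():
        cls = classify_read(h, mouse.get(read_id), min_human_mapq, mouse_mapq_cutoff)
        if cls != CLASS_NONE:
            relaxed.add(read_id)
            if cls == CLASS_STRICT:
                strict.add(read_id)
    return PartitionedReads(sample_id, relaxed, strict, n_total=len(human))


@dataclass
class PartitionMasks:
    """Vectorized partition of a simulated :class:`ReadSet`."""

    sample_id: str
    relaxed: np.ndarray
    strict: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "relaxed": int(self.relaxed.sum()),
            "strict": int(self.strict.sum()),
            "relaxed_only": int((self.relaxed & ~self.strict).sum()),
            "none": int((~self.relaxed).sum()),
        }


def partition_readset(
    readset: ReadSet,
    min_human_mapq: int = DEFAULT_MIN_HUMAN_MAPQ,
    mouse_mapq_cutoff: int = DEFAULT_MOUSE_MAPQ_CUTOFF,
) -> PartitionMasks:
    """Vectorized equivalent of :func:`partition_sample` on in-memory reads."""
    h = readset.mapq_human
    m = readset.mapq_mouse
    relaxed = (h != MAPQ_UNMAPPED) & (h >= min_human_mapq)
    strict = relaxed & ((m == MAPQ_UNMAPPED) | (m < mouse_mapq_cutoff))
    return PartitionMasks(readset.sample_id, relaxed, strict)
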