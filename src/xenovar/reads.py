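"""Read simulation with dual-genome alignment records and full truth tables.

One simulated sample is a mixture of read compartments — tumor cells, human
stroma, mouse stroma — drawn per the clonal model's stage composition. Tumor
and human-stroma reads are copied from the human-like reference (with planted
variants applied per carrying clone and heterozygous phase), mouse reads from
the mouse-like reference. Per-base substitution errors are applied at a
configurable rate with a matching constant base quality.

Alignment is simulated, not performed. Each read receives a dual alignment:
against its genome of origin the MAPQ is high (60 minus small noise); against
the other genome the MAPQ decays with the local human/mouse divergence in the
read footprint,

    MAPQ_cross = round(60 * max(0, 1 - k * d_local)),

with the read reported unmapped when the score hits zero. This reproduces the
phenomenon the downstream MAPQ thresholds exploit — mouse reads map poorly to
the human reference except in conserved regions — without running an aligner.

Reads are single-end and fixed-length, matching semiconductor-sequencer
semantics, and all randomness flows from the sample's single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clonal import (
    ORIGIN_HUMAN_STROMA,
    ORIGIN_MOUSE_STROMA,
    ORIGIN_NAMES,
    ORIGIN_TUMOR,
    ClonalModel,
)
from .genome import GenomePair, seq_to_codes

# pysam-style CIGAR operation codes
CIG_M, CIG_I, CIG_D = 0, 1, 2

MAPQ_UNMAPPED = -1
OWN_MAPQ = 60


@dataclass
class SampleSpec:
    """Sequencing parameters for one simulated sample."""

    stage: str
    depth: float = 500.0
    read_length: int = 100
    base_error_rate: float = 0.01
    base_quality: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if not (0.0 <= self.base_error_rate < 0.05):
            raise ValueError("base_error_rate must lie in [0, 0.05)")


@dataclass
class ComplexRead:
    """A read whose alignment is not a plain match (it carries an indel)."""

    index: int
    cigar: tuple[tuple[int, int], ...]
    seq_codes: np.ndarray
    ref_span: int


@dataclass
class ReadSet:
    """All reads of one sample, column-oriented for vectorized processing.

    ``seqs`` holds the aligned-orientation sequence of every read as base
    codes; reads flagged in ``is_complex`` carry an indel and their true
    sequence/CIGAR live in ``complex_reads`` instead. ``mapq_human`` /
    ``mapq_mouse`` are the dual alignment MAPQs (-1 = unmapped). ``origins``
    and ``clone_idx`` are truth labels, not visible to the analysis stages.
    """

    sample_id: str
    stage: str
    read_length: int
    base_quality: int
    starts: np.ndarray
    strand: np.ndarray
    seqs: np.ndarray
    origins: np.ndarray
    clone_idx: np.ndarray
    mapq_human: np.ndarray
    mapq_mouse: np.ndarray
    mmqs: np.ndarray
    is_complex: np.ndarray
    complex_reads: dict[int, ComplexRead] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return len(self.starts)

    def read_id(self, i: int) -> str:
        return f"{self.sample_id}:r{i:06d}"

    def origin_name(self, i: int) -> str:
        return ORIGIN_NAMES[self.origins[i]]

    def read_sequence(self, i: int) -> np.ndarray:
        if self.is_complex[i]:
            return self.complex_reads[i].seq_codes
        return self.seqs[i]


@dataclass
class TruthSet:
    """Ground truth for one simulated sample.

    ``expected_af[variant_id][stage]`` is purity x carrying-clone fraction x
    ploidy factor; ``read_origins`` maps read index to compartment.
    """

    case_id: str
    sample_id: str
    stage: str
    variants: list
    expected_af: dict[str, dict[str, float]]
    read_origins: np.ndarray

    def origin_counts(self) -> dict[str, int]:
        counts = np.bincount(self.read_origins, minlength=3)
        return dict(zip(ORIGIN_NAMES, (int(c) for c in counts)))


def _apply_snv(seqs, starts, idx, pos0, alt_code):
    offs = pos0 - starts[idx]
    seqs[idx, offs] = alt_code


def simulate_reads(
    genomes: GenomePair,
    model: ClonalModel,
    spec: SampleSpec,
    sample_id: str | None = None,
    targets: list[tuple[int, int]] | None = None,
    mapq_decay: float = 10.0,
) -> tuple[ReadSet, TruthSet]:
    """Simulate one sample's reads with dual alignments and truth labels.

    Returns a :class:`ReadSet` (reads plus dual-genome alignment records)
    and a :class:`TruthSet`. Deterministic given ``spec.seed``.
    """
    G = len(genomes)
    L = spec.read_length
    if L >= G:
        raise ValueError("read_length must be smaller than the genome")
    stage = spec.stage
    sample_id = sample_id or f"{model.case_id}_{stage}"

    if targets is not None:
        tmask = np.zeros(G, dtype=bool)
        for t_start, t_end in targets:
            tmask[t_start:t_end] = True
        for v in model.variants:
            if not tmask[v.pos0]:
                raise ValueError(f"variant {v.variant_id} outside target regions")
    for v in model.variants:
        end_on_ref = v.pos0 + len(v.ref)
        if end_on_ref > G:
            raise ValueError(f"variant {v.variant_id} outside reference")

    rng = np.random.default_rng(spec.seed)
    n_reads = int(round(spec.depth * (G - L + 1) / L))
    if n_reads < 1:
        raise ValueError("depth too low: no reads to simulate")

    sh = model.stromal_human_fraction.get(stage, 0.0)
    sm = model.stromal_mouse_fraction.get(stage, 0.0)
    p_origin = np.array([1.0 - sh - sm, sh, sm])
    origins = rng.choice(3, size=n_reads, p=p_origin).astype(np.uint8)

    clone_idx = np.full(n_reads, -1, dtype=np.int16)
    tumor_mask = origins == ORIGIN_TUMOR
    fracs = model.clone_fractions(stage)
    clone_idx[tumor_mask] = rng.choice(len(fracs), size=int(tumor_mask.sum()), p=fracs).astype(np.int16)

    starts = rng.integers(0, G - L + 1, size=n_reads).astype(np.int64)
    strand = rng.random(n_reads) < 0.5

    offsets = np.arange(L)
    seqs = genomes.human_codes[starts[:, None] + offsets]
    mouse_rows = origins == ORIGIN_MOUSE_STROMA
    if mouse_rows.any():
        seqs[mouse_rows] = genomes.mouse_codes[starts[mouse_rows, None] + offsets]

    # plant variants; heterozygous sites hit each carrier read with p=1/2
    indel_events: dict[int, object] = {}
    for v in model.variants:
        if v.germline:
            carrier = origins != ORIGIN_MOUSE_STROMA
        else:
            carrier = np.isin(clone_idx, model.carriers(v.variant_id))
        if v.vtype == "SNP":
            overlap = (starts <= v.pos0) & (starts + L > v.pos0)
        else:
            d = len(v.ref) - len(v.alt)
            li = max(0, -d)
            # anchor inside the read with room for the event and ref tail
            overlap = (starts <= v.pos0) & (starts + L - 2 - li >= v.pos0)
            if d > 0:
                overlap &= starts + L + d <= G
        idx = np.flatnonzero(carrier & overlap)
        if v.zygosity == "het":
            idx = idx[rng.random(len(idx)) < 0.5]
        if v.vtype == "SNP":
            _apply_snv(seqs, starts, idx, v.pos0, seq_to_codes(v.alt)[0])
        else:
            for ridx in idx:
                indel_events.setdefault(int(ridx), v)

    # sequencing errors: uniform substitutions at the configured rate
    n_err = rng.binomial(n_reads * L, spec.base_error_rate)
    if n_err:
        flat = rng.integers(0, n_reads * L, size=n_err)
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        seqs.reshape(-1)[flat] = (seqs.reshape(-1)[flat] + shift) % 4

    # realize indel-carrying reads as complex reads (CIGAR with I/D)
    is_complex = np.zeros(n_reads, dtype=bool)
    complex_reads: dict[int, ComplexRead] = {}
    hcodes = genomes.human_codes
    for ridx, v in indel_events.items():
        start = int(starts[ridx])
        o = v.pos0 - start
        row = seqs[ridx]
        if len(v.ref) > len(v.alt):  # deletion
            d = len(v.ref) - len(v.alt)
            seq = np.concatenate([row[: o + 1], row[o + 1 + d :], hcodes[start + L : start + L + d]])
            cigar = ((CIG_M, o + 1), (CIG_D, d), (CIG_M, L - o - 1))
            ref_span = L + d
        else:  # insertion
            ins = seq_to_codes(v.alt[1:])
            li = len(ins)
            seq = np.concatenate([row[: o + 1], ins, row[o + 1 : L - li]])
            cigar = ((CIG_M, o + 1), (CIG_I, li), (CIG_M, L - o - 1 - li))
            ref_span = L - li
        is_complex[ridx] = True
        complex_reads[ridx] = ComplexRead(ridx, cigar, seq.astype(np.uint8), ref_span)

    # mismatch-quality sums vs the human reference (MMQS, fpfilter-style)
    mm = np.zeros(n_reads, dtype=np.int32)
    simple = ~is_complex
    ref_block = hcodes[starts[:, None] + offsets]
    mm[simple] = (seqs[simple] != ref_block[simple]).sum(axis=1)
    for ridx, cr in complex_reads.items():
        pos = int(starts[ridx])
        qoff = 0
        count = 0
        for op, length in cr.cigar:
            if op == CIG_M:
                count += int((cr.seq_codes[qoff : qoff + length] != hcodes[pos : pos + length]).sum())
                pos += length
                qoff += length
            elif op == CIG_D:
                pos += length
            else:
                qoff += length
        mm[ridx] = count
    mmqs = (mm * spec.base_quality).astype(np.float32)

    # dual-alignment MAPQs
    own = (OWN_MAPQ - rng.binomial(2, 0.1, size=n_reads)).astype(np.int16)
    pre = genomes.diff_prefix
    nd = pre[starts + L] - pre[starts]
    score = 1.0 - mapq_decay * nd / L
    cross = np.where(score > 0, np.round(OWN_MAPQ * np.clip(score, 0, 1)), MAPQ_UNMAPPED).astype(np.int16)
    mouse_origin = origins == ORIGIN_MOUSE_STROMA
    mapq_human = np.where(mouse_origin, cross, own).astype(np.int16)
    mapq_mouse = np.where(mouse_origin, own, cross).astype(np.int16)

    readset = ReadSet(
        sample_id=sample_id,
        stage=stage,
        read_length=L,
        base_quality=spec.base_quality,
        starts=starts,
        strand=strand,
        seqs=seqs,
        origins=origins,
        clone_idx=clone_idx,
        mapq_human=mapq_human,
        mapq_mouse=mapq_mouse,
        mmqs=mmqs,
        is_complex=is_complex,
        complex_reads=complex_reads,
    )
    expected = {
        v.variant_id: {s: model.expected_af(v.variant_id, s) for s in model.stages()}
        for v in model.variants
    }
    truth = TruthSet(
        case_id=model.case_id,
        sample_id=sample_id,
        stage=stage,
        variants=list(model.variants),
        expected_af=expected,
        read_origins=origins.copy(),
    )
    return readset, truth
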