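"""Pileup-based candidate variant calling with hard-filterable metrics.

This module replaces an opaque vendor caller with a transparent pileup: it
tabulates, per reference base inside the target regions, allele counts split
by strand together with per-allele mean mapping quality, mean read length and
mean mismatch-quality sum (MMQS — the sum of base qualities at a read's
mismatching positions, attributed to every allele the read supports). Any
non-reference allele with at least ``min_alt_obs`` supporting reads becomes a
:class:`CandidateVariant` carrying every metric the downstream hard-filter
cascade consumes:

* ``DP``/``FDP`` — depth (flow-corrected depth is equated to plain depth, as
  no flow-space signal exists outside the vendor stack);
* ``FAO``, ``alt_fwd``/``alt_rev``, ``STB`` — alternate observations, their
  strand split, and the majority-strand share of alternate reads;
* ``HRUN`` — reference homopolymer-run length at the variant context;
* ``QUAL`` — Phred-scaled likelihood ratio of "alt allele present at its
  observed fraction" versus "all alternate reads are sequencing errors at a
  fixed rate" under a binomial model;
* ``GQ`` — Phred gap between the best and second-best of the hom-ref /
  het / hom-alt binomial genotype likelihoods.

Insertions and deletions are registered at their left-anchored VCF position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy.stats import binom

from .genome import BASES, codes_to_seq, seq_to_codes
from .reads import CIG_D, CIG_I, CIG_M, ReadSet

LOG10 = np.log(10.0)


def compute_stb(alt_fwd: int, alt_rev: int) -> float:
    """Strand bias of alternate reads: majority-strand share, in [0.5, 1]."""
    total = alt_fwd + alt_rev
    if total <= 0:
        raise ValueError("STB undefined with zero alternate reads")
    return max(alt_fwd, alt_rev) / total


def _run_span(seq: str, i: int) -> int:
    """Length of the homopolymer run containing index ``i``."""
    b = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = i
    n = len(seq)
    while hi + 1 < n and seq[hi + 1] == b:
        hi += 1
    return hi - lo + 1


def compute_hrun(reference: str, pos: int, ref: str, alt: str) -> int:
    """Reference homopolymer-run length (HRUN) at a variant context.

    ``pos`` is 1-based. For a SNP this is the run containing the variant
    base; for an indel, the longest reference run containing or immediately
    abutting the inserted/deleted bases (ties resolve to the longer run).
    Long runs drive indel errors on semiconductor sequencers, hence the
    downstream ``HRUN < 6`` indel filter.
    """
    p0 = pos - 1
    if not (0 <= p0 < len(reference)):
        raise ValueError("variant position outside the reference")
    if len(ref) == 1 and len(alt) == 1:
        return _run_span(reference, p0)
    probe: set[int] = {p0}
    if len(ref) > len(alt):  # deletion of ref[len(alt):]
        probe.update(range(p0 + len(alt), p0 + len(ref)))
        probe.add(p0 + len(ref))
    else:  # insertion after the anchor base
        probe.add(p0 + 1)
    return max(_run_span(reference, i) for i in probe if 0 <= i < len(reference))


@dataclass(slots=True)
class CandidateVariant:
    """A called site with every metric the filter cascade consumes."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    vtype: str  # "SNP" | "indel"
    DP: int
    FDP: int
    FAO: int
    RO: int
    alt_fwd: int
    alt_rev: int
    STB: float
    HRUN: int
    QUAL: float
    GQ: float
    mapq_ref_mean: float | None
    mapq_alt_mean: float | None
    readlen_ref_mean: float | None
    readlen_alt_mean: float | None
    mmqs_ref_mean: float | None
    mmqs_alt_mean: float | None

    @property
    def alt_fraction(self) -> float:
        return self.FAO / self.FDP if self.FDP else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class PileupColumn:
    """One covered target base: per-allele, per-strand counts and metric sums."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, tuple[int, int]]  # allele -> (fwd, rev)
    mapq_sum: dict[str, float]
    mmqs_sum: dict[str, float]
    rlen_sum: dict[str, float]

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())


class _IndelObs:
    __slots__ = ("fwd", "rev", "mapq_sum", "mmqs_sum", "rlen_sum")

    def __init__(self):
        self.fwd = 0
        self.rev = 0
        self.mapq_sum = 0.0
        self.mmqs_sum = 0.0
        self.rlen_sum = 0.0

    @property
    def n(self) -> int:
        return self.fwd + self.rev


class Pileup:
    """Array-backed pileup over one contig, restricted to target regions."""

    def __init__(self, contig: str, ref_codes: np.ndarray, targets: list[tuple[int, int]]):
        self.contig = contig
        self.ref_codes = ref_codes
        G = len(ref_codes)
        self.G = G
        self.target_mask = np.zeros(G, dtype=bool)
        for t_start, t_end in targets:
            if not (0 <= t_start < t_end <= G):
                raise ValueError("target region outside the reference")
            self.target_mask[t_start:t_end] = True
        self.counts = np.zeros((G, 4, 2), dtype=np.int64)
        self.mapq_sum = np.zeros((G, 4), dtype=np.float64)
        self.mmqs_sum = np.zeros((G, 4), dtype=np.float64)
        self.rlen_sum = np.zeros((G, 4), dtype=np.float64)
        self.indels: dict[tuple[int, str, str], _IndelObs] = {}
        self._ref_str: str | None = None

    @property
    def reference(self) -> str:
        if self._ref_str is None:
            self._ref_str = codes_to_seq(self.ref_codes)
        return self._ref_str

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    # ------------------------------------------------------------------ build

    @classmethod
    def from_readset(
        cls,
        readset: ReadSet,
        ref_codes: np.ndarray,
        targets: list[tuple[int, int]],
        read_mask: np.ndarray | None = None,
        contig: str = "chrT_h",
    ) -> "Pileup":
        """Vectorized pileup of an in-memory read set (human-reference frame)."""
        pu = cls(contig, np.asarray(ref_codes, dtype=np.uint8), targets)
        G = pu.G
        mask = np.ones(readset.n_reads, dtype=bool) if read_mask is None else read_mask
        # reads unmapped against this (human) frame contribute no pileup
        mask = mask & (readset.mapq_human != -1)
        simple = mask & ~readset.is_complex

        starts = readset.starts[simple]
        seqs = readset.seqs[simple]
        strand = readset.strand[simple].astype(np.int64)
        mapq = readset.mapq_human[simple].astype(np.float64)
        mmqs = readset.mmqs[simple].astype(np.float64)
        L = readset.read_length

        counts_flat = np.zeros(G * 8, dtype=np.int64)
        mapq_flat = np.zeros(G * 4, dtype=np.float64)
        mmqs_flat = np.zeros(G * 4, dtype=np.float64)
        for j in range(L):
            pb = (starts + j) * 4 + seqs[:, j]
            counts_flat += np.bincount(pb * 2 + strand, minlength=G * 8)
            mapq_flat += np.bincount(pb, weights=mapq, minlength=G * 4)
            mmqs_flat += np.bincount(pb, weights=mmqs, minlength=G * 4)
        pu.counts += counts_flat.reshape(G, 4, 2)
        pu.mapq_sum += mapq_flat.reshape(G, 4)
        pu.mmqs_sum += mmqs_flat.reshape(G, 4)
        pu.rlen_sum += pu.counts.sum(axis=2) * float(L)

        for ridx in np.flatnonzero(mask & readset.is_complex):
            cr = readset.complex_reads[int(ridx)]
            pu._add_complex(
                int(readset.starts[ridx]),
                cr.cigar,
                cr.seq_codes,
                bool(readset.strand[ridx]),
                float(readset.mapq_human[ridx]),
                float(readset.mmqs[ridx]),
            )
        return pu

    def _add_complex(self, start, cigar, seq_codes, strand, mapq, mmqs):
        """Register one gapped read: matched blocks plus its indel allele."""
        pos = start
        qoff = 0
        qlen = len(seq_codes)
        s = int(strand)
        ref = self.reference
        for op, length in cigar:
            if op == CIG_M:
                p = np.arange(pos, pos + length)
                b = seq_codes[qoff : qoff + length].astype(np.int64)
                np.add.at(self.counts, (p, b, s), 1)
                np.add.at(self.mapq_sum, (p, b), mapq)
                np.add.at(self.mmqs_sum, (p, b), mmqs)
                np.add.at(self.rlen_sum, (p, b), float(qlen))
                pos += length
                qoff += length
            elif op == CIG_D:
                anchor = pos - 1
                key = (anchor + 1, ref[anchor : anchor + length + 1], ref[anchor])
                self._add_indel(key, s, mapq, mmqs, qlen)
                pos += length
            elif op == CIG_I:
                anchor = pos - 1
                ins = codes_to_seq(seq_codes[qoff : qoff + length])
                key = (anchor + 1, ref[anchor], ref[anchor] + ins)
                self._add_indel(key, s, mapq, mmqs, qlen)
                qoff += length
            else:
                raise ValueError(f"unsupported CIGAR op {op}")

    def _add_indel(self, key, strand, mapq, mmqs, qlen):
        obs = self.indels.setdefault(key, _IndelObs())
        if strand:
            obs.rev += 1
        else:
            obs.fwd += 1
        obs.mapq_sum += mapq
        obs.mmqs_sum += mmqs
        obs.rlen_sum += qlen

    @classmethod
    def from_alignments(
        cls,
        alignments,
        reference: str,
        targets: list[tuple[int, int]],
        contig: str | None = None,
        default_base_quality: int = 20,
    ) -> "Pileup":
        """Per-read pileup of a SAM/BAM source (path or pysam AlignmentFile).

        Secondary, supplementary and unmapped records are skipped. MMQS per
        read is computed against ``reference`` using the record's base
        qualities (falling back to ``default_base_quality``).
        """
        import pysam

        close = False
        if isinstance(alignments, (str,)) or hasattr(alignments, "__fspath__"):
            alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
            close = True
        ref_codes = seq_to_codes(reference)
        pu = cls(contig or "ref", ref_codes, targets)
        try:
            for rec in alignments:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                seq = rec.query_sequence
                if seq is None:
                    continue
                quals = rec.query_qualities
                codes = seq_to_codes(seq)
                cigar = tuple((op, ln) for op, ln in rec.cigartuples if op in (CIG_M, CIG_I, CIG_D))
                # mismatch-quality sum over matched blocks
                pos, qoff, mmqs = rec.reference_start, 0, 0.0
                for op, ln in cigar:
                    if op == CIG_M:
                        block = codes[qoff : qoff + ln]
                        mism = np.flatnonzero(block != ref_codes[pos : pos + ln])
                        if quals is not None:
                            mmqs += float(sum(quals[qoff + int(i)] for i in mism))
                        else:
                            mmqs += default_base_quality * len(mism)
                        pos += ln
                        qoff += ln
                    elif op == CIG_D:
                        pos += ln
                    else:
                        qoff += ln
                pu._add_complex(
                    rec.reference_start, cigar, codes, rec.is_reverse,
                    float(rec.mapping_quality), mmqs,
                )
        finally:
            if close:
                alignments.close()
        return pu

    # ----------------------------------------------------------------- views

    def columns(self) -> Iterator[PileupColumn]:
        """Yield one :class:`PileupColumn` per covered target base."""
        depth = self.depth
        for pos0 in np.flatnonzero(self.target_mask & (depth > 0)):
            pos0 = int(pos0)
            counts, mapq_s, mmqs_s, rlen_s = {}, {}, {}, {}
            for b in range(4):
                f, r = int(self.counts[pos0, b, 0]), int(self.counts[pos0, b, 1])
                if f + r:
                    allele = BASES[b]
                    counts[allele] = (f, r)
                    mapq_s[allele] = float(self.mapq_sum[pos0, b])
                    mmqs_s[allele] = float(self.mmqs_sum[pos0, b])
                    rlen_s[allele] = float(self.rlen_sum[pos0, b])
            yield PileupColumn(
                self.contig, pos0 + 1, BASES[self.ref_codes[pos0]],
                counts, mapq_s, mmqs_s, rlen_s,
            )

    @classmethod
    def from_columns(cls, columns: Iterable[PileupColumn], reference: str) -> "Pileup":
        """Rebuild an array pileup from explicit columns (substitutions only)."""
        cols = list(columns)
        ref_codes = seq_to_codes(reference)
        contig = cols[0].contig if cols else "ref"
        pu = cls(contig, ref_codes, [(0, len(ref_codes))])
        for col in cols:
            p0 = col.pos - 1
            for allele, (f, r) in col.counts.items():
                b = BASES.index(allele)
                pu.counts[p0, b, 0] += f
                pu.counts[p0, b, 1] += r
                pu.mapq_sum[p0, b] += col.mapq_sum.get(allele, 0.0)
                pu.mmqs_sum[p0, b] += col.mmqs_sum.get(allele, 0.0)
                pu.rlen_sum[p0, b] += col.rlen_sum.get(allele, 0.0)
        return pu


def compute_pileup(alignments, reference, targets) -> Pileup:
    """Pileup entry point: in-memory :class:`ReadSet` or SAM/BAM source.

    ``reference`` may be a sequence string or an encoded uint8 array;
    ``targets`` is a list of 0-based half-open intervals.
    """
    ref_codes = seq_to_codes(reference) if isinstance(reference, str) else np.asarray(reference, dtype=np.uint8)
    if isinstance(alignments, ReadSet):
        return Pileup.from_readset(alignments, ref_codes, targets)
    return Pileup.from_alignments(alignments, codes_to_seq(ref_codes), targets)


def _phred_ratio(ll1: np.ndarray, ll0: np.ndarray) -> np.ndarray:
    return 10.0 * (ll1 - ll0) / LOG10


def call_candidates(
    pileup,
    min_alt_obs: int = 3,
    error_rate: float = 0.01,
) -> list[CandidateVariant]:
    """Emit every non-reference allele with >= ``min_alt_obs`` observations.

    Accepts a :class:`Pileup` or an iterable of :class:`PileupColumn`.
    All hard filtering is deferred to the filter cascade; this stage only
    enforces the minimum alternate-observation count.
    """
    if not isinstance(pileup, Pileup):
        first = list(pileup)
        if not first:
            return []
        # reconstruct a reference long enough for run-length context
        max_pos = max(c.pos for c in first)
        ref = ["A"] * (max_pos + 10)
        for c in first:
            ref[c.pos - 1] = c.ref_base
        pileup = Pileup.from_columns(first, "".join(ref))

    e = error_rate
    ref_codes = pileup.ref_codes
    cnts = pileup.counts.sum(axis=2)  # (G, 4)
    depth = cnts.sum(axis=1)
    is_ref = np.zeros_like(cnts, dtype=bool)
    is_ref[np.arange(pileup.G), ref_codes] = True
    cand = (cnts >= min_alt_obs) & ~is_ref & pileup.target_mask[:, None]
    pos_arr, b_arr = np.nonzero(cand)

    out: list[CandidateVariant] = []
    if len(pos_arr):
        FAO = cnts[pos_arr, b_arr]
        DP = depth[pos_arr]
        fwd = pileup.counts[pos_arr, b_arr, 0]
        rev = pileup.counts[pos_arr, b_arr, 1]
        ref_b = ref_codes[pos_arr]
        RO = cnts[pos_arr, ref_b]
        qual, gq = _qual_gq(FAO, DP, e)
        mapq_alt = pileup.mapq_sum[pos_arr, b_arr] / FAO
        mmqs_alt = pileup.mmqs_sum[pos_arr, b_arr] / FAO
        rlen_alt = pileup.rlen_sum[pos_arr, b_arr] / FAO
        with np.errstate(invalid="ignore", divide="ignore"):
            mapq_ref = np.where(RO > 0, pileup.mapq_sum[pos_arr, ref_b] / np.maximum(RO, 1), mapq_alt)
            mmqs_ref = np.where(RO > 0, pileup.mmqs_sum[pos_arr, ref_b] / np.maximum(RO, 1), mmqs_alt)
            rlen_ref = np.where(RO > 0, pileup.rlen_sum[pos_arr, ref_b] / np.maximum(RO, 1), rlen_alt)
        reference = pileup.reference
        for i in range(len(pos_arr)):
            pos1 = int(pos_arr[i]) + 1
            ref_allele = BASES[ref_b[i]]
            alt_allele = BASES[b_arr[i]]
            out.append(
                CandidateVariant(
                    contig=pileup.contig, pos=pos1, ref=ref_allele, alt=alt_allele,
                    vtype="SNP", DP=int(DP[i]), FDP=int(DP[i]), FAO=int(FAO[i]),
                    RO=int(RO[i]), alt_fwd=int(fwd[i]), alt_rev=int(rev[i]),
                    STB=compute_stb(int(fwd[i]), int(rev[i])),
                    HRUN=compute_hrun(reference, pos1, ref_allele, alt_allele),
                    QUAL=float(qual[i]), GQ=float(gq[i]),
                    mapq_ref_mean=float(mapq_ref[i]), mapq_alt_mean=float(mapq_alt[i]),
                    readlen_ref_mean=float(rlen_ref[i]), readlen_alt_mean=float(rlen_alt[i]),
                    mmqs_ref_mean=float(mmqs_ref[i]), mmqs_alt_mean=float(mmqs_alt[i]),
                )
            )

    reference = pileup.reference
    cnts_all = cnts
    for (pos1, ref_allele, alt_allele), obs in sorted(pileup.indels.items()):
        if obs.n < min_alt_obs:
            continue
        p0 = pos1 - 1
        if not pileup.target_mask[p0]:
            continue
        # anchor-base column depth; indel reads match the anchor so they count
        dp = int(depth[p0])
        fao = obs.n
        ro = int(cnts_all[p0, ref_codes[p0]])
        qual, gq = _qual_gq(np.array([fao]), np.array([max(dp, fao)]), e)
        mapq_alt = obs.mapq_sum / fao
        mmqs_alt = obs.mmqs_sum / fao
        rlen_alt = obs.rlen_sum / fao
        if ro > 0:
            mapq_ref = float(pileup.mapq_sum[p0, ref_codes[p0]]) / ro
            mmqs_ref = float(pileup.mmqs_sum[p0, ref_codes[p0]]) / ro
            rlen_ref = float(pileup.rlen_sum[p0, ref_codes[p0]]) / ro
        else:
            mapq_ref, mmqs_ref, rlen_ref = mapq_alt, mmqs_alt, rlen_alt
        out.append(
            CandidateVariant(
                contig=pileup.contig, pos=pos1, ref=ref_allele, alt=alt_allele,
                vtype="indel", DP=dp, FDP=max(dp, fao), FAO=fao, RO=ro,
                alt_fwd=obs.fwd, alt_rev=obs.rev, STB=compute_stb(obs.fwd, obs.rev),
                HRUN=compute_hrun(reference, pos1, ref_allele, alt_allele),
                QUAL=float(qual[0]), GQ=float(gq[0]),
                mapq_ref_mean=mapq_ref, mapq_alt_mean=mapq_alt,
                readlen_ref_mean=rlen_ref, readlen_alt_mean=rlen_alt,
                mmqs_ref_mean=mmqs_ref, mmqs_alt_mean=mmqs_alt,
            )
        )
    out.sort(key=lambda c: (c.pos, c.ref, c.alt))
    return out


def _qual_gq(fao: np.ndarray, fdp: np.ndarray, e: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized QUAL and GQ under the binomial error model."""
    fao = np.asarray(fao, dtype=np.int64)
    fdp = np.asarray(fdp, dtype=np.int64)
    f = np.clip(fao / np.maximum(fdp, 1), e, 1.0 - 1e-12)
    ll_alt = binom.logpmf(fao, fdp, f)
    ll_err = binom.logpmf(fao, fdp, e)
    qual = np.maximum(0.0, _phred_ratio(ll_alt, ll_err))
    geno = np.stack([
        binom.logpmf(fao, fdp, e),            # hom-ref
        binom.logpmf(fao, fdp, 0.5),          # het
        binom.logpmf(fao, fdp, 1.0 - e),      # hom-alt
    ])
    top2 = np.sort(geno, axis=0)[-2:, :]
    gq = _phred_ratio(top2[1], top2[0])
    return qual, gq
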