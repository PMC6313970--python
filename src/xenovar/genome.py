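"""Toy human/mouse reference pairs.

Xenograft sequencing mixes human tumor DNA with mouse stromal DNA. Reads are
mapped against both a human and a mouse reference, and the mapping-quality
contrast between the two is what separates graft from host. For desk-scale
testing we use a coordinate-aligned pair of toy references: the "mouse"
sequence is derived from the "human" one by independent per-position
substitution at a configurable divergence rate, optionally with designated
low-divergence windows that emulate conserved regions where mouse reads map
convincingly to the human reference (the source of mouse-homology artifacts).

Because the pair is coordinate-aligned, the homologous coordinate of any
position is itself, which lets artifacts be planted and traced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (A=0 .. T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for b, i in _CODE.items():
        codes[arr == ord(b)] = i
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside A/C/G/T")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


@dataclass
class GenomePair:
    """A coordinate-aligned pair of toy references.

    ``human_seq`` and ``mouse_seq`` have equal length; ``divergence`` is the
    nominal per-position substitution rate between them (low-divergence
    windows excepted). ``homology_map`` is the identity because the toy pair
    is built without rearrangement.
    """

    human_seq: str
    mouse_seq: str
    divergence: float
    contig_name_human: str = "chrT_h"
    contig_name_mouse: str = "chrT_m"
    homology_map: str = "identity"
    low_divergence_windows: tuple = ()

    # caches
    _human_codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _mouse_codes: np.ndarray | None = field(default=None, repr=False, compare=False)
    _diff_prefix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.human_seq) != len(self.mouse_seq):
            raise ValueError("human and mouse sequences must have equal length")

    def __len__(self) -> int:
        return len(self.human_seq)

    @property
    def human_codes(self) -> np.ndarray:
        if self._human_codes is None:
            self._human_codes = seq_to_codes(self.human_seq)
        return self._human_codes

    @property
    def mouse_codes(self) -> np.ndarray:
        if self._mouse_codes is None:
            self._mouse_codes = seq_to_codes(self.mouse_seq)
        return self._mouse_codes

    @property
    def diff_prefix(self) -> np.ndarray:
        """Prefix sums of per-position human/mouse differences.

        ``diff_prefix[j] - diff_prefix[i]`` is the number of diverged
        positions in ``[i, j)``; used for local-divergence MAPQ models.
        """
        if self._diff_prefix is None:
            diffs = (self.human_codes != self.mouse_codes).astype(np.int64)
            self._diff_prefix = np.concatenate([[0], np.cumsum(diffs)])
        return self._diff_prefix

    def diverged_positions(self, start: int = 0, end: int | None = None) -> np.ndarray:
        """0-based positions in [start, end) where the two references differ."""
        end = len(self) if end is None else end
        window = self.human_codes[start:end] != self.mouse_codes[start:end]
        return np.flatnonzero(window) + start

    def local_divergence(self, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        pre = self.diff_prefix
        return float(pre[end] - pre[start]) / (end - start)


def make_genome_pair(
    length: int,
    divergence: float,
    homopolymer_enrichment: float = 0.0,
    seed: int = 0,
    low_divergence_windows: list[tuple[int, int, float]] | None = None,
) -> GenomePair:
    """Build a coordinate-aligned human-like/mouse-like reference pair.

    Parameters
    ----------
    length : int
        Genome length in bases (>= 1000).
    divergence : float
        Per-position substitution rate between the two sequences, in [0, 0.5].
    homopolymer_enrichment : float
        Expected number of planted homopolymer runs (length 4-8) per kilobase.
        Runs are written into both sequences identically, so they carry no
        divergence themselves; they exist to exercise homopolymer-run (HRUN)
        metrics and indel placement.
    seed : int
        Seed for the generator; output is deterministic given the arguments.
    low_divergence_windows : list of (start, end, rate)
        Half-open 0-based intervals whose substitution rate overrides
        ``divergence``. Used to plant conserved regions.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if not (0.0 <= divergence <= 0.5):
        raise ValueError("divergence must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)

    human = rng.integers(0, 4, size=length).astype(np.uint8)

    if homopolymer_enrichment > 0:
        n_runs = rng.poisson(homopolymer_enrichment * length / 1000.0)
        for _ in range(n_runs):
            run_len = int(rng.integers(4, 9))
            start = int(rng.integers(0, length - run_len))
            human[start : start + run_len] = rng.integers(0, 4)

    rate = np.full(length, divergence)
    windows = tuple(low_divergence_windows or ())
    for w_start, w_end, w_rate in windows:
        if not (0 <= w_start < w_end <= length):
            raise ValueError("low-divergence window outside genome")
        rate[w_start:w_end] = w_rate

    sub_mask = rng.random(length) < rate
    mouse = human.copy()
    # substituted base is always different from the human base
    mouse[sub_mask] = (human[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4

    return GenomePair(
        human_seq=codes_to_seq(human),
        mouse_seq=codes_to_seq(mouse),
        divergence=divergence,
        low_divergence_windows=windows,
    )
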