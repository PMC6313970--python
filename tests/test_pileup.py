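"""Pileup metrics: STB, HRUN, candidate emission, and a pysam cross-check."""

import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xenovar import (
    Clone,
    ClonalModel,
    PlantedVariant,
    Pileup,
    SampleSpec,
    call_candidates,
    compute_hrun,
    compute_pileup,
    compute_stb,
    make_genome_pair,
    simulate_reads,
)
from xenovar.io import write_sam
from xenovar.pileup import PileupColumn

# ------------------------------------------------------------------ STB


@pytest.mark.parametrize("fwd,rev,expected", [(5, 5, 0.5), (9, 1, 0.9), (7, 0, 1.0), (1, 3, 0.75)])
def test_stb_values(fwd, rev, expected):
    assert compute_stb(fwd, rev) == pytest.approx(expected)


def test_stb_zero_alt_reads_undefined():
    with pytest.raises(ValueError):
        compute_stb(0, 0)


@given(st.integers(0, 500), st.integers(0, 500))
def test_stb_symmetric_and_bounded(a, b):
    if a + b == 0:
        return
    stb = compute_stb(a, b)
    assert stb == compute_stb(b, a)
    assert 0.5 <= stb <= 1.0


# ------------------------------------------------------------------ HRUN


def test_hrun_deletion_in_run():
    # deleting one A out of the 5-A run: HRUN is the run length
    ref = "CGAAAAAG"
    assert compute_hrun(ref, 2, "GA", "G") == 5


def test_hrun_snp_without_run_context():
    assert compute_hrun("ACGT", 2, "C", "G") == 1


def test_hrun_insertion_abutting_long_run():
    ref = "CTAAAAAAG"  # six As starting at index 2
    assert compute_hrun(ref, 2, "T", "TA") == 6


def test_hrun_snp_inside_run_counts_whole_run():
    ref = "GGAAAAATT"
    assert compute_hrun(ref, 5, "A", "C") == 5


def test_hrun_out_of_range_position():
    with pytest.raises(ValueError):
        compute_hrun("ACGT", 9, "A", "C")


# ------------------------------------------------------- columns/candidates


def _column(ref_counts, alt_counts, pos=50, ref="A", alt="G", mapq=(59.0, 59.0), mmqs=(20.0, 30.0)):
    rf, rr = ref_counts
    af, ar = alt_counts
    counts, mapq_s, mmqs_s, rlen_s = {}, {}, {}, {}
    if rf + rr:
        counts[ref] = (rf, rr)
        mapq_s[ref] = mapq[0] * (rf + rr)
        mmqs_s[ref] = mmqs[0] * (rf + rr)
        rlen_s[ref] = 100.0 * (rf + rr)
    if af + ar:
        counts[alt] = (af, ar)
        mapq_s[alt] = mapq[1] * (af + ar)
        mmqs_s[alt] = mmqs[1] * (af + ar)
        rlen_s[alt] = 100.0 * (af + ar)
    return PileupColumn("chrT_h", pos, ref, counts, mapq_s, mmqs_s, rlen_s)


def test_balanced_alt_column_yields_candidate_with_expected_metrics():
    col = _column((30, 30), (20, 20))
    cands = call_candidates([col])
    assert len(cands) == 1
    c = cands[0]
    assert c.alt_fraction == pytest.approx(0.4)
    assert c.STB == pytest.approx(0.5)
    assert c.DP == 100 and c.FAO == 40 and c.RO == 60
    assert c.QUAL > 20 and c.GQ > 5


def test_pure_reference_column_yields_no_candidate():
    assert call_candidates([_column((50, 50), (0, 0))]) == []


def test_min_alt_obs_threshold_is_inclusive():
    assert call_candidates([_column((49, 49), (1, 1))], min_alt_obs=3) == []
    assert call_candidates([_column((49, 48), (2, 1))], min_alt_obs=3) != []


def test_error_level_alt_fraction_gets_no_qual_support():
    col = _column((248, 249), (2, 1))
    (c,) = call_candidates([col], min_alt_obs=3, error_rate=0.01)
    assert c.QUAL < 20  # indistinguishable from sequencing error


# ------------------------------------------------------------ simulated data


def _flat_model(genomes, variants, purity=1.0):
    return ClonalModel(
        case_id="case",
        clones=[Clone("c", tuple(v.variant_id for v in variants), {"primary": 1.0})],
        variants=variants,
        stromal_human_fraction={"primary": 1.0 - purity},
        stromal_mouse_fraction={"primary": 0.0},
    )


@pytest.fixture(scope="module")
def noise_free_sample():
    genomes = make_genome_pair(4000, 0.0, homopolymer_enrichment=1.0, seed=30)
    pos_snv, pos_hom = 1200, 2400
    ref1 = genomes.human_seq[pos_snv]
    ref2 = genomes.human_seq[pos_hom]
    variants = [
        PlantedVariant("het", pos_snv, ref1, "ACGT"[("ACGT".index(ref1) + 1) % 4], "SNP"),
        PlantedVariant("hom", pos_hom, ref2, "ACGT"[("ACGT".index(ref2) + 2) % 4], "SNP", zygosity="hom"),
    ]
    model = _flat_model(genomes, variants)
    spec = SampleSpec("primary", depth=300, base_error_rate=0.0, seed=31)
    rs, truth = simulate_reads(genomes, model, spec)
    return genomes, model, rs, truth, variants


def test_noise_free_calls_are_exactly_the_planted_variants(noise_free_sample):
    genomes, model, rs, truth, variants = noise_free_sample
    pileup = compute_pileup(rs, genomes.human_codes, [(200, 3800)])
    cands = call_candidates(pileup, min_alt_obs=3, error_rate=0.001)
    assert {c.key for c in cands} == {v.key for v in variants}
    by_id = {c.key: c for c in cands}
    het = by_id[variants[0].key]
    sd = 3 * np.sqrt(0.5 * 0.5 / het.DP)
    assert abs(het.alt_fraction - 0.5) < sd
    hom = by_id[variants[1].key]
    assert hom.alt_fraction == pytest.approx(1.0)
    assert hom.RO == 0  # fpfilter comparisons must be vacuous downstream


def test_alt_fraction_converges_to_expected_af_at_high_depth():
    genomes = make_genome_pair(2000, 0.0, seed=33)
    pos0 = 900
    ref = genomes.human_seq[pos0]
    v = PlantedVariant("t", pos0, ref, "ACGT"[("ACGT".index(ref) + 1) % 4], "SNP")
    model = _flat_model(genomes, [v], purity=0.8)
    rs, _ = simulate_reads(genomes, model, SampleSpec("primary", depth=2000, seed=34))
    pileup = compute_pileup(rs, genomes.human_codes, [(800, 1000)])
    (c,) = [c for c in call_candidates(pileup) if c.pos == pos0 + 1 and c.alt == v.alt]
    expected = 0.4
    assert abs(c.alt_fraction - expected) < 3 * np.sqrt(expected * (1 - expected) / c.DP)


def test_empty_targets_produce_no_columns(noise_free_sample):
    genomes, model, rs, _, _ = noise_free_sample
    pileup = compute_pileup(rs, genomes.human_codes, [])
    assert list(pileup.columns()) == []
    assert call_candidates(pileup) == []


def test_deletion_registered_at_left_anchor():
    genomes = make_genome_pair(3000, 0.0, homopolymer_enrichment=2.0, seed=35)
    pos0 = 1500
    ref = genomes.human_seq[pos0 : pos0 + 2]
    v = PlantedVariant("d", pos0, ref, ref[0], "indel", zygosity="hom")
    model = _flat_model(genomes, [v])
    rs, _ = simulate_reads(genomes, model, SampleSpec("primary", depth=80, base_error_rate=0.0, seed=36))
    pileup = compute_pileup(rs, genomes.human_codes, [(1000, 2000)])
    indel_cands = [c for c in call_candidates(pileup) if c.vtype == "indel"]
    assert len(indel_cands) == 1
    c = indel_cands[0]
    assert (c.pos, c.ref, c.alt) == (pos0 + 1, ref, ref[0])
    assert c.FAO > 0 and c.alt_fwd + c.alt_rev == c.FAO


def test_pileup_counts_match_pysam_count_coverage(tmp_path):
    """Independent oracle: htslib's pileup over the same written alignments."""
    pysam = pytest.importorskip("pysam")
    genomes = make_genome_pair(2500, 0.0, seed=40)
    pos0 = 1100
    ref = genomes.human_seq[pos0]
    v = PlantedVariant("t", pos0, ref, "ACGT"[("ACGT".index(ref) + 1) % 4], "SNP")
    model = _flat_model(genomes, [v], purity=0.8)
    rs, _ = simulate_reads(genomes, model, SampleSpec("primary", depth=40, seed=41))
    sam = tmp_path / "s.sam"
    write_sam(rs, sam, genomes, "human")
    bam = tmp_path / "s.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    with pysam.AlignmentFile(bam) as fh:
        cov = fh.count_coverage(genomes.contig_name_human, 0, 2500, quality_threshold=0)
    oracle = np.array(cov)  # (4, G) in A,C,G,T order
    mine = compute_pileup(rs, genomes.human_codes, [(0, 2500)]).counts.sum(axis=2).T
    assert np.array_equal(oracle, mine)
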