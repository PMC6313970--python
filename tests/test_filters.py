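"""Filter cascade: printed-threshold boundaries, cohort exclusions, merging."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from xenovar import (
    FilterConfig,
    GeneModel,
    VariantCall,
    annotate_genes,
    apply_fpfilter,
    apply_primary_filters,
    apply_support_filters,
    exclude_high_prevalence,
    exclude_pdx_enriched_artifacts,
    filter_population,
    merge_datasets,
    normalize_variant,
    run_call_filters,
)

from conftest import make_candidate

CFG = FilterConfig()


def failed(trail):
    return [rule for rule, ok in trail if not ok]


# ------------------------------------------------------------ primary rules


@pytest.mark.parametrize(
    "overrides,expect_fail",
    [
        (dict(DP=19), ["DP"]),                       # depth just below 20
        (dict(DP=20), []),                           # inclusive boundary
        (dict(QUAL=19.99), ["QUAL"]),
        (dict(GQ=5.0), ["GQ"]),                      # GQ must exceed 5
        (dict(STB=0.9, alt_fwd=54, alt_rev=6), ["STB"]),  # STB < 0.9 is strict
        (dict(FDP=6, DP=6), ["DP", "FDP"]),
        (dict(FAO=2, alt_fwd=1, alt_rev=1), ["FAO"]),
    ],
)
def test_snp_primary_boundaries(overrides, expect_fail):
    ok, trail = apply_primary_filters(make_candidate(**overrides), CFG)
    assert failed(trail) == expect_fail
    assert ok == (not expect_fail)


def test_minimal_passing_snp_vector():
    c = make_candidate(DP=20, QUAL=20.0, GQ=6.0, FDP=7, FAO=3, STB=0.89, alt_fwd=2, alt_rev=1)
    ok, _ = apply_primary_filters(c, CFG)
    assert ok


@pytest.mark.parametrize(
    "overrides,expect_fail",
    [
        (dict(HRUN=6), ["HRUN"]),   # HRUN < 6 is strict
        (dict(HRUN=5), []),
        (dict(FDP=10, DP=20), ["FDP"]),  # indel FDP must exceed 10
        (dict(FAO=4, alt_fwd=2, alt_rev=2), ["FAO"]),
    ],
)
def test_indel_primary_boundaries(overrides, expect_fail):
    base = dict(vtype="indel", ref="TA", alt="T", FDP=30, FAO=8, alt_fwd=4, alt_rev=4, HRUN=3)
    base.update(overrides)
    ok, trail = apply_primary_filters(make_candidate(**base), CFG)
    assert failed(trail) == expect_fail


def test_unknown_variant_type_rejected():
    with pytest.raises(ValueError):
        apply_primary_filters(make_candidate(vtype="mnp"), CFG)


# ----------------------------------------------------------- fpfilter rules


def test_one_sided_strand_support_fails_strandedness():
    c = make_candidate(FAO=41, alt_fwd=40, alt_rev=1, RO=100)
    ok, trail = apply_fpfilter(c, CFG)
    assert "strandedness" in failed(trail)


def test_mapqual_difference_boundary():
    ok, _ = apply_fpfilter(make_candidate(mapq_ref_mean=58.0, mapq_alt_mean=48.0), CFG)
    assert ok  # diff exactly 10 allowed
    ok, trail = apply_fpfilter(make_candidate(mapq_ref_mean=58.0, mapq_alt_mean=47.0), CFG)
    assert failed(trail) == ["mapqual_diff"]


def test_mmqs_difference_is_one_sided():
    # alt cleaner than ref never fails the MMQS rule
    ok, _ = apply_fpfilter(make_candidate(mmqs_ref_mean=100.0, mmqs_alt_mean=20.0), CFG)
    assert ok
    ok, trail = apply_fpfilter(make_candidate(mmqs_ref_mean=20.0, mmqs_alt_mean=71.0), CFG)
    assert failed(trail) == ["mm_qualsum_diff"]


def test_identical_allele_profiles_pass():
    ok, _ = apply_fpfilter(make_candidate(), CFG)
    assert ok


def test_missing_metric_fails_closed():
    ok, trail = apply_fpfilter(make_candidate(mapq_ref_mean=None), CFG)
    assert not ok
    assert any("metric_missing" in rule for rule in failed(trail))


def test_no_reference_reads_make_comparisons_vacuous():
    c = make_candidate(RO=0, FAO=200, FDP=200, DP=200, alt_fwd=100, alt_rev=100,
                       mmqs_ref_mean=0.0, mmqs_alt_mean=500.0)
    ok, _ = apply_fpfilter(c, CFG)
    assert ok  # homozygous sites must not be killed by undefined comparisons


# ------------------------------------------------------------ support rules


@pytest.mark.parametrize(
    "fwd,rev,fao,fdp,ok",
    [
        (5, 4, 9, 30, False),   # one strand below five
        (5, 5, 10, 30, True),
        (10, 10, 20, 202, False),  # fraction 0.099 just under 10%
        (50, 50, 100, 200, True),
    ],
)
def test_support_boundaries(fwd, rev, fao, fdp, ok):
    c = make_candidate(alt_fwd=fwd, alt_rev=rev, FAO=fao, FDP=fdp, DP=fdp)
    got, _ = apply_support_filters(c, CFG)
    assert got == ok


# ------------------------------------------------------------ cohort rules


def _af_maps(n_pairs, enriched_pairs, af=0.3):
    key = ("chrT_h", 100, "A", "G")
    maps, pairing = {}, []
    for i in range(n_pairs):
        pt, px = f"pt{i}", f"px{i}"
        pairing.append((pt, px))
        maps[pt] = {}
        maps[px] = {key: af} if i < enriched_pairs else {}
    return key, maps, pairing


def test_pdx_enrichment_four_of_ten_pairs_removed():
    key, maps, pairing = _af_maps(10, 4)
    assert key in exclude_pdx_enriched_artifacts(maps, pairing, CFG)


def test_pdx_enrichment_three_pairs_retained():
    key, maps, pairing = _af_maps(10, 3)
    assert exclude_pdx_enriched_artifacts(maps, pairing, CFG) == {}


def test_pdx_enrichment_ignores_error_level_fractions():
    # noise at the error scale in unrelated xenografts must not count
    key, maps, pairing = _af_maps(10, 2, af=0.3)
    for i in range(2, 10):
        maps[f"px{i}"][key] = 0.01
    assert exclude_pdx_enriched_artifacts(maps, pairing, CFG) == {}


def test_pdx_enrichment_missing_sample_rejected():
    key, maps, pairing = _af_maps(4, 1)
    del maps["px0"]
    with pytest.raises(ValueError):
        exclude_pdx_enriched_artifacts(maps, pairing, CFG)


def _prevalence_input(n_samples, n_with, dataset="relaxed"):
    key = ("chrT_h", 100, "A", "G")
    by_sample = {f"s{i}": ({key} if i < n_with else set()) for i in range(n_samples)}
    return key, {dataset: by_sample}


def test_prevalence_twentysix_percent_removed():
    key, data = _prevalence_input(50, 13)  # 0.26 in relaxed only
    data["strict"] = {s: set() for s in data["relaxed"]}
    assert key in exclude_high_prevalence(data, CFG)


def test_prevalence_twentyfour_percent_in_both_datasets_retained():
    key, data = _prevalence_input(50, 12)
    data["strict"] = {s: set(v) for s, v in data["relaxed"].items()}
    assert exclude_high_prevalence(data, CFG) == {}


def test_prevalence_boundary_is_strictly_more_than():
    key, data = _prevalence_input(4, 1)  # exactly 0.25
    assert exclude_high_prevalence(data, CFG) == {}


def test_prevalence_empty_cohort_rejected():
    with pytest.raises(ValueError):
        exclude_high_prevalence({"relaxed": {}}, CFG)


# ------------------------------------------------------------------- merge


def _call(sample, pos, dataset, ref="A", alt="G", af=0.4):
    fao = int(af * 200)
    cand = make_candidate(pos=pos, ref=ref, alt=alt, FAO=fao, alt_fwd=fao // 2, alt_rev=fao - fao // 2)
    return VariantCall(cand, sample, dataset)


def test_merge_keeps_provenance_and_dedupes():
    strict = [_call("s1", 100, "strict")]
    relaxed = [_call("s1", 100, "relaxed"), _call("s1", 200, "relaxed")]
    merged = merge_datasets(strict, relaxed)
    by_pos = {c.candidate.pos: c for c in merged}
    assert len(merged) == 2
    assert by_pos[100].provenance == "both"
    assert by_pos[200].provenance == "relaxed"


def test_merge_disjoint_sets_is_additive():
    strict = [_call("s1", 100 + i, "strict") for i in range(10)]
    relaxed = [_call("s1", 500 + i, "relaxed") for i in range(7)]
    assert len(merge_datasets(strict, relaxed)) == 17


def test_merge_conflicting_reference_alleles_rejected():
    strict = [_call("s1", 100, "strict", ref="A", alt="G")]
    relaxed = [_call("s1", 100, "relaxed", ref="C", alt="G")]
    with pytest.raises(ValueError):
        merge_datasets(strict, relaxed)


# -------------------------------------------------------------- population


def test_population_filter_boundaries():
    common = _call("s1", 100, "strict")
    rare = _call("s1", 200, "strict")
    unknown = _call("s1", 300, "strict")
    table = {common.key: 0.05, rare.key: 0.001}
    kept = filter_population([common, rare, unknown], table, CFG)
    assert {c.candidate.pos for c in kept} == {200, 300}  # 0.001 is retained


def test_population_filter_malformed_af():
    call = _call("s1", 100, "strict")
    with pytest.raises(ValueError):
        filter_population([call], {call.key: 7.0}, CFG)


# -------------------------------------------------------------- annotation


def test_gene_driver_and_pathway_annotation():
    genes = [GeneModel("APC", 0, 200), GeneModel("KRAS", 150, 400)]
    inside = _call("s1", 100, "strict")
    overlap = _call("s1", 180, "strict")
    outside = _call("s1", 900, "strict")
    annotate_genes(
        [inside, overlap, outside], genes, driver_list={"APC"},
        pathway_map={"APC": ["Wnt", "TGF-beta"], "KRAS": ["MAPK"]},
    )
    assert inside.gene == "APC" and inside.is_driver
    assert set(inside.pathways) == {"Wnt", "TGF-beta"}
    assert set(overlap.genes) == {"APC", "KRAS"}
    assert set(overlap.pathways) == {"Wnt", "TGF-beta", "MAPK"}
    assert outside.gene is None and not outside.is_driver


# ------------------------------------------------------------ normalization


@pytest.mark.parametrize(
    "pos,ref,alt,expected",
    [
        (4, "AA", "A", (3, "CA", "C")),     # deletion shifts left through AA context
        (4, "AC", "TC", (4, "A", "T")),     # suffix trim to a SNP
        (4, "A", "A" , (4, "A", "A")),
        (2, "GAT", "GCT", (3, "A", "C")),   # prefix+suffix trim
    ],
)
def test_normalize_variant(pos, ref, alt, expected):
    #       123456789
    ref_seq = "GGCAATTGG"
    assert normalize_variant(ref_seq, pos, ref, alt) == expected


# ---------------------------------------------------- trail/oracle property


RULE_STRATEGY = st.fixed_dictionaries(
    dict(
        vtype=st.sampled_from(["SNP", "indel"]),
        DP=st.integers(0, 60),
        QUAL=st.floats(0, 40, allow_nan=False),
        GQ=st.floats(0, 10, allow_nan=False),
        FDP=st.integers(1, 25),
        alt_fwd=st.integers(0, 12),
        alt_rev=st.integers(0, 12),
        STB_bias=st.floats(0.5, 1.0),
        HRUN=st.integers(1, 8),
        mapq_alt_mean=st.floats(40, 60),
        mmqs_alt_mean=st.floats(0, 90),
    )
)


def brute_force_pass(c, cfg=CFG):
    """Independent re-statement of the cascade as one boolean expression."""
    common = c.DP >= 20 and c.QUAL >= 20 and c.GQ > 5
    if c.vtype == "SNP":
        typed = c.FDP > 6 and c.FAO > 2 and c.STB < 0.9
    else:
        typed = c.FDP > 10 and c.HRUN < 6 and c.FAO > 4
    if c.RO == 0:
        fp_cmp = True
    else:
        fp_cmp = (
            abs(c.mapq_ref_mean - c.mapq_alt_mean) <= 10
            and abs(c.readlen_ref_mean - c.readlen_alt_mean) <= 10
            and (c.mmqs_alt_mean - c.mmqs_ref_mean) <= 50
        )
    fp = c.FAO > 0 and min(c.alt_fwd, c.alt_rev) / c.FAO >= 0.05 and fp_cmp
    support = c.alt_fwd >= 5 and c.alt_rev >= 5 and c.FAO / c.FDP >= 0.10
    return common and typed and fp and support


@given(RULE_STRATEGY)
def test_cascade_agrees_with_brute_force_predicate(params):
    fao = params["alt_fwd"] + params["alt_rev"]
    if fao == 0:
        return
    fdp = max(params["FDP"], fao)
    c = make_candidate(
        vtype=params["vtype"],
        ref="TA" if params["vtype"] == "indel" else "A",
        alt="T" if params["vtype"] == "indel" else "G",
        DP=params["DP"], FDP=fdp, FAO=fao,
        RO=max(params["DP"] - fao, 0),
        alt_fwd=params["alt_fwd"], alt_rev=params["alt_rev"],
        STB=max(params["alt_fwd"], params["alt_rev"]) / fao,
        HRUN=params["HRUN"], QUAL=params["QUAL"], GQ=params["GQ"],
        mapq_alt_mean=params["mapq_alt_mean"], mmqs_alt_mean=params["mmqs_alt_mean"],
    )
    call = run_call_filters(c, "s", "strict", CFG)
    assert call.passed == brute_force_pass(c)
    # the trail must pinpoint the rules that removed a failed call
    if not call.passed:
        assert call.failed_rules
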