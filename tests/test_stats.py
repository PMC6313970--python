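"""Concordance, burden and subtype arithmetic at targeted-panel report precision."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xenovar import (
    PanelDefinition,
    VariantCall,
    af_shift,
    cohort_concordance,
    engraftment_rate,
    mutations_per_mb,
    pair_concordance,
    pathway_overlap,
    retention_pct,
    subtype_match_rate,
    variants_per_gene_per_sample,
    waterfall_matrix,
)

from conftest import make_candidate


def _call(sample, pos, af=0.4, genes=(), driver=False):
    fao = max(int(round(af * 200)), 1)
    cand = make_candidate(pos=pos, FAO=fao, FDP=200, DP=200,
                          alt_fwd=fao // 2, alt_rev=fao - fao // 2)
    vc = VariantCall(cand, sample, "both")
    vc.genes = tuple(genes)
    vc.gene = genes[0] if genes else None
    vc.is_driver = driver
    return vc


# ----------------------------------------------------------- concordance


def test_cohort_retention_from_published_style_counts():
    # 228 shared, 48 source-private, 11 xenograft-private -> 287 total, 79%
    assert retention_pct(228, 48, 11) == 79
    assert 228 + 48 + 11 == 287


def test_pair_concordance_partitions_the_union():
    primary = [_call("pt", p) for p in (100, 200, 300)]
    pdx = [_call("px", p) for p in (200, 300, 400, 500)]
    rep = pair_concordance(primary, pdx)
    assert {k[1] for k in rep.shared_keys} == {200, 300}
    assert {k[1] for k in rep.primary_only_keys} == {100}
    assert {k[1] for k in rep.pdx_only_keys} == {400, 500}
    assert rep.union_size == 5
    assert rep.retention_pct == 40


def test_identical_and_disjoint_call_sets():
    same = [_call("pt", p) for p in (1, 2, 3)]
    rep = pair_concordance(same, [_call("px", p) for p in (1, 2, 3)])
    assert rep.retention_pct == 100 and not rep.primary_only_keys and not rep.pdx_only_keys
    rep = pair_concordance([_call("pt", 1)], [_call("px", 2)])
    assert rep.retention_pct == 0


def test_driver_only_restricts_to_driver_calls():
    primary = [_call("pt", 100, driver=True), _call("pt", 200)]
    pdx = [_call("px", 100, driver=True), _call("px", 300)]
    rep = pair_concordance(primary, pdx, driver_only=True)
    assert rep.union_size == 1 and rep.retention_pct == 100


@given(
    st.sets(st.integers(1, 40), max_size=15),
    st.sets(st.integers(1, 40), max_size=15),
)
def test_partition_identity_and_symmetry(pos_a, pos_b):
    if not pos_a | pos_b:
        return
    a = [_call("pt", p) for p in pos_a]
    b = [_call("px", p) for p in pos_b]
    rep = pair_concordance(a, b)
    assert len(rep.shared_keys) + len(rep.primary_only_keys) + len(rep.pdx_only_keys) == rep.union_size
    flipped = pair_concordance(b, a)
    assert flipped.retention_pct == rep.retention_pct
    assert flipped.primary_only_keys == rep.pdx_only_keys


def test_cohort_concordance_sums_pairs():
    reps = [
        pair_concordance([_call("pt", 1), _call("pt", 2)], [_call("px", 2)]),
        pair_concordance([_call("pt", 5)], [_call("px", 5), _call("px", 6)]),
    ]
    roll = cohort_concordance(reps)
    assert (roll.shared_total, roll.primary_only_total, roll.pdx_only_total) == (2, 1, 1)
    assert roll.retention_pct == 50


# -------------------------------------------------------------- AF shift


def test_af_shift_deltas_and_full_flag():
    primary = [_call("pt", 100, af=0.3), _call("pt", 200, af=0.5)]
    pdx = [_call("px", 100, af=0.6), _call("px", 200, af=1.0)]
    rep = pair_concordance(primary, pdx)
    shift = af_shift(rep)
    deltas = {k[1][1]: d for k, d in shift.deltas.items()}
    assert deltas[100] == pytest.approx(0.3)
    assert shift.frac_elevated == 1.0
    assert shift.n_reached_full == 1
    assert shift.median_delta == pytest.approx(0.4, abs=1e-9)


# ------------------------------------------------------------------- TMB


def test_mutations_per_mb_rounding_against_panel_length():
    panel = PanelDefinition()  # 1.29 Mb
    tmb, medians = mutations_per_mb(
        {"pt": 14, "px": 19, "empty": 0}, panel,
        classes={"pt": "primary", "px": "PDX_P2", "empty": "primary"},
    )
    assert tmb == {"pt": 10.9, "px": 14.7, "empty": 0.0}
    assert medians["PDX_P2"] == 14.7
    assert medians["primary"] == pytest.approx(5.5)


def test_tmb_linear_in_call_count():
    panel = PanelDefinition(assayed_mb=0.5)
    tmb, _ = mutations_per_mb({"a": 10, "b": 20}, panel)
    assert tmb["b"] == pytest.approx(2 * tmb["a"])


# -------------------------------------------------------------- per gene


@pytest.mark.parametrize(
    "total,genes,samples,expected",
    [(2832, 409, 50, 0.14), (0, 409, 50, 0.0), (409, 409, 1, 1.0)],
)
def test_variants_per_gene_per_sample(total, genes, samples, expected):
    assert variants_per_gene_per_sample(total, genes, samples) == pytest.approx(expected)


def test_variants_per_gene_rejects_zero_denominator():
    with pytest.raises(ValueError):
        variants_per_gene_per_sample(10, 0, 5)


def test_panel_from_regions_measures_length_and_genes():
    panel = PanelDefinition.from_regions([(0, 1000, "A"), (2000, 3500, "B")])
    assert panel.assayed_mb == pytest.approx(0.0025)
    assert panel.gene_count == 2


# -------------------------------------------------------------- waterfall


def test_waterfall_excludes_boundary_and_orders_by_frequency():
    samples = {f"s{i}": [] for i in range(50)}
    for i in range(5):  # exactly 10% of samples: excluded (strictly more than)
        samples[f"s{i}"].append(_call(f"s{i}", 100, genes=("RARE",)))
    for i in range(32):  # 64%
        samples[f"s{i}"].append(_call(f"s{i}", 200, genes=("COMMON",)))
    for i in range(6):  # 12%
        samples[f"s{i}"].append(_call(f"s{i}", 300, genes=("MID",)))
    matrix, freqs = waterfall_matrix(samples, min_sample_frac=0.10)
    assert list(matrix.index) == ["COMMON", "MID"]
    assert freqs["COMMON"] == 64
    assert matrix.loc["COMMON"].sum() == 32


def test_waterfall_zygosity_and_empty_cohort():
    samples = {"s0": [_call("s0", 100, af=0.95, genes=("G1",))]}
    matrix, _ = waterfall_matrix(samples, min_sample_frac=0.0)
    assert matrix.loc["G1", "s0"] == 2  # homozygous at AF >= 0.8
    empty, freqs = waterfall_matrix({})
    assert empty.empty and freqs.empty


# ---------------------------------------------------------------- pathway


def test_pathway_matrix_takes_max_zygosity():
    pw_map = {"APC": ["Wnt"], "KRAS": ["MAPK"], "SMAD4": ["TGF-beta"]}
    samples = {
        "s0": [
            _call("s0", 100, af=0.4, genes=("APC",)),
            _call("s0", 200, af=0.9, genes=("APC",)),   # hom beats het in Wnt
            _call("s0", 300, af=0.4, genes=("KRAS",)),
        ],
        "s1": [],
    }
    matrix = pathway_overlap(samples, pw_map)
    assert matrix.loc["Wnt", "s0"] == 2
    assert matrix.loc["MAPK", "s0"] == 1
    assert matrix.loc["TGF-beta"].sum() == 0  # mapped gene never mutated
    assert matrix["s1"].sum() == 0


# ---------------------------------------------------------------- subtype


def _subtype_table(matches_by_classifier, total=20):
    rows = []
    for clf, n_match in matches_by_classifier.items():
        for i in range(total):
            rows.append(
                dict(
                    case=f"c{i}", classifier=clf,
                    primary_label="CMS2",
                    pdx_label="CMS2" if i < n_match else "CMS3",
                )
            )
    return pd.DataFrame(rows)


def test_subtype_match_percentages():
    # classifiers failing 10, 17, 5 and 9 of 20 pairs match 10, 3, 15, 11
    table = _subtype_table({"CMS": 10, "CMScaller": 3, "PDX": 15, "CRIS": 11})
    assert subtype_match_rate(table, "PDX").percent == 75
    assert subtype_match_rate(table, "PDX").matched == 15
    assert subtype_match_rate(table, "CMS").percent == 50
    assert subtype_match_rate(table, "CMScaller").percent == 15
    assert subtype_match_rate(table, "CRIS").percent == 55


def test_subtype_all_mismatched_and_missing_labels():
    table = _subtype_table({"CMS": 0}, total=20)
    assert subtype_match_rate(table, "CMS").percent == 0
    table.loc[0, "pdx_label"] = None
    rate = subtype_match_rate(table, "CMS")
    assert rate.total == 19 and rate.excluded == 1
    with pytest.raises(ValueError):
        subtype_match_rate(table, "nope")


# ------------------------------------------------------------- engraftment


def test_engraftment_rates():
    assert engraftment_rate(20, 37) == 54
    assert engraftment_rate(5, 5) == 100
    with pytest.raises(ValueError):
        engraftment_rate(6, 5)
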