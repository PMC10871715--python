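"""Pooling of per-study tables: crude vs CMH risk ratios and the confounding gate."""

from fractions import Fraction

import pytest

import roar


def _study(sid, a, b, c, d):
    return roar.StudyTable(sid, roar.DichotomousTable(a, b, c, d))


@pytest.fixture
def confounded_pair():
    """Two studies with identical stratum RR = 2 but opposite allocation ratios.

    Crude pooling mixes the strata (Simpson-style) while CMH recovers the
    common stratum risk ratio, so the confounding gate must fire.
    """
    return [_study("s1", 20, 80, 30, 270), _study("s2", 150, 150, 25, 75)]


def _crude_exact(studies):
    sa = sum(s.table.a for s in studies)
    sc = sum(s.table.c for s in studies)
    return Fraction(sa * sum(s.table.c + s.table.d for s in studies),
                    sc * sum(s.table.a + s.table.b for s in studies))


def test_single_stratum_identity(example_table):
    studies = [roar.StudyTable("only", example_table)]
    assert roar.pooled_crude_rr(studies) == pytest.approx(1.4, rel=1e-12)
    assert roar.cmh_rr(studies) == pytest.approx(1.4, rel=1e-12)


def test_pooled_crude_rr_printed_meta_value(meta_table):
    studies = [roar.StudyTable("pooled", meta_table)]
    assert roar.pooled_crude_rr(studies) == pytest.approx(0.8481, abs=5e-5)


def test_homogeneous_copies_have_zero_confounding(example_table):
    for k in (2, 5):
        studies = [roar.StudyTable(f"s{i}", example_table) for i in range(k)]
        analysis = roar.assess_pooling(studies)
        assert analysis.rr_crude == pytest.approx(1.4, rel=1e-12)
        assert analysis.confounding == pytest.approx(0.0, abs=1e-12)
        assert analysis.roar_applicable


def test_confounded_pair_fires_gate(confounded_pair):
    crude = roar.pooled_crude_rr(confounded_pair)
    cmh = roar.cmh_rr(confounded_pair)
    assert crude == pytest.approx(float(_crude_exact(confounded_pair)), rel=1e-12)
    assert cmh == pytest.approx(2.0, rel=1e-12)  # both strata have RR exactly 2
    assert crude != pytest.approx(cmh, rel=1e-3)
    analysis = roar.assess_pooling(confounded_pair)
    assert analysis.confounding > 0.10
    assert not analysis.roar_applicable


def test_gate_is_strict_less_than(example_table):
    studies = [roar.StudyTable("s1", example_table), roar.StudyTable("s2", example_table)]
    analysis = roar.assess_pooling(studies, threshold=0.0)
    assert not analysis.roar_applicable  # confounding 0 is not < 0


def test_pooled_table_is_exact_cellwise_sum(confounded_pair):
    pooled = roar.pooled_table(confounded_pair)
    assert pooled.cells() == (170, 230, 55, 345)


def test_order_invariance(confounded_pair):
    forward = roar.assess_pooling(confounded_pair)
    backward = roar.assess_pooling(list(reversed(confounded_pair)))
    assert forward.rr_crude == backward.rr_crude
    assert forward.rr_cmh == backward.rr_cmh
    assert forward.pooled == backward.pooled


def test_synthetic_split_of_pooled_meta_table(meta_table):
    """A synthetic near-homogeneous 5-study split of the pooled table keeps the
    crude RR (which depends only on the cell sums) and passes the gate."""
    split = [
        _study("t1", 80, 3840, 94, 3825),
        _study("t2", 79, 3841, 93, 3826),
        _study("t3", 80, 3841, 94, 3826),
        _study("t4", 79, 3841, 93, 3825),
        _study("t5", 79, 3841, 94, 3826),
    ]
    assert roar.pooled_table(split) == meta_table
    analysis = roar.assess_pooling(split)
    assert analysis.rr_crude == pytest.approx(0.8481, abs=5e-5)
    assert analysis.confounding < 0.10
    assert analysis.roar_applicable


def test_duplicate_or_empty_ids_rejected(example_table):
    with pytest.raises(ValueError):
        roar.assess_pooling(
            [roar.StudyTable("x", example_table), roar.StudyTable("x", example_table)]
        )
    with pytest.raises(ValueError):
        roar.StudyTable("  ", example_table)
    with pytest.raises(ValueError):
        roar.assess_pooling([])


def test_zero_cell_study_warns(example_table):
    studies = [_study("s1", 0, 50, 10, 40), roar.StudyTable("s2", example_table)]
    analysis = roar.assess_pooling(studies)
    assert any("zero cell" in w for w in analysis.warnings)


def test_read_studies_csv_round_trip(tmp_path):
    path = tmp_path / "studies.csv"
    path.write_text("study,a,b,c,d\ns1,70,30,50,50\ns2,10,90,20,80\n")
    studies = roar.read_studies_csv(path)
    assert [s.study_id for s in studies] == ["s1", "s2"]
    assert studies[1].table.cells() == (10, 90, 20, 80)


@pytest.mark.parametrize(
    "content",
    [
        "trial,a,b,c,d\ns1,70,30,50,50\n",  # wrong header
        "study,a,b,c,d\ns1,70,thirty,50,50\n",  # non-numeric cell
        "study,a,b,c,d\ns1,70.5,30,50,50\n",  # non-integer cell
        "study,a,b,c,d\n",  # no rows
    ],
)
def test_read_studies_csv_schema_violations(tmp_path, content):
    path = tmp_path / "bad.csv"
    path.write_text(content)
    with pytest.raises(ValueError):
        roar.read_studies_csv(path)
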