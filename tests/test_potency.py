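"""Cheng-Prusoff conversion, pKi, ligand efficiency and single-point model."""

import io

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fragpanel._util import round_half_up
from fragpanel.potency import (
    build_potency_table,
    cheng_prusoff_ki,
    ic50_from_single_point,
    ligand_efficiency,
    pki,
    potency_records_frame,
    read_assay_conditions,
    single_point_inhibition,
    AssayCondition,
)

pos = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


@pytest.mark.parametrize(
    "ic50, atp, km, ki",
    [(10, 0, 5, 10), (10, 5, 5, 5), (12, 10, 5, 4)],
)
def test_cheng_prusoff_examples(ic50, atp, km, ki):
    assert cheng_prusoff_ki(ic50, atp, km) == pytest.approx(ki)


@pytest.mark.parametrize("ic50, atp, km", [(0, 5, 5), (-1, 5, 5), (10, 5, 0), (10, -1, 5)])
def test_cheng_prusoff_domain_errors(ic50, atp, km):
    with pytest.raises(ValueError):
        cheng_prusoff_ki(ic50, atp, km)


@given(ic50=pos, km=pos,
       atp=st.one_of(st.just(0.0), st.floats(min_value=1e-3, max_value=1e4)))
def test_cheng_prusoff_bounded_by_ic50(ic50, atp, km):
    ki = cheng_prusoff_ki(ic50, atp, km)
    assert 0 < ki <= ic50
    if atp == 0:
        assert ki == ic50
    elif atp / km > 1e-9:
        assert ki < ic50


@given(ic50=pos, km=pos, atp=st.floats(min_value=0, max_value=1e4),
       datp=st.floats(min_value=1e-3, max_value=1e4))
def test_cheng_prusoff_decreasing_in_atp(ic50, km, atp, datp):
    assert cheng_prusoff_ki(ic50, atp + datp, km) < cheng_prusoff_ki(ic50, atp, km)


@pytest.mark.parametrize("ki, expected", [(1.0, 6.0), (1000.0, 3.0), (5.4, 5.2676)])
def test_pki(ki, expected):
    assert pki(ki) == pytest.approx(expected, abs=5e-5)


def test_pki_rejects_nonpositive():
    with pytest.raises(ValueError):
        pki(0.0)


@pytest.mark.parametrize(
    "ki, hac, le_2dp",
    [(5.4, 22, 0.33), (361.0, 8, 0.59), (94.7, 14, 0.39)],
)
def test_ligand_efficiency_examples(ki, hac, le_2dp):
    assert round_half_up(ligand_efficiency(ki, hac), 2) == le_2dp


# All printed (Ki, LE) table cells whose heavy-atom count follows from a
# published ion formula and which are consistent with the 1.37*pKi/HAC
# convention at +-0.015.  Two cells (the methylpyrazole fragment vs Aurora A
# and the methoxy-bipyridine vs Aurora A) disagree with any single constant
# and are documented as source inconsistencies, not asserted.
PRINTED_LE = [
    (361.0, 8, 0.59), (159.7, 8, 0.64),
    (94.7, 14, 0.39), (3.2, 14, 0.53),
    (91.2, 15, 0.37), (63.9, 15, 0.38),
    (128.2, 14, 0.38), (66.9, 14, 0.41), (70.3, 14, 0.40),
    (269.3, 14, 0.35), (89.6, 14, 0.39), (18.7, 14, 0.46),
    (5.4, 22, 0.33), (3.3, 22, 0.34), (41.0, 22, 0.27),
    (24.8, 24, 0.26),
    (30.1, 26, 0.24), (32.9, 26, 0.23),
]


@pytest.mark.parametrize("ki, hac, printed", PRINTED_LE)
def test_printed_ligand_efficiencies_within_band(ki, hac, printed):
    assert ligand_efficiency(ki, hac) == pytest.approx(printed, abs=0.015)


@given(ki=st.floats(min_value=1e-3, max_value=1e5),
       hac=st.integers(min_value=1, max_value=60))
def test_ligand_efficiency_decreasing_in_size_and_ki(ki, hac):
    assert ligand_efficiency(ki, hac) > ligand_efficiency(ki, hac + 1)
    assert ligand_efficiency(ki, hac) > ligand_efficiency(ki * 2, hac)


@pytest.mark.parametrize(
    "ic50, conc, hill, pct",
    [(100, 100, 1, 50.0), (25, 100, 1, 80.0), (1e9, 100, 1, 1e-5), (10, 0, 1, 0.0)],
)
def test_single_point_inhibition(ic50, conc, hill, pct):
    assert single_point_inhibition(ic50, conc, hill) == pytest.approx(pct, abs=1e-4)


@pytest.mark.parametrize("pct, conc, ic50", [(50, 100, 100), (80, 100, 25)])
def test_ic50_from_single_point(pct, conc, ic50):
    est = ic50_from_single_point(pct, conc)
    assert not est.censored
    assert est.value == pytest.approx(ic50)


def test_saturated_and_inactive_points_are_censored():
    assert ic50_from_single_point(100.0, 100).censor == "<"
    assert ic50_from_single_point(0.0, 100).censor == ">"
    assert ic50_from_single_point(-5.0, 100).censor == ">"


@given(pct=st.floats(min_value=0.1, max_value=99.9),
       conc=st.floats(min_value=1e-2, max_value=1e4),
       hill=st.floats(min_value=0.2, max_value=5))
def test_single_point_round_trip(pct, conc, hill):
    est = ic50_from_single_point(pct, conc, hill)
    assert single_point_inhibition(est.value, conc, hill) == pytest.approx(pct, rel=1e-9)


def test_read_assay_conditions(tmp_path):
    p = tmp_path / "cond.csv"
    p.write_text("kinase_id,atp_conc_uM,km_atp_uM\nMPS1,10,10\nAURKA,30,15\n")
    conds = read_assay_conditions(p)
    assert conds["MPS1"].atp_over_km == 1.0
    assert conds["AURKA"].atp_over_km == 2.0


def test_assay_condition_validation():
    with pytest.raises(ValueError):
        AssayCondition("X", atp_conc=-1, km_atp=5)
    with pytest.raises(ValueError):
        AssayCondition("X", atp_conc=1, km_atp=0)


def test_build_potency_table_full_pipeline():
    ic50 = pd.read_csv(io.StringIO(
        "compound_id,kinase_id,ic50_uM\n"
        "2,MPS1,189.4\n"       # halves to Ki 94.7 at [ATP]=Km
        "1,MPS1,>1000\n"       # censored bound
        "9,MPS1,256.4\n"       # compound without a heavy-atom count
    ))
    conds = {"MPS1": AssayCondition("MPS1", 10.0, 10.0)}
    warnings = []
    recs = build_potency_table(ic50, conds, {"2": 14, "1": 8}, warn=warnings.append)

    by_id = {r.compound_id: r for r in recs}
    assert by_id["2"].ki == pytest.approx(94.7)
    assert round_half_up(by_id["2"].le, 2) == 0.39
    assert by_id["2"].render_ki_le() == "94.7 (0.39)"

    assert by_id["1"].censored and by_id["1"].le is None and by_id["1"].pki is None
    assert by_id["1"].render_ki_le() == ">500 (-)"  # bound also Cheng-Prusoff scaled

    assert by_id["9"].le is None and not by_id["9"].censored
    assert warnings and "9" in warnings[0]

    frame = potency_records_frame(recs)
    assert list(frame.columns) == ["compound_id", "kinase_id", "ic50_uM",
                                   "ki_uM", "pki", "le", "censored"]
    assert frame["censored"].tolist() == [False, True, False]


def test_build_potency_table_unknown_kinase():
    ic50 = pd.DataFrame({"compound_id": ["2"], "kinase_id": ["NOPE"], "ic50_uM": [1.0]})
    with pytest.raises(KeyError):
        build_potency_table(ic50, {"MPS1": AssayCondition("MPS1", 10, 10)}, {})
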