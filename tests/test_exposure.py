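"""Fuzzy intake, hazard quotient/index, and carcinogenic risk."""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

import dustrisk as dr
from conftest import classical_intakes
from dustrisk.exposure import (
    ExposureScenario,
    ToxicityParameters,
    carcinogenic_risk,
    hazard_index,
    hazard_quotient,
    intake_dermal,
    intake_ingestion,
    intake_inhalation,
)
from dustrisk.fuzzy import AlphaCutInterval, TriangularFuzzyNumber, make_tfn


def crisp_scenario(IngR=200.0, InhR=7.5, BW=20.0, ED=6.0, EF=350.0,
                   AT_nc=2190.0, AT_ca=25550.0, SA=2800.0, SSAR=0.2,
                   ABS=0.001, PEF=1.36e9) -> ExposureScenario:
    return ExposureScenario(
        receptor="test",
        IngR=TriangularFuzzyNumber.crisp(IngR),
        InhR=TriangularFuzzyNumber.crisp(InhR),
        BW=TriangularFuzzyNumber.crisp(BW),
        ED=ED, EF=EF, AT_nc=AT_nc, AT_ca=AT_ca,
        SA=SA, SSAR=SSAR, ABS=ABS, PEF=PEF,
    )


def test_scenario_validation():
    with pytest.raises(ValueError, match="EF"):
        crisp_scenario(EF=400.0)
    with pytest.raises(ValueError, match="positive"):
        crisp_scenario(PEF=-1.0)
    with pytest.raises(ValueError, match="BW"):
        ExposureScenario(
            receptor="x",
            IngR=TriangularFuzzyNumber.crisp(100),
            InhR=TriangularFuzzyNumber.crisp(10),
            BW=make_tfn(0, 20, 30),
            ED=6, EF=350, AT_nc=2190, AT_ca=25550,
            SA=2800, SSAR=0.2, ABS=0.001, PEF=1.36e9,
        )


def test_toxicity_validation():
    with pytest.raises(ValueError, match="unknown pathway"):
        ToxicityParameters(rfd={"Cd": {"oral": 1e-3}}, sf={})
    with pytest.raises(ValueError, match="positive"):
        ToxicityParameters(rfd={}, sf={"As": {"ingestion": -1.5}})


# --- intakes ----------------------------------------------------------------


def test_ingestion_intake_degenerate_hand_value():
    """100 mg/kg · 6 yr · 350 d/yr · 200 mg/d / (20 kg · 2190 d) · 1e-6."""
    scn = crisp_scenario()
    res = intake_ingestion(TriangularFuzzyNumber.crisp(100.0), scn, alpha=0.9)
    expected = 100 * 6 * 350 * 200 / (20 * 2190) * 1e-6
    assert res.lo == pytest.approx(expected, rel=1e-12)
    assert res.hi == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(9.589e-4, rel=1e-3)


def test_inhalation_intake_degenerate_hand_value():
    scn = crisp_scenario()
    res = intake_inhalation(TriangularFuzzyNumber.crisp(100.0), scn, alpha=0.9)
    expected = 100 * 6 * 350 * 7.5 / (20 * 2190 * 1.36e9)
    assert res.lo == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(2.64e-8, rel=1e-2)


def test_zero_concentration_gives_zero_intake():
    scn = crisp_scenario()
    zero = TriangularFuzzyNumber.crisp(0.0)
    for fn in (intake_ingestion, intake_inhalation, intake_dermal):
        res = fn(zero, scn, alpha=0.9)
        assert (res.lo, res.hi) == (0.0, 0.0)


def test_fuzzy_body_weight_widens_interval_and_contains_crisp_value():
    crisp_val = 100 * 6 * 350 * 200 / (20 * 2190) * 1e-6
    fuzzy_scn = dataclasses.replace(crisp_scenario(), BW=make_tfn(16, 20, 24))
    res = intake_ingestion(TriangularFuzzyNumber.crisp(100.0), fuzzy_scn, alpha=0.9)
    assert res.lo < crisp_val < res.hi


def test_dermal_zero_absorption_gives_zero_intake():
    scn = crisp_scenario(ABS=0.0)
    res = intake_dermal(make_tfn(50, 100, 150), scn, 0.9)
    assert (res.lo, res.hi) == (0.0, 0.0)
    with pytest.raises(ValueError, match="ABS"):
        crisp_scenario(ABS=-0.1)


def test_dermal_homogeneity_in_skin_area():
    scn1 = crisp_scenario(SA=2800.0)
    scn2 = crisp_scenario(SA=5600.0)
    c = make_tfn(50, 100, 150)
    r1 = intake_dermal(c, scn1, 0.9)
    r2 = intake_dermal(c, scn2, 0.9)
    assert r2.lo == pytest.approx(2 * r1.lo, rel=1e-12)
    assert r2.hi == pytest.approx(2 * r1.hi, rel=1e-12)


def test_intake_linear_in_exposure_frequency():
    c = make_tfn(50, 100, 150)
    r1 = intake_ingestion(c, crisp_scenario(EF=175.0), 0.9)
    r2 = intake_ingestion(c, crisp_scenario(EF=350.0), 0.9)
    assert r2.lo == pytest.approx(2 * r1.lo, rel=1e-12)
    assert r2.hi == pytest.approx(2 * r1.hi, rel=1e-12)


def test_inhalation_vanishes_as_pef_grows():
    c = make_tfn(50, 100, 150)
    prev = None
    for pef in (1e8, 1e10, 1e12):
        r = intake_inhalation(c, crisp_scenario(PEF=pef), 0.9)
        if prev is not None:
            assert r.hi < prev.hi
        prev = r
    assert prev.hi < 1e-9


@given(
    c3=st.floats(100, 1000),
    bw1=st.floats(10, 20),
)
def test_monotonicity_in_numerator_and_body_weight(c3, bw1):
    """Growing the concentration maximum never shrinks the intake's right
    endpoint; growing the body-weight minimum never grows it."""
    base = crisp_scenario()
    c = make_tfn(50, 80, 100)
    c_wide = make_tfn(50, 80, max(100, c3))
    r0 = intake_ingestion(c, base, 0.9)
    r1 = intake_ingestion(c_wide, base, 0.9)
    assert r1.hi >= r0.hi * (1 - 1e-12)

    slim = dataclasses.replace(base, BW=make_tfn(min(bw1, 20), 20, 25))
    heavy = dataclasses.replace(base, BW=make_tfn(20, 20, 25))
    r_slim = intake_ingestion(c, slim, 0.9)
    r_heavy = intake_ingestion(c, heavy, 0.9)
    assert r_heavy.hi <= r_slim.hi * (1 + 1e-12)


# --- risk metrics -----------------------------------------------------------


def test_hazard_quotient_scales_by_reference_dose():
    hq = hazard_quotient(AlphaCutInterval(1e-4, 2e-4, 0.9), 1e-3)
    assert (hq.lo, hq.hi) == pytest.approx((0.1, 0.2))
    zero = hazard_quotient(AlphaCutInterval(0, 0, 0.9), 1e-3)
    assert (zero.lo, zero.hi) == (0.0, 0.0)
    with pytest.raises(ValueError, match="positive"):
        hazard_quotient(AlphaCutInterval(0, 1, 0.9), 0.0)


def test_hazard_index_is_componentwise_sum():
    hqs = [
        AlphaCutInterval(0.1, 0.2, 0.9),
        AlphaCutInterval(0.05, 0.3, 0.9),
        AlphaCutInterval(0.0, 0.1, 0.9),
    ]
    hi, below = hazard_index(hqs)
    assert hi.lo == pytest.approx(sum(h.lo for h in hqs))
    assert hi.hi == pytest.approx(sum(h.hi for h in hqs))
    assert below is True
    # permutation invariance
    hi_rev, _ = hazard_index(list(reversed(hqs)))
    assert (hi_rev.lo, hi_rev.hi) == pytest.approx((hi.lo, hi.hi))


def test_hazard_index_empty_sum_warns(caplog):
    with caplog.at_level("WARNING", logger="dustrisk.exposure"):
        hi, below = hazard_index([])
    assert (hi.lo, hi.hi) == (0.0, 0.0) and below
    assert any("empty" in rec.message for rec in caplog.records)


def test_carcinogenic_risk_scaling_and_pathway_total():
    cr = carcinogenic_risk(AlphaCutInterval(1e-6, 2e-6, 0.9), 1.5)
    assert (cr.lo, cr.hi) == pytest.approx((1.5e-6, 3e-6))
    zero = carcinogenic_risk(AlphaCutInterval(0, 0, 0.9), 1.5)
    mv = dr.classify_interval(zero)
    assert dr.assign_level(mv) == "I"


# --- pipeline ---------------------------------------------------------------


def _one_sample(c: float) -> dr.DustSample:
    return dr.DustSample(
        site="S1", season="winter", replicate=1,
        ct={"Cd": c * 2}, cdba={"Cd": c},
    )


def test_degenerate_pipeline_matches_scalar_oracle():
    """One sample + crisp scenario → every interval is the classical value."""
    scn = crisp_scenario()
    tox = ToxicityParameters(
        rfd={"Cd": {"ingestion": 1e-3, "inhalation": 1e-3, "dermal": 1e-5}},
        sf={"Cd": {"ingestion": 6.1}},
    )
    c = 37.5
    res = dr.run_risk_assessment(
        [_one_sample(c)], [scn], tox, grouping="pooled", alpha=0.9
    )[0]
    p = dict(IngR=200.0, InhR=7.5, BW=20.0, ED=6.0, EF=350.0,
             SA=2800.0, SSAR=0.2, ABS=0.001, PEF=1.36e9)
    oracle_nc = classical_intakes(c, p, scn.AT_nc)
    oracle_ca = classical_intakes(c, p, scn.AT_ca)
    for pathway in dr.PATHWAYS:
        got = res.intake_nc["Cd"][pathway]
        assert got.lo == pytest.approx(oracle_nc[pathway], rel=1e-12)
        assert got.hi == pytest.approx(oracle_nc[pathway], rel=1e-12)
    hq_expect = (oracle_nc["ingestion"] / 1e-3 + oracle_nc["inhalation"] / 1e-3
                 + oracle_nc["dermal"] / 1e-5)
    assert res.hi.lo == pytest.approx(hq_expect, rel=1e-12)
    assert res.cr_total["Cd"].hi == pytest.approx(
        oracle_ca["ingestion"] * 6.1, rel=1e-12
    )


def test_pipeline_interval_contains_mode_combination(samples34, default_scenarios,
                                                     default_tox):
    """Crisp evaluation at all modes lies inside every fuzzy interval."""
    fuzzy = dr.run_risk_assessment(
        samples34, list(default_scenarios.values()), default_tox,
        grouping="season", alpha=0.9,
    )
    crisp_scns = [
        dataclasses.replace(
            s,
            IngR=TriangularFuzzyNumber.crisp(s.IngR.a2),
            InhR=TriangularFuzzyNumber.crisp(s.InhR.a2),
            BW=TriangularFuzzyNumber.crisp(s.BW.a2),
        )
        for s in default_scenarios.values()
    ]
    crisp = dr.run_risk_assessment(
        samples34, crisp_scns, default_tox,
        grouping="season", alpha=0.9, fuzzy_concentration=False,
    )
    by_key = {(r.group, r.receptor): r for r in crisp}
    for rf in fuzzy:
        rc = by_key[(rf.group, rf.receptor)]
        assert rf.hi.lo <= rc.hi.lo * (1 + 1e-12)
        assert rc.hi.hi <= rf.hi.hi * (1 + 1e-12)
        for metal in rf.cr_total:
            assert rf.cr_total[metal].lo <= rc.cr_total[metal].lo * (1 + 1e-12)
            assert rc.cr_total[metal].hi <= rf.cr_total[metal].hi * (1 + 1e-12)


def test_hi_decomposes_into_hq_totals(samples34, default_scenarios, default_tox):
    res = dr.run_risk_assessment(
        samples34, [default_scenarios["child"]], default_tox,
        grouping="season", alpha=0.9,
    )
    for r in res:
        assert r.hi.lo == pytest.approx(sum(h.lo for h in r.hq_total.values()))
        assert r.hi.hi == pytest.approx(sum(h.hi for h in r.hq_total.values()))


def test_metals_without_toxicity_data_are_excluded(samples34, default_scenarios,
                                                   default_tox):
    res = dr.run_risk_assessment(
        samples34, [default_scenarios["adult"]], default_tox,
        grouping="pooled",
    )[0]
    assert "Pb" not in res.hq_total          # no reference dose for Pb
    assert set(res.cr_total) == {"Cd", "Ni", "As", "Pb"}  # slope factors only
    assert "Zn" not in res.cr_total


def test_pipeline_guards():
    scn = crisp_scenario()
    tox = ToxicityParameters(rfd={}, sf={})
    with pytest.raises(ValueError, match="empty sample"):
        dr.run_risk_assessment([], [scn], tox)
    with pytest.raises(ValueError, match="scenario"):
        dr.run_risk_assessment([_one_sample(1.0)], [], tox)
    with pytest.raises(ValueError, match="unknown grouping"):
        dr.run_risk_assessment([_one_sample(1.0)], [scn], tox, grouping="by-moon")
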