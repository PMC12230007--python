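"""Domain scorers against a literal decision-table oracle, plus properties."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

import icscore as ic
from icscore.scoring import InputError, MissingValueError

from conftest import favourable_record

FIXED = ic.FixedCutoffs()
NORMS = ic.NormTable(entries=(ic.NormBand("F", 60, 64, 12, -0.5, 5.0),))
MOCA = ic.MocaCutoffs(entries={"low": 22, "high": 26})


# --- independent oracles: the printed rule table, re-implemented literally ---

def oracle_vitality(hgs, sex, bmi, loss, appetite):
    pts = 0.0
    pts += 0.5 if hgs >= (27 if sex == "M" else 16) else 0.0
    pts += 0.5 if 22 <= bmi <= 27 else 0.0
    pts += 0.5 if loss < 3 else 0.0
    pts += 0.5 if not appetite else 0.0
    return pts


# all 16 flag states written out: (glasses, vis_diff, aid, hear_diff) -> points
ORACLE_SENSORY = {
    (False, False, False, False): 2,
    (False, False, False, True): 1,
    (False, False, True, False): 1,
    (False, False, True, True): 1,
    (False, True, False, False): 1,
    (False, True, False, True): 0,
    (False, True, True, False): 0,
    (False, True, True, True): 0,
    (True, False, False, False): 1,
    (True, False, False, True): 0,
    (True, False, True, False): 0,
    (True, False, True, True): 0,
    (True, True, False, False): 1,
    (True, True, False, True): 0,
    (True, True, True, False): 0,
    (True, True, True, True): 0,
}


def oracle_locomotion(tug, reps, reach, balance, reps_min, reach_lo, reach_hi):
    pts = 0.0
    pts += 0.5 if tug < 10 else 0.0
    pts += 0.5 if reps >= reps_min else 0.0
    pts += 0.5 if reach_lo <= reach <= reach_hi else 0.0
    pts += 0.5 if balance > 20 else 0.0
    return pts


def oracle_psychological(gds):
    if 0 <= gds <= 5:
        return 2.0
    if 6 <= gds <= 10:
        return 1.0
    return 0.0


def oracle_cognition(moca, cutoff):
    return 2.0 if moca >= cutoff else 0.0


# --- worked examples ---------------------------------------------------------

@pytest.mark.parametrize("hgs,sex,bmi,loss,app,expected", [
    (30, "M", 24.5, 0, False, 2.0),     # all four sub-rules pass
    (14, "F", 20, 4, True, 0.0),        # all four fail
    (16.0, "F", 27.0, 2.9, False, 2.0), # every rule exactly at its boundary
    (25, "M", 24.5, 0, False, 1.5),     # male handgrip below 27 kgf
])
def test_vitality_examples(hgs, sex, bmi, loss, app, expected):
    assert ic.score_vitality(hgs, sex, bmi, loss, app, FIXED) == expected


def test_vitality_unknown_sex_rejected():
    with pytest.raises(InputError):
        ic.score_vitality(30, "X", 24, 0, False, FIXED)


@pytest.mark.parametrize("flags,expected", [
    ((False, False, False, False), 2),
    ((True, True, True, True), 0),
    ((True, False, False, False), 1),  # glasses alone zeroes vision only
])
def test_sensory_examples(flags, expected):
    assert ic.score_sensory(*flags) == expected


@pytest.mark.parametrize("tug,reps,reach,bal,expected", [
    (9.0, 14, 3.0, 25, 2.0),
    (12, 10, -3.0, 15, 0.0),
    (9.5, 10, 3.0, 30, 1.5),
    (9.2, 10, -3.0, 15, 0.5),   # TUG alone passes
    (12, 10, -3.0, 25, 0.5),    # balance alone passes
])
def test_locomotion_examples(tug, reps, reach, bal, expected):
    got = ic.score_locomotion(tug, reps, reach, bal, 62, "F", FIXED, NORMS)
    assert got == expected


def test_locomotion_missing_norm_band_propagates():
    with pytest.raises(KeyError):
        ic.score_locomotion(9.0, 12, 0.0, 25, 70, "F", FIXED, NORMS)


@pytest.mark.parametrize("gds,expected", [(3, 2), (0, 2), (5, 2), (6, 1),
                                          (8, 1), (10, 1), (11, 0), (13, 0), (15, 0)])
def test_psychological_bands(gds, expected):
    assert ic.score_psychological(gds, FIXED) == expected


def test_psychological_out_of_range():
    with pytest.raises(InputError):
        ic.score_psychological(16, FIXED)


@pytest.mark.parametrize("moca,edu,expected", [
    (28, "high", 2.0), (20, "high", 0.0), (26, "high", 2.0), (25, "high", 0.0),
    (22, "low", 2.0), (21, "low", 0.0),
])
def test_cognition_threshold(moca, edu, expected):
    assert ic.score_cognition(moca, edu, MOCA) == expected


def test_composite_examples():
    top = ic.DomainScores(sensory=2, psychological=2, cognitive=2,
                          vitality=2.0, locomotion=2.0)
    assert ic.composite(top) == ic.CompositeIC(10.0, "high")
    zero = ic.DomainScores(0, 0, 0, 0.0, 0.0)
    assert ic.composite(zero) == ic.CompositeIC(0.0, "low")
    mid = ic.DomainScores(sensory=1, psychological=2, cognitive=2,
                          vitality=1.5, locomotion=1.5)
    assert ic.composite(mid) == ic.CompositeIC(8.0, "moderate")


@pytest.mark.parametrize("score,expected", [
    (0, "low"), (4, "low"), (4.5, "low"),
    (5, "moderate"), (8, "moderate"), (8.5, "moderate"),
    (9, "high"), (10, "high"),
])
def test_classify_composite_bands(score, expected):
    assert ic.classify_composite(score, FIXED) == expected


def test_classify_composite_rejects_out_of_range():
    for bad in (-0.5, 10.5, float("nan")):
        with pytest.raises(InputError):
            ic.classify_composite(bad, FIXED)


# --- decision-table oracle over an enumerated grid ---------------------------

def test_vitality_matches_decision_table():
    hgs_grid = [14, 15.9, 16, 16.1, 25, 26.9, 27, 27.1, 30]
    bmi_grid = [20, 21.9, 22, 22.1, 24.5, 26.9, 27, 27.1, 29]
    loss_grid = [0, 1, 2.9, 3, 3.1, 5]
    for hgs in hgs_grid:
        for sex in ("F", "M"):
            for bmi in bmi_grid:
                for loss in loss_grid:
                    for app in (False, True):
                        assert ic.score_vitality(hgs, sex, bmi, loss, app, FIXED) \
                            == oracle_vitality(hgs, sex, bmi, loss, app)


def test_sensory_matches_decision_table():
    for (g, vd, a, hd), expected in ORACLE_SENSORY.items():
        assert ic.score_sensory(g, vd, a, hd) == expected


def test_locomotion_matches_decision_table():
    tug_grid = [8, 9, 9.5, 9.99, 10, 10.01, 11, 12]
    reps_grid = [9, 10, 11, 12, 13, 14]
    reach_grid = [-1, -0.5, -0.4, 0, 2, 5.0, 5.01, 6]
    bal_grid = [10, 19, 20, 20.01, 20.5, 21, 22, 30]
    for tug in tug_grid:
        for reps in reps_grid:
            for reach in reach_grid:
                for bal in bal_grid:
                    got = ic.score_locomotion(tug, reps, reach, bal, 62, "F",
                                              FIXED, NORMS)
                    want = oracle_locomotion(tug, reps, reach, bal,
                                             12, -0.5, 5.0)
                    assert got == want, (tug, reps, reach, bal)


def test_psych_and_cognition_match_decision_table():
    for gds in range(16):
        assert ic.score_psychological(gds, FIXED) == oracle_psychological(gds)
    for cutoff, edu in ((22, "low"), (26, "high")):
        for moca in range(31):
            assert ic.score_cognition(moca, edu, MOCA) == oracle_cognition(moca, cutoff)


def test_composite_enumeration_sum_and_class():
    """Every reachable domain combination sums exactly and classifies once."""
    grid_half = (0, 0.5, 1, 1.5, 2)
    for s in (0, 1, 2):
        for p in (0, 1, 2):
            for c in (0, 2):
                for v in grid_half:
                    for l in grid_half:
                        comp = ic.composite(ic.DomainScores(s, p, c, v, l))
                        assert comp.score == s + p + c + v + l
                        assert comp.score * 2 == int(comp.score * 2)  # 0.5 grid
                        assert comp.category in ic.CATEGORIES


# --- properties --------------------------------------------------------------

def test_classifier_partitions_half_point_grid():
    cats = [ic.classify_composite(k / 2, FIXED) for k in range(21)]
    assert all(c in ic.CATEGORIES for c in cats)
    ranks = [ic.CATEGORIES.index(c) for c in cats]
    assert ranks == sorted(ranks)  # non-decreasing in score
    assert set(cats) == set(ic.CATEGORIES)


record_strategy = st.fixed_dictionaries({
    "hgs": st.floats(0, 50), "bmi": st.floats(15, 40),
    "weight_loss_3mo": st.floats(0, 8),
    "appetite_loss": st.booleans(), "wears_glasses": st.booleans(),
    "vision_difficulty": st.booleans(), "uses_hearing_aid": st.booleans(),
    "hearing_difficulty": st.booleans(),
    "tug": st.floats(4, 20), "chair_stand": st.integers(0, 25),
    "sit_reach": st.floats(-15, 15), "balance": st.floats(0, 60),
    "gds15": st.integers(0, 15), "moca": st.integers(0, 30),
    "sex": st.sampled_from(["F", "M"]),
})


def _total(raw, thresholds):
    rec = favourable_record(age=62.0, **raw)
    # the tiny fixture NORMS covers F only; use a two-sex table here
    cfg = ic.ThresholdConfig(
        fixed=FIXED,
        norms=ic.NormTable(entries=(
            ic.NormBand("F", 60, 64, 12, -0.5, 5.0),
            ic.NormBand("M", 60, 64, 14, -2.5, 4.0),
        )),
        moca=MOCA,
    )
    rec = dataclasses.replace(rec, education="high")
    _, comp = ic.score_record(rec, cfg)
    return comp.score


@settings(derandomize=True, max_examples=200, deadline=None)
@given(raw=record_strategy, which=st.sampled_from(
    ["hgs", "tug", "chair_stand", "balance", "gds15", "moca",
     "vision_difficulty", "wears_glasses"]))
def test_single_measure_improvement_never_lowers_composite(raw, which, thresholds):
    before = _total(raw, thresholds)
    improved = dict(raw)
    if which == "hgs":
        improved["hgs"] = raw["hgs"] + 5
    elif which == "tug":
        improved["tug"] = max(raw["tug"] - 3, 1)
    elif which == "chair_stand":
        improved["chair_stand"] = raw["chair_stand"] + 3
    elif which == "balance":
        improved["balance"] = raw["balance"] + 10
    elif which == "gds15":
        improved["gds15"] = max(raw["gds15"] - 4, 0)
    elif which == "moca":
        improved["moca"] = min(raw["moca"] + 4, 30)
    else:
        improved[which] = False
    assert _total(improved, thresholds) >= before


# --- score_record contract ---------------------------------------------------

def test_score_record_favourable_is_ten(thresholds):
    domains, comp = ic.score_record(favourable_record(), thresholds)
    assert domains == ic.DomainScores(2, 2, 2, 2.0, 2.0)
    assert comp == ic.CompositeIC(10.0, "high")


def test_score_record_deterministic(thresholds):
    rec = favourable_record(tug=10.5, gds15=7)
    assert ic.score_record(rec, thresholds) == ic.score_record(rec, thresholds)


def test_score_record_missing_field_named(thresholds):
    rec = favourable_record(gds15=float("nan"))
    with pytest.raises(MissingValueError, match="gds15"):
        ic.score_record(rec, thresholds)


def test_boundary_conventions(thresholds):
    """The continuous-scale tie rules: TUG 10 fails, balance 20 fails,
    20.5 passes, handgrip and MoCA at their cutoffs pass."""
    assert ic.score_locomotion(10.0, 14, 3.0, 25, 62, "F", FIXED, NORMS) == 1.5
    assert ic.score_locomotion(9.0, 14, 3.0, 20.0, 62, "F", FIXED, NORMS) == 1.5
    assert ic.score_locomotion(9.0, 14, 3.0, 20.5, 62, "F", FIXED, NORMS) == 2.0
    assert ic.score_vitality(16.0, "F", 24, 0, False, FIXED) == 2.0
    assert ic.score_cognition(26, "high", MOCA) == 2.0
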