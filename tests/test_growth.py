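"""Z-scores, SGA/EUGR classification and the growth reference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neogrowth.growth import (
    P10_Z_CUTOFF,
    GrowthReference,
    assess_growth,
    classify_eugr,
    classify_sga,
    default_reference,
    delta_zscore,
    max_weight_loss,
    value_from_z,
    zscore,
)


def lms_table(L):
    rows = []
    for ga in (210, 252):
        rows.append({"sex": "F", "ga_days": ga, "measure": "weight", "L": L, "M": 1500.0 + 5 * (ga - 210), "S": 0.12})
    return pd.DataFrame(rows)


def test_zscore_at_mean_and_one_sd():
    ref = default_reference()
    mean, sd = ref.params_at("M", 217, "weight")
    assert ref.zscore(mean, "M", 217, "weight") == pytest.approx(0.0)
    assert ref.zscore(mean + sd, "M", 217, "weight") == pytest.approx(1.0)


def test_lms_with_unit_L_matches_mean_sd():
    ref = GrowthReference(lms_table(L=1.0))
    M, S = 1500.0, 0.12
    value = 1300.0
    # with L=1 the LMS z reduces to (value/M - 1)/S == (value - M)/(M*S)
    assert ref.zscore(value, "F", 210, "weight") == pytest.approx((value - M) / (M * S))


def test_lms_L_zero_log_limit():
    ref = GrowthReference(lms_table(L=0.0))
    z = ref.zscore(1800.0, "F", 210, "weight")
    assert z == pytest.approx(np.log(1800.0 / 1500.0) / 0.12)
    assert ref.value_from_z(z, "F", 210, "weight") == pytest.approx(1800.0)


def test_lms_rejects_nonpositive_value():
    ref = GrowthReference(lms_table(L=0.5))
    with pytest.raises(ValueError):
        ref.zscore(0.0, "F", 210, "weight")


@given(z=st.floats(-3, 3), ga=st.floats(180, 290))
@settings(max_examples=50, deadline=None)
def test_roundtrip_value_from_z(z, ga):
    assert zscore(value_from_z(z, "F", ga, "weight"), "F", ga, "weight") == pytest.approx(z, abs=1e-9)


def test_zscore_strictly_increasing_in_value():
    zs = [zscore(w, "M", 224, "weight") for w in (1200, 1400, 1600)]
    assert zs == sorted(zs) and len(set(zs)) == 3


def test_mean_sd_scale_invariance():
    tbl = pd.DataFrame(
        [{"sex": "F", "ga_days": g, "measure": "weight", "mean": m, "sd": 0.1 * m}
         for g, m in ((210, 1400.0), (252, 2500.0))]
    )
    k = 2.5
    scaled = tbl.assign(mean=tbl["mean"] * k, sd=tbl["sd"] * k)
    z1 = GrowthReference(tbl).zscore(1500.0, "F", 230, "weight")
    z2 = GrowthReference(scaled).zscore(1500.0 * k, "F", 230, "weight")
    assert z1 == pytest.approx(z2)


def test_ga_outside_domain_raises():
    with pytest.raises(ValueError, match="domain"):
        zscore(1500, "M", 100, "weight")


def test_sga_cutoff_strict():
    assert not classify_sga(0.0)
    assert classify_sga(-1.30)
    assert not classify_sga(P10_Z_CUTOFF)  # boundary: strict <
    assert classify_sga(np.nextafter(P10_Z_CUTOFF, -np.inf))


def test_sga_monotone_heavier_never_flips_true():
    ref = default_reference()
    weights = np.linspace(900, 2500, 40)
    flags = [classify_sga(ref.zscore(w, "F", 217, "weight")) for w in weights]
    assert flags == sorted(flags, reverse=True)  # True...False, one switch


@pytest.mark.parametrize(
    "sga,below,expected",
    [(False, True, True), (True, True, False), (False, False, False), (True, False, False)],
)
def test_eugr_definition(sga, below, expected):
    assert classify_eugr(sga, below) is expected


def test_delta_zscore():
    assert delta_zscore(-0.17, -1.00) == pytest.approx(-0.83)
    assert delta_zscore(0.5, 0.5) == 0.0
    assert delta_zscore(0.0, 1.0) == 1.0


def test_max_weight_loss():
    assert max_weight_loss([1500, 1380, 1450], 1500) == pytest.approx(8.0)
    assert max_weight_loss([1510, 1600], 1500) == 0.0
    assert max_weight_loss([1500], 1500) == 0.0
    with pytest.raises(ValueError):
        max_weight_loss([1400], 0)


def test_assessment_invariants():
    a = assess_growth(1500.0, 1900.0, "F", 217, 252, weight_series_g=[1500, 1400, 1900])
    assert a.delta_z == pytest.approx(a.z_36 - a.z_birth)
    assert not (a.eugr and a.sga)
    if a.eugr:
        assert a.below_p10_at36
    assert a.max_weight_loss_pct == pytest.approx(100 * 100 / 1500)


def test_partition_identity_on_cohort(small_cohort):
    """below-P10-at-36 splits exactly into SGA-and-below plus EUGR."""
    ref = default_reference()
    n_below = n_sga_below = n_eugr = 0
    for r in small_cohort.records:
        a = assess_growth(r.birth_weight_g, r.weight36_g, r.sex, r.ga_days, r.pca36_days, ref)
        n_below += a.below_p10_at36
        n_sga_below += a.sga and a.below_p10_at36
        n_eugr += a.eugr
    assert n_below == n_sga_below + n_eugr
    assert n_below > 0  # the identity should not pass vacuously


def test_reference_csv_roundtrip(tmp_path):
    ref = default_reference()
    path = tmp_path / "ref.csv"
    ref.to_csv(path)
    ref2 = GrowthReference.from_csv(path)
    assert ref2.parameterization == "mean_sd"
    assert ref2.zscore(1500, "M", 224, "weight") == pytest.approx(
        ref.zscore(1500, "M", 224, "weight")
    )


def test_reference_validation():
    bad = pd.DataFrame(
        [{"sex": "F", "ga_days": 210, "measure": "weight", "mean": 1500.0, "sd": 0.0}]
    )
    with pytest.raises(ValueError, match="sd"):
        GrowthReference(bad)
    with pytest.raises(ValueError, match="mean/sd or L/M/S"):
        GrowthReference(pd.DataFrame([{"sex": "F", "ga_days": 1, "measure": "weight"}]))
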