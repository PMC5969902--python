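"""Closed-form model: Bell rates, state occupancies, routes, mean lengths."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from forminproc import (
    KBT_ROOM,
    SUBUNIT_SIZE_UM,
    Conditions,
    ForminRateParams,
    UnphysicalParameterError,
    bell_rate,
    dissociation_rate,
    elongation_rate,
    koff_force_family,
    mean_filament_length,
    p_open,
    profilin_occupancy,
)


@pytest.mark.parametrize("k0,delta,f,expected", [
    (0.1, 0.0, 5.0, 0.1),       # zero working distance: force-independent
    (0.1, 2.7, 0.0, 0.1),       # zero force: base rate
    (0.1, 2.7, 1.522, 0.1 * math.e),  # f*delta/kBT = 1 (within 4 digits)
])
def test_bell_rate_values(k0, delta, f, expected):
    assert bell_rate(k0, delta, f, kBT=4.11) == pytest.approx(expected, rel=1e-3)


def test_bell_rate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bell_rate(0.1, 2.7, math.nan)
    with pytest.raises(ValueError):
        bell_rate(0.1, 2.7, 1.0, kBT=0.0)
    with pytest.raises(ValueError):
        bell_rate(-0.1, 2.7, 1.0)
    with pytest.raises(UnphysicalParameterError):
        bell_rate(0.1, 2.7, 1e6)


@given(st.floats(0, 20), st.floats(0, 20))
def test_bell_rate_monotone_in_force(f1, f2):
    lo, hi = sorted([f1, f2])
    assert bell_rate(0.05, 1.3, lo) <= bell_rate(0.05, 1.3, hi)


def test_p_open_values(mdia1):
    assert p_open(0.0, mdia1) == pytest.approx(0.5)  # K_co = 1
    assert p_open(2.85, mdia1, kBT=4.11) == pytest.approx(0.867, abs=1e-3)
    assert p_open(200.0, mdia1) == pytest.approx(1.0)
    # tension favors the open state
    fs = np.linspace(0, 10, 30)
    po = [p_open(f, mdia1) for f in fs]
    assert np.all(np.diff(po) > 0)


def test_profilin_occupancy(mdia1):
    assert profilin_occupancy(Conditions(actin=1.0, profilin=0.0), mdia1) == (0.0, 0.0)
    pi_sol, pi_fh1 = profilin_occupancy(
        Conditions(actin=1.0, profilin=mdia1.K_PB), mdia1)
    assert pi_sol == pytest.approx(0.5)
    fh2 = mdia1.with_(has_FH1=False)
    _, pi_fh1 = profilin_occupancy(Conditions(actin=1.0, profilin=10.0), fh2)
    assert pi_fh1 == 0.0


def test_elongation_rate_limits(mdia1):
    assert elongation_rate(Conditions(actin=0.0), 0.0, mdia1) == 0.0
    # without profilin, FH1-FH2 elongates exactly like FH2
    c = Conditions(actin=1.0, profilin=0.0)
    fh2 = mdia1.with_(has_FH1=False)
    assert elongation_rate(c, 0.0, mdia1) == elongation_rate(c, 0.0, fh2)


def test_elongation_biphasic_in_profilin():
    p = ForminRateParams(k_on=10.0, K_co=1e-9, k_offO0=0.0, k_offT0=0.0,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0,
                         K_PB=50.0, fh1_boost_max=9.0, K_boost=1.0,
                         has_FH1=True)
    prof = np.linspace(0.0, 40.0, 161)
    v = np.array([elongation_rate(Conditions(actin=1.0, profilin=x), 0.0, p)
                  for x in prof])
    imax = int(np.argmax(v))
    assert 0 < imax < len(prof) - 1          # interior maximum
    assert v[imax] > v[0] and v[imax] > v[-1]


def test_dissociation_routes_sum_and_actin_zero(mdia1):
    pred = dissociation_rate(Conditions(actin=0.0, profilin=0.0), 0.0, mdia1)
    assert pred.k_off_transition_route == 0.0
    assert pred.k_off == pred.k_off_open_route
    pred1 = dissociation_rate(Conditions(actin=1.0, profilin=2.0), 1.5, mdia1)
    assert pred1.k_off == pytest.approx(
        pred1.k_off_open_route + pred1.k_off_transition_route)


def test_fh2_only_collapses_onto_elongation_rate(mdia1):
    """FH2-only: equal elongation rates imply (nearly) equal k_off.

    Matching v with and without profilin leaves the dominant transition
    route identical; the residual difference sits entirely in the small,
    profilin-gated open route.
    """
    fh2 = mdia1.with_(has_FH1=False)
    c_plain = Conditions(actin=1.0, profilin=0.0)
    prof = 10.0
    pi_sol = prof / (prof + fh2.K_PB)
    c_prof = Conditions(actin=1.0 / (1.0 - pi_sol), profilin=prof)
    pa = dissociation_rate(c_plain, 0.0, fh2)
    pb = dissociation_rate(c_prof, 0.0, fh2)
    assert pb.v_elong == pytest.approx(pa.v_elong, rel=1e-12)
    assert pb.k_off == pytest.approx(pa.k_off, rel=0.01)
    assert pb.k_off_transition_route == pytest.approx(
        pa.k_off_transition_route, rel=1e-12)


def test_profilin_protects_fh1_constructs(mdia1):
    """k_off falls with profilin while elongation still rises (FH1 present)."""
    prof = np.linspace(0.0, 5.0, 26)
    preds = [dissociation_rate(Conditions(actin=1.0, profilin=x), 0.0, mdia1)
             for x in prof]
    v = np.array([p.v_elong for p in preds])
    k = np.array([p.k_off for p in preds])
    assert np.all(np.diff(v) > 0)
    assert np.all(np.diff(k) < 0)


def test_no_universal_scaling_with_fh1(mdia1):
    """Equal v reached with vs without profilin gives different k_off."""
    c_plain = Conditions(actin=1.0, profilin=0.0)
    v_target = elongation_rate(c_plain, 0.0, mdia1)
    prof = 5.0
    v_unit = elongation_rate(Conditions(actin=1.0, profilin=prof), 0.0, mdia1)
    c_prof = Conditions(actin=v_target / v_unit, profilin=prof)
    pa = dissociation_rate(c_plain, 0.0, mdia1)
    pb = dissociation_rate(c_prof, 0.0, mdia1)
    assert pb.v_elong == pytest.approx(pa.v_elong, rel=1e-12)
    assert abs(pb.k_off - pa.k_off) / pa.k_off > 0.2


def test_fh2_flag_irrelevant_without_profilin(mdia1):
    fh2 = mdia1.with_(has_FH1=False)
    c = Conditions(actin=0.7, profilin=0.0)
    for f in (0.0, 2.0):
        pa = dissociation_rate(c, f, mdia1)
        pb = dissociation_rate(c, f, fh2)
        assert pa == pb


@given(st.floats(0.1, 5.0), st.floats(0.0, 8.0), st.floats(0.0, 6.0))
def test_koff_monotone_in_force(actin, f1, f2):
    p = ForminRateParams(k_on=15.0, K_co=2.0, k_offO0=1e-3, k_offT0=0.2,
                         k_decay=500.0, delta_O=2.0, delta_T=1.0)
    lo, hi = sorted([f1, f2])
    c = Conditions(actin=actin, profilin=0.0)
    assert dissociation_rate(c, lo, p).k_off <= dissociation_rate(c, hi, p).k_off * (1 + 1e-12)


def test_koff_affine_in_actin(mdia1):
    """At f=0 without profilin, k_off is affine in actin (route structure)."""
    c = lambda a: Conditions(actin=a, profilin=0.0)
    k = lambda a: dissociation_rate(c(a), 0.0, mdia1).k_off
    slope = k(2.0) - k(1.0)
    assert k(3.0) == pytest.approx(k(1.0) + 2 * slope, rel=1e-10)
    assert slope > 0


@given(st.floats(0.1, 4.0), st.floats(0.0, 20.0), st.floats(0.0, 5.0))
def test_mean_length_identity(actin, profilin, f):
    """L * k_off / v equals one subunit size for any parameter set."""
    p = ForminRateParams(k_on=20.0, K_co=1.0, k_offO0=1e-3, k_offT0=0.1,
                         k_decay=800.0, delta_O=2.7, delta_T=0.5,
                         fh1_boost_max=4.0, has_FH1=True)
    cond = Conditions(actin=actin, profilin=profilin)
    pred = dissociation_rate(cond, f, p)
    L = mean_filament_length(cond, f, p)
    if pred.v_elong > 0:
        assert L * pred.k_off / pred.v_elong == pytest.approx(SUBUNIT_SIZE_UM)


def test_mean_length_unit_conversion():
    # v = 1 subunit/s and k_off = 1/s gives 2.7 nm
    p = ForminRateParams(k_on=1.0, K_co=1e-12, k_offO0=1.0, k_offT0=0.0,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0)
    L = mean_filament_length(Conditions(actin=1.0), 0.0, p)
    assert L == pytest.approx(0.0027, rel=1e-9)


def test_mean_length_infinite_when_koff_zero():
    p = ForminRateParams(k_on=1.0, K_co=1.0, k_offO0=0.0, k_offT0=0.0,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0)
    assert mean_filament_length(Conditions(actin=1.0), 0.0, p) == math.inf


def test_mean_length_tenfold_per_3pN():
    """With delta = ln(10) kBT / 3 on the dominant route, L drops 10x per 3 pN."""
    delta = math.log(10.0) * KBT_ROOM / 3.0
    p = ForminRateParams(k_on=10.0, K_co=1e-9, k_offO0=1e-3, k_offT0=0.0,
                         k_decay=1.0, delta_O=delta, delta_T=0.0)
    c = Conditions(actin=1.0)
    for f in (0.0, 1.5):
        ratio = (mean_filament_length(c, f, p)
                 / mean_filament_length(c, f + 3.0, p))
        assert ratio == pytest.approx(10.0, rel=1e-9)


def test_mean_length_varies_moderately_with_actin(mdia1):
    """Doubling actin changes mean length by less than the factor 2 in v."""
    c1 = Conditions(actin=1.0, profilin=0.0)
    c2 = Conditions(actin=2.0, profilin=0.0)
    r = (mean_filament_length(c2, 0.0, mdia1)
         / mean_filament_length(c1, 0.0, mdia1))
    assert 0.5 < r < 2.0


class TestKoffForceFamily:
    f_grid = np.linspace(0.0, 7.0, 15)

    def test_open_route_sensitive_converges(self, mdia1, cond_1uM):
        p = mdia1.with_(delta_O=2.7, delta_T=0.0)
        fam = koff_force_family([0.3, 1.0, 2.0], self.f_grid, cond_1uM, p)
        assert fam.classification == "converging"
        assert fam.ratio_high < fam.ratio_low

    def test_transition_route_sensitive_stays_separated(self, mdia1, cond_1uM):
        p = mdia1.with_(delta_O=0.0, delta_T=2.7)
        fam = koff_force_family([0.3, 1.0, 2.0], self.f_grid, cond_1uM, p)
        assert fam.classification == "separated"
        assert fam.ratio_high >= fam.ratio_low

    def test_degenerate_grid_ties_to_separated(self, mdia1, cond_1uM):
        fam = koff_force_family([0.3, 1.0], [2.0], cond_1uM, mdia1)
        assert fam.ratio_low == fam.ratio_high
        assert fam.classification == "separated"

    def test_requires_two_concentrations(self, mdia1, cond_1uM):
        with pytest.raises(ValueError):
            koff_force_family([1.0], self.f_grid, cond_1uM, mdia1)


def test_params_validation():
    with pytest.raises(ValueError):
        ForminRateParams(k_on=-1.0, K_co=1.0, k_offO0=0.1, k_offT0=0.1,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0)
    with pytest.raises(ValueError):
        ForminRateParams(k_on=1.0, K_co=0.0, k_offO0=0.1, k_offT0=0.1,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0)
    # FH2-only normalizes the boost away
    p = ForminRateParams(k_on=1.0, K_co=1.0, k_offO0=0.1, k_offT0=0.1,
                         k_decay=1.0, delta_O=0.0, delta_T=0.0,
                         has_FH1=False, fh1_boost_max=7.0)
    assert p.fh1_boost_max == 0.0


def test_conditions_validation():
    with pytest.raises(ValueError):
        Conditions(actin=-0.1)
    with pytest.raises(ValueError):
        Conditions(actin=1.0, labeling_fraction=1.5)
    with pytest.raises(ValueError):
        Conditions(actin=1.0, kBT=0.0)


def test_predictions_table_schema(mdia1):
    from forminproc.model import predictions_table
    df = predictions_table({"mDia1": mdia1},
                           [Conditions(actin=1.0, profilin=2.0)], [0.0, 1.0])
    assert list(df.columns) == ["construct", "actin_uM", "profilin_uM",
                                "kcl_mM", "force_pN", "v_elong_sub_s",
                                "koff_s", "route_open_s", "route_transition_s"]
    assert np.allclose(df.koff_s, df.route_open_s + df.route_transition_s)
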