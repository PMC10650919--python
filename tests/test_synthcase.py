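"""Simulator correctness: closed forms, mass balance, phase structure, determinism."""

import numpy as np
import pytest

from doapred import synthcase as sc


def test_sample_patient_deterministic():
    a = sc.sample_patient(42)
    b = sc.sample_patient(42)
    assert a == b
    assert a != sc.sample_patient(43)


def test_sample_patient_null_shift_has_no_trend():
    cfg = {"ec50_prop_per_year": 0.0, "ec50_remi_per_year": 0.0, "ke0_prop_per_year": 0.0}
    ages = []
    ec50 = []
    for s in range(500):
        p = sc.sample_patient(s, cfg)
        ages.append(p.age)
        ec50.append(p.pd.EC50_prop)
    slope, se = _ols_slope(np.array(ages), np.array(ec50))
    assert abs(slope) < 3 * se


def test_sample_patient_declared_slope_recovered():
    cfg = {"ec50_prop_per_year": -0.01}
    ages, ec50 = [], []
    for s in range(1000):
        p = sc.sample_patient(s, cfg)
        ages.append(p.age)
        ec50.append(p.pd.EC50_prop)
    slope, se = _ols_slope(np.array(ages), np.array(ec50))
    assert abs(slope - (-0.01)) < 3 * se


def _ols_slope(x, y):
    x_ = x - x.mean()
    slope = (x_ * y).sum() / (x_**2).sum()
    resid = y - y.mean() - slope * x_
    se = np.sqrt(resid.var(ddof=2) / (x_**2).sum())
    return slope, se


def test_invalid_shift_slope_rejected():
    with pytest.raises(ValueError, match="non-positive"):
        sc.sample_patient(0, {"ec50_prop_per_year": -1.0})


class TestPK:
    pk = sc.PKParams(V1=5.0, V2=10.0, V3=100.0, k10=0.2, k12=0.1,
                     k21=0.05, k13=0.01, k31=0.002, ke0=0.4)

    def test_zero_infusion_all_zero(self):
        out = sc.simulate_drug_pk(self.pk, np.zeros(300))
        assert np.all(out["cp"] == 0) and np.all(out["ce"] == 0)

    def test_bolus_central_concentration(self):
        # 100 mg delivered in the first second ~ bolus: Cp(0+) ~ D/V1
        rates = np.zeros(600)
        rates[0] = 100.0
        out = sc.simulate_drug_pk(self.pk, rates)
        assert out["cp"][0] == pytest.approx(100.0 / 5.0, rel=5e-3)

    def test_one_compartment_closed_form(self):
        pk1 = sc.PKParams(V1=5.0, V2=1.0, V3=1.0, k10=0.2, k12=1e-12,
                          k21=1.0, k13=1e-12, k31=1.0, ke0=0.4)
        rates = np.zeros(601)
        rates[0] = 100.0  # bolus over 1 s
        out = sc.simulate_drug_pk(pk1, rates)
        k = 0.2 / 60.0  # per s
        for t_min in (1, 5, 10):
            t = t_min * 60
            # exact solution for a 1-s constant-rate input then decay
            cp_exact = (100.0 / 5.0) * (1 - np.exp(-k)) / k * np.exp(-k * (t - 1))
            assert out["cp"][t - 1] == pytest.approx(cp_exact, rel=1e-6)

    def test_mass_balance_exact(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(0, 2, size=900)
        out = sc.simulate_drug_pk(self.pk, rates)
        total = out["masses"].sum(axis=1) + out["eliminated"]
        np.testing.assert_allclose(total, out["infused"], rtol=1e-9, atol=1e-9)

    def test_effect_site_lags_plasma(self):
        rates = np.zeros(600)
        rates[0] = 100.0
        out = sc.simulate_drug_pk(self.pk, rates)
        assert out["ce"][5] < out["cp"][5]
        assert np.argmax(out["ce"]) > np.argmax(out["cp"])

    def test_coarse_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            sc.simulate_drug_pk(self.pk, np.zeros(10), dt=5.0)


class TestBIS:
    profile = sc.sample_patient(0)

    def test_zero_concentration_gives_e0(self):
        z = np.zeros(50)
        np.testing.assert_allclose(sc.simulate_bis(z, z, self.profile), self.profile.pd.E0)

    def test_hill_midpoint(self):
        pd_ = self.profile.pd
        ce_p = np.array([pd_.EC50_prop])  # U = 1
        bis = sc.simulate_bis(ce_p, np.zeros(1), self.profile)
        assert bis[0] == pytest.approx(pd_.E0 - pd_.Emax / 2)

    def test_hand_evaluated_surface(self):
        from dataclasses import replace
        prof = sc.PatientProfile(
            age=50, sex="male", height=170, weight=70,
            pk_prop=self.profile.pk_prop, pk_remi=self.profile.pk_remi,
            pd=replace(self.profile.pd, E0=95.0, Emax=70.0, EC50_prop=1.0,
                       EC50_remi=1.0, gamma=2.0),
        )
        # U = 3, gamma = 2 -> 95 - 70 * 9/10 = 32
        bis = sc.simulate_bis(np.array([3.0]), np.zeros(1), prof)
        assert bis[0] == pytest.approx(32.0, abs=1e-12)

    def test_monotone_in_each_drug(self):
        ce = np.linspace(0, 10, 50)
        b1 = sc.simulate_bis(ce, np.full(50, 2.0), self.profile)
        assert np.all(np.diff(b1) < 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sc.simulate_bis(np.zeros(3), np.zeros(4), self.profile)


class TestCorrupt:
    def _case(self, seed=5):
        p = sc.sample_patient(seed)
        proto = sc.default_protocol(p, np.random.default_rng(seed))
        return sc.simulate_case("c", p, proto)

    def test_identity_when_no_noise(self):
        case = self._case()
        out, meta = sc.corrupt(case, sc.NoiseConfig(), 0)
        np.testing.assert_array_equal(out.bis, case.bis)
        np.testing.assert_array_equal(out.prop_cum, case.prop_cum)
        assert meta["violation"] is None

    def test_single_glitch_single_decrease(self):
        case = self._case()
        out, meta = sc.corrupt(case, sc.NoiseConfig(glitch_count=1), 0)
        assert int((np.diff(out.prop_cum) < 0).sum()) == 1
        i = meta["glitches"][0]
        assert out.prop_cum[i] < out.prop_cum[i - 1]

    def test_long_gap_flagged(self):
        case = self._case()
        out, meta = sc.corrupt(case, sc.NoiseConfig(missing_gap_lengths=(301,)), 0)
        assert meta["violation"] == "long_gap"
        lo, ln = meta["gaps"][0]
        assert ln == 301 and np.isnan(out.bis[lo: lo + 301]).all()

    def test_gap_longer_than_record_rejected(self):
        case = self._case()
        with pytest.raises(ValueError, match="gap"):
            sc.corrupt(case, sc.NoiseConfig(missing_gap_lengths=(10_000,)), 0)


class TestCohort:
    def test_single_clean_case_phases(self):
        cases, metas = sc.generate_cohort(1, rng_seed=11)
        case = cases[0]
        b = case.bis
        start = case.infusion_start
        assert b[start] > 80  # awake at induction
        maint = np.nanmean(b[start + 600: case.infusion_stop - 60])
        assert maint < 60  # induction drop to a plateau
        assert np.nanmean(b[-30:]) > maint + 5  # recovery rise after stop

    def test_reproducible(self):
        a, _ = sc.generate_cohort(3, rng_seed=7)
        b, _ = sc.generate_cohort(3, rng_seed=7)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.bis, cb.bis)
            np.testing.assert_array_equal(ca.prop_cum, cb.prop_cum)

    def test_planted_violation_metadata(self):
        menu = {
            0: sc.NoiseConfig(start_bis_override=70.0),
            2: sc.NoiseConfig(missing_gap_lengths=(320,)),
            4: sc.NoiseConfig(first_bis_delay=120),
        }
        _, metas = sc.generate_cohort(5, rng_seed=3, noise_menu=menu)
        assert [m["violation"] for m in metas] == [
            "start_bis", None, "long_gap", None, "dose_before_bis"]
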