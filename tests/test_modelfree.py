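"""Model-free machinery: spectral density, rates, tau_m, fits, summaries."""

import math

import numpy as np
import pytest

from allodyn.core_io import ResidueRange
from allodyn.modelfree import (
    DynamicsParams,
    SpinParameters,
    estimate_tm,
    fit_dataset,
    fit_residue,
    predict_rates,
    s2_threshold,
    spectral_density,
)
from allodyn.synthetic import RelaxSpec, flat_profile_truth, generate_relaxation

SPIN_500 = SpinParameters(field_mhz=500.0)


# --- independent oracle (coded from the standard expressions, scalar math) ---

def oracle_j(omega, s2, tm_s, te_s, sf2=1.0):
    j = s2 * tm_s / (1.0 + (omega * tm_s) ** 2)
    if te_s > 0.0 and sf2 - s2 > 0.0:
        tp = 1.0 / (1.0 / tm_s + 1.0 / te_s)
        j += (sf2 - s2) * tp / (1.0 + (omega * tp) ** 2)
    return 0.4 * j


def oracle_rates(s2, tm_ns, te_ps, rex, field_mhz, rnh=1.02, csa=-172.0):
    mu0_4pi, hbar = 1e-7, 1.054571817e-34
    gh, gn = 2.6752218744e8, 2.71261804e7  # magnitudes
    wh = 2.0 * math.pi * field_mhz * 1e6
    wn = wh * gn / gh
    d = mu0_4pi * hbar * gh * gn / (rnh * 1e-10) ** 3
    c = abs(csa) * 1e-6 * wn / math.sqrt(3.0)
    tm, te = tm_ns * 1e-9, te_ps * 1e-12

    def j(w):
        return oracle_j(w, s2, tm, te)

    r1 = (d * d / 4.0) * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c * c * j(wn)
    r2 = (d * d / 8.0) * (4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn)) \
        + (c * c / 6.0) * (4 * j(0) + 3 * j(wn)) + rex
    noe = 1.0 - (gh / gn) * (d * d / 4.0) * (6 * j(wh + wn) - j(wh - wn)) / r1
    return r1, r2, noe


class TestSpectralDensity:
    def test_rigid_limit_collapses_to_single_lorentzian(self):
        p = DynamicsParams(model="M2", S2=1.0, tau_e=100.0, tau_m=8.0)
        tm = 8e-9
        for w in (0.0, 1e8, 5e8):
            assert spectral_density(p, w) == pytest.approx(
                0.4 * tm / (1 + (w * tm) ** 2), rel=1e-14)

    def test_zero_frequency_rigid_value(self):
        p = DynamicsParams(S2=1.0, tau_m=8.0)
        assert spectral_density(p, 0.0) == pytest.approx(0.4 * 8e-9, rel=1e-15)

    def test_matches_independent_oracle(self):
        p = DynamicsParams(model="M2", S2=0.85, tau_e=50.0, tau_m=8.0)
        wn = SPIN_500.omega_n
        for w in (0.0, wn, 3.1 * wn):
            assert spectral_density(p, w) == pytest.approx(
                oracle_j(w, 0.85, 8e-9, 50e-12), rel=1e-12)

    def test_monotone_nonincreasing_in_frequency_without_internal_motion(self):
        p = DynamicsParams(S2=0.7, tau_m=10.0)
        ws = np.linspace(0, 5e9, 200)
        j = spectral_density(p, ws)
        assert np.all(np.diff(j) <= 0)


class TestPredictRates:
    def test_matches_independent_oracle(self):
        p = DynamicsParams(model="M2", S2=0.85, tau_e=50.0, tau_m=8.0)
        got = predict_rates(p, SPIN_500)
        want = oracle_rates(0.85, 8.0, 50.0, 0.0, 500.0)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-9)

    def test_rex_is_purely_additive_to_r2(self):
        base = DynamicsParams(model="M3", S2=0.85, Rex=0.0, tau_m=8.0)
        bumped = DynamicsParams(model="M3", S2=0.85, Rex=5.0, tau_m=8.0)
        r1a, r2a, noea = predict_rates(base, SPIN_500)
        r1b, r2b, noeb = predict_rates(bumped, SPIN_500)
        assert r2b - r2a == pytest.approx(5.0, abs=1e-12)
        assert r1b == r1a and noeb == noea

    def test_model_nesting_at_zero_tau_e(self):
        m1 = DynamicsParams(model="M1", S2=0.8, tau_m=8.0)
        m2 = DynamicsParams(model="M2", S2=0.8, tau_e=0.0, tau_m=8.0)
        assert predict_rates(m1, SPIN_500) == predict_rates(m2, SPIN_500)

    @pytest.mark.parametrize("s2,te", [(0.9, 30.0), (0.6, 200.0), (0.3, 800.0)])
    def test_noe_never_exceeds_rigid_limit(self, s2, te):
        rigid_noe = predict_rates(DynamicsParams(S2=1.0, tau_m=8.0), SPIN_500)[2]
        p = DynamicsParams(model="M2", S2=s2, tau_e=te, tau_m=8.0)
        assert predict_rates(p, SPIN_500)[2] <= rigid_noe + 1e-12

    def test_axial_with_unit_ratio_reduces_to_isotropic(self):
        iso = DynamicsParams(model="M2", S2=0.85, tau_e=50.0, tau_m=8.0)
        ax = DynamicsParams(model="M2", S2=0.85, tau_e=50.0, tau_m=8.0,
                            diffusion="axial", d_ratio=1.0)
        for a, b in zip(predict_rates(iso, SPIN_500),
                        predict_rates(ax, SPIN_500, angle=0.7)):
            assert abs(a - b) < 1e-9


class TestEstimateTm:
    def test_noise_free_recovery(self):
        # S2-only scaling cancels in R2/R1, so recovery is essentially exact
        truth = flat_profile_truth(range(30, 80), s2=0.85, tau_m=8.0, tau_e=0.0)
        ds = generate_relaxation(RelaxSpec(truth=truth, noise={}, seed=0))
        assert estimate_tm(ds) == pytest.approx(8.0, abs=0.05)

    def test_noisy_recovery_within_three_percent(self):
        truth = flat_profile_truth(range(30, 80), s2=0.85, tau_m=8.0, tau_e=50.0)
        hits = 0
        for seed in range(20):
            ds = generate_relaxation(RelaxSpec(truth=truth, seed=seed))
            if abs(estimate_tm(ds) - 8.0) / 8.0 <= 0.03:
                hits += 1
        assert hits >= 18

    def test_too_few_rigid_residues_is_an_error(self):
        truth = flat_profile_truth(range(1, 4), s2=0.85, tau_m=8.0)
        ds = generate_relaxation(RelaxSpec(truth=truth, noise={}, seed=0))
        with pytest.raises(ValueError, match="tau_m|rigid"):
            estimate_tm(ds)


class TestFitResidue:
    def _record(self, p, noise=None, seed=0):
        spec = RelaxSpec(truth=((1, p),), noise=noise or {}, seed=seed,
                         include_r1rho=False)
        row = generate_relaxation(spec).data.iloc[0]
        return {k: row[k] for k in
                ("residue", "R1", "R2", "NOE", "R1_err", "R2_err", "NOE_err")}

    def test_m1_round_trip_selects_m1(self):
        p = DynamicsParams(model="M1", S2=0.9, tau_m=8.0)
        fit = fit_residue(self._record(p), 8.0, SPIN_500)
        assert fit.model == "M1"
        assert fit.params.S2 == pytest.approx(0.9, abs=1e-3)

    def test_m3_round_trip_recovers_rex(self):
        p = DynamicsParams(model="M3", S2=0.85, Rex=4.0, tau_m=8.0)
        fit = fit_residue(self._record(p), 8.0, SPIN_500)
        assert fit.model in ("M3", "M4")  # M3 is nested in M4
        assert fit.params.S2 == pytest.approx(0.85, abs=1e-3)
        assert fit.params.Rex == pytest.approx(4.0, abs=0.1)

    def test_noisy_m2_recovery_is_unbiased(self):
        p = DynamicsParams(model="M2", S2=0.8, tau_e=50.0, tau_m=8.0)
        noise = {"R1": 0.02, "R2": 0.02, "NOE": 0.03}
        s2 = [fit_residue(self._record(p, noise=noise, seed=s), 8.0, SPIN_500).params.S2
              for s in range(20)]
        assert abs(np.mean(s2) - 0.8) < 0.02

    def test_chi2_respects_model_nesting(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = DynamicsParams(model="M4", S2=rng.uniform(0.5, 0.95),
                               tau_e=rng.uniform(10, 300),
                               Rex=rng.uniform(0, 5), tau_m=8.0)
            noise = {"R1": 0.02, "R2": 0.02, "NOE": 0.03}
            fit = fit_residue(self._record(p, noise=noise, seed=rng.integers(1 << 31)),
                              8.0, SPIN_500)
            c = fit.chi2_by_model
            tol = 1e-6
            assert c["M4"] <= c["M2"] + tol <= c["M1"] + 2 * tol
            assert c["M4"] <= c["M3"] + tol

    def test_missing_rates_leave_residue_unfit(self):
        fit = fit_residue({"residue": 5, "R1": float("nan"), "R2": 12.0,
                           "NOE": 0.8}, 8.0, SPIN_500)
        assert not fit.converged
        assert fit.model == "none"

    def test_ftest_criterion_also_recovers_exchange(self):
        p = DynamicsParams(model="M3", S2=0.85, Rex=4.0, tau_m=8.0)
        fit = fit_residue(self._record(p), 8.0, SPIN_500, criterion="ftest")
        assert fit.params.Rex == pytest.approx(4.0, abs=0.1)


class TestFitDataset:
    def test_flexible_tail_and_core_are_separated(self):
        ids = list(range(30, 100))
        flexible = {rid: 0.3 for rid in range(30, 40)}
        truth = flat_profile_truth(ids, s2=0.8, tau_m=8.0, tau_e=50.0,
                                   flexible=flexible)
        ds = generate_relaxation(RelaxSpec(truth=truth, seed=2))
        fit = fit_dataset(ds, ResidueRange(30, 99), tau_m=8.0)
        by_res = {f.residue: f.params.S2 for f in fit.residues if f.converged}
        tail = np.mean([by_res[r] for r in range(30, 40)])
        core = np.mean([by_res[r] for r in range(40, 100)])
        assert abs(tail - 0.3) < 0.03 and abs(core - 0.8) < 0.03
        assert set(fit.flexible_residues) == set(range(30, 40))

    def test_summary_is_deterministic(self):
        truth = flat_profile_truth(range(30, 60), s2=0.85, tau_m=8.0, tau_e=50.0)
        ds = generate_relaxation(RelaxSpec(truth=truth, seed=3))
        a = fit_dataset(ds, ResidueRange(30, 59))
        b = fit_dataset(ds, ResidueRange(30, 59))
        assert (a.s2_mean, a.s2_sd, a.tau_m) == (b.s2_mean, b.s2_sd, b.tau_m)

    def test_empty_range_intersection_is_an_error(self):
        truth = flat_profile_truth(range(30, 60), tau_m=8.0)
        ds = generate_relaxation(RelaxSpec(truth=truth, noise={}, seed=0))
        with pytest.raises(ValueError, match="no residues"):
            fit_dataset(ds, ResidueRange(200, 250))


class TestS2Threshold:
    def test_printed_summary_arithmetic(self):
        # mean 0.79, SD 0.13, two SDs below the mean
        assert s2_threshold(0.79, 0.13, 2.0) == pytest.approx(0.53)

    def test_degenerate_multipliers(self):
        assert s2_threshold(0.79, 0.13, 0.0) == 0.79
        assert s2_threshold(0.8, 0.0, 5.0) == 0.8
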