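"""CSP arithmetic, global Kd fitting, intensity titrations, competition model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from fragscreen.titration import (
    CSPCurve,
    HSQCPeak,
    IntensityTitration,
    analyze_intensity_titration,
    bound_fraction,
    competition_model,
    csp,
    fit_kd_global,
)
from fragscreen.synthetic import make_intensity_titration, make_titration

RATIOS = (0.1, 0.25, 0.5, 1.0, 2.0, 5.0)


class TestCsp:
    def test_no_shift_is_zero(self):
        a = HSQCPeak("D67", 8.0, 120.0)
        assert csp(a, a) == 0.0

    def test_nitrogen_scaled_by_five(self):
        ref = HSQCPeak("D67", 8.0, 120.0)
        obs = HSQCPeak("D67", 8.0, 120.5)
        assert csp(ref, obs) == pytest.approx(0.1)

    def test_combined_shift(self):
        ref = HSQCPeak("A61", 8.00, 120.00)
        obs = HSQCPeak("A61", 8.03, 120.20)
        assert csp(ref, obs) == pytest.approx(0.05)  # sqrt(0.0009 + 0.0016)

    def test_residue_mismatch_rejected(self):
        with pytest.raises(ValueError):
            csp(HSQCPeak("A61", 8.0, 120.0), HSQCPeak("D67", 8.0, 120.0))

    @settings(max_examples=40, derandomize=True)
    @given(dh=st.floats(-0.5, 0.5), dn=st.floats(-3.0, 3.0))
    def test_nonnegative_and_sign_symmetric(self, dh, dn):
        ref = HSQCPeak("r", 8.0, 120.0)
        plus = HSQCPeak("r", 8.0 + dh, 120.0 + dn)
        minus = HSQCPeak("r", 8.0 - dh, 120.0 - dn)
        assert csp(ref, plus) >= 0
        assert csp(ref, plus) == pytest.approx(csp(ref, minus))
        if dn == 0:
            assert csp(ref, plus) == pytest.approx(abs(dh))


class TestBoundFraction:
    def test_monotone_in_ligand_and_kd(self):
        r = np.linspace(0.1, 5, 30)
        fb = bound_fraction(r, 0.5, 0.2)
        assert np.all(np.diff(fb) > 0)
        fb_weak = bound_fraction(r, 0.5, 1.0)
        assert np.all(fb_weak < fb)

    def test_limits(self):
        assert bound_fraction(0.0, 0.5, 0.2) == 0.0
        assert bound_fraction(50.0, 0.5, 1e-9) == pytest.approx(1.0, abs=1e-6)


class TestFitKdGlobal:
    DDMAX = {"A61": 0.05, "D65": 0.08, "D67": 0.11, "peak_NA1": 0.06}

    def test_noise_free_recovery_within_one_percent(self):
        curves = make_titration(0.2, 0.5, self.DDMAX, ratios=RATIOS)
        fit = fit_kd_global(curves, 0.5)
        assert fit.kd == pytest.approx(0.2, rel=0.01)
        for res, amp in self.DDMAX.items():
            assert fit.per_residue_ddmax[res] == pytest.approx(amp, rel=0.01)
        assert fit.residual_rms < 1e-6

    def test_median_error_under_proportional_noise(self):
        errs = []
        for seed in range(100):
            curves = make_titration(0.2, 0.5, self.DDMAX, ratios=RATIOS,
                                    noise_frac=0.05, seed=seed)
            fit = fit_kd_global(curves, 0.5)
            errs.append(abs(fit.kd - 0.2) / 0.2)
        assert np.median(errs) <= 0.15

    def test_kd_scales_with_truth(self):
        for kd in (0.05, 0.5):
            curves = make_titration(kd, 0.5, self.DDMAX, ratios=RATIOS)
            assert fit_kd_global(curves, 0.5).kd == pytest.approx(kd, rel=0.01)

    def test_saturated_curves_flagged(self):
        # constant CSP at ddmax for every ratio: no information below full
        # saturation, the fit runs to its lower bound and is flagged
        curves = [CSPCurve("r1", [(r, 0.1) for r in RATIOS])]
        fit = fit_kd_global(curves, 0.5)
        assert "saturated" in fit.flags

    def test_all_zero_curves_rejected(self):
        curves = [CSPCurve("r1", [(r, 0.0) for r in RATIOS])]
        with pytest.raises(ValueError, match="no perturbation"):
            fit_kd_global(curves, 0.5)

    def test_short_curves_rejected(self):
        with pytest.raises(ValueError):
            fit_kd_global([CSPCurve("r1", [(0.5, 0.01), (1.0, 0.02)])], 0.5)


class TestIntensityTitration:
    def test_normalization_anchor_enforced(self):
        with pytest.raises(ValueError, match="normaliz"):
            IntensityTitration("control", [(0.0, {"p1": 0.9}), (0.5, {"p1": 0.5})])

    def test_missing_zero_point_rejected(self):
        with pytest.raises(ValueError):
            IntensityTitration("control", [(0.5, {"p1": 0.5})])

    def test_infinitely_weak_binding_keeps_intensity_at_one(self):
        t = make_intensity_titration(1e9, 0.2, n_residues=5)
        res = analyze_intensity_titration(t, 0.2)
        assert all(abs(v - 1.0) < 1e-6 for v in res["free_fraction"].values())

    def test_kd_recovered_within_factor_two_over_noisy_seeds(self):
        # 5 uM partner affinity at 0.2 mM protein: identifiability is weak
        # when the protein is far above Kd, hence the wide tolerance
        ratios = []
        for seed in range(50):
            t = make_intensity_titration(0.005, 0.2, noise_frac=0.02, seed=seed)
            res = analyze_intensity_titration(t, 0.2)
            ratios.append(res["kd"] / 0.005)
        assert all(0.5 <= r <= 2.0 for r in ratios)

    def test_low_intensity_residues_excluded(self):
        t = make_intensity_titration(0.005, 0.2, n_residues=6, seed=1)
        # push three residues below the 3x noise floor at the last point
        ratio, intens = t.points[-1]
        for res in list(intens)[:3]:
            intens[res] = 0.01
        t.noise_sd = 0.02
        res = analyze_intensity_titration(t, 0.2, k_noise=3.0)
        assert res["n_residues"] == 3 and len(res["excluded"]) == 3

    def test_too_few_usable_residues_is_an_error(self):
        t = make_intensity_titration(0.005, 0.2, n_residues=2, seed=1)
        with pytest.raises(ValueError, match=">= 3"):
            analyze_intensity_titration(t, 0.2)


def brute_force_competition(kd_g, kd_l, P, G, L, n=2001, rounds=14):
    """Independent oracle: grid search over the two bound-species concentrations.

    Scans (PG, PL) on a shrinking 2-D grid and keeps the point that best
    satisfies both mass-action laws; no root finder involved.
    """
    lo_pg, hi_pg = 0.0, min(P, G)
    lo_pl, hi_pl = 0.0, min(P, L) if L > 0 else 0.0
    m = int(np.sqrt(n))
    pg, pl = 0.0, 0.0
    for _ in range(rounds):
        pgs = np.linspace(lo_pg, hi_pg, m)
        pls = np.linspace(lo_pl, hi_pl, m) if hi_pl > 0 else np.array([0.0])
        PG, PL = np.meshgrid(pgs, pls, indexing="ij")
        pf = P - PG - PL
        bad = pf < 0
        # mass-action residuals of both binding equilibria
        r1 = pf * (G - PG) - kd_g * PG
        r2 = pf * (L - PL) - kd_l * PL
        err = np.where(bad, np.inf, np.abs(r1) / kd_g + np.abs(r2) / max(kd_l, 1e-30))
        i, j = np.unravel_index(np.argmin(err), err.shape)
        pg, pl = float(pgs[i]), float(pls[j] if hi_pl > 0 else 0.0)
        # keep a generous window: the argmin in one dimension is biased by
        # coarseness in the other, so shrinking too fast loses the root
        span_pg = (hi_pg - lo_pg) / m * 4
        lo_pg, hi_pg = max(0.0, pg - span_pg), min(min(P, G), pg + span_pg)
        if hi_pl > 0:
            span_pl = (hi_pl - lo_pl) / m * 4
            lo_pl, hi_pl = max(0.0, pl - span_pl), min(min(P, L), pl + span_pl)
    return {"P_free": (P - pg - pl) / P, "PG": pg / P, "PL": pl / P}


class TestCompetitionModel:
    # native-gel conditions: DH 37.5 uM, RhoA 30 uM, Kd(complex) ~5 uM,
    # Kd(ligand) 0.11 mM
    KD_G, KD_L, P, G = 0.005, 0.11, 0.03, 0.0375

    def test_no_ligand_reduces_to_two_species_depletion(self):
        out = competition_model(self.KD_G, self.KD_L, self.P, self.G, 0.0)
        assert out["PL"] == 0.0
        # closed-form two-species bound fraction
        s = self.P + self.G + self.KD_G
        pg = (s - math.sqrt(s * s - 4 * self.P * self.G)) / 2
        assert out["PG"] == pytest.approx(pg / self.P, rel=1e-9)

    def test_infinitely_weak_ligand_binds_nothing(self):
        out = competition_model(self.KD_G, 1e12, self.P, self.G, 0.375)
        assert out["PL"] == pytest.approx(0.0, abs=1e-12)

    def test_complex_fraction_strictly_decreasing_in_ligand(self):
        sweep = np.linspace(0.0, 10 * self.G, 25)
        pg = [competition_model(self.KD_G, self.KD_L, self.P, self.G, L)["PG"]
              for L in sweep]
        assert all(b < a for a, b in zip(pg, pg[1:]))

    def test_matches_brute_force_solver(self):
        for L in (0.01, 0.1, 0.375, 1.0):
            ours = competition_model(self.KD_G, self.KD_L, self.P, self.G, L)
            oracle = brute_force_competition(self.KD_G, self.KD_L, self.P, self.G, L)
            for key in ("P_free", "PG", "PL"):
                assert ours[key] == pytest.approx(oracle[key], abs=1e-6)

    def test_mass_conservation(self):
        out = competition_model(self.KD_G, self.KD_L, self.P, self.G, 0.375)
        p_total = (out["P_free"] + out["PG"] + out["PL"]) * self.P
        assert p_total == pytest.approx(self.P, rel=1e-9)
        g_total = out["G_free"] * self.G + out["PG"] * self.P
        assert g_total == pytest.approx(self.G, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            competition_model(0.0, self.KD_L, self.P, self.G, 0.1)
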