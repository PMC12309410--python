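"""Enrichment factors, Eu anomaly, REE summaries, C/N, salt correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seepflux import (
    cn_ratios,
    compute_indices,
    enrichment_factor,
    eu_anomaly,
    linear_r2,
    ree_summary,
    salt_correct,
    summarize_isotopes,
)
from seepflux.refdata import REE_ELEMENTS, Constants
from seepflux.synthetic import GUAYMAS_DEMO, make_sediment


class TestEnrichmentFactor:
    def test_crustal_ratio_gives_unity(self, ucc):
        assert enrichment_factor(ucc["Ni"], ucc["Al"], "Ni", ucc) == pytest.approx(1.0)

    def test_hand_arithmetic(self, ucc):
        # (10/40000)/(2/80000) = 10 for a reference with X=2, Al=80000
        from seepflux.refdata import ReferenceComposition
        ref = ReferenceComposition("UCC", {"Al": 80000.0, "Ni": 2.0})
        assert enrichment_factor(10.0, 40000.0, "Ni", ref) == pytest.approx(10.0)

    def test_silver_anomaly_back_solved_al(self, ucc):
        """EF(Ag)=9368 at Ag=120 ppm implies sample Al ~ 1.97 wt%.

        Brute-force inversion over a fine Al grid confirms the algebraic
        back-solve, then the forward EF at that Al reproduces the anomaly.
        """
        target = 9368.0
        al_grid = np.linspace(5.0e3, 8.0e4, 300001)
        efs = np.array([(120.0 / al) / (ucc["Ag"] / ucc["Al"]) for al in al_grid])
        al_best = al_grid[np.argmin(np.abs(efs - target))]
        assert al_best == pytest.approx(1.97e4, rel=0.01)
        assert enrichment_factor(120.0, al_best, "Ag", ucc) == pytest.approx(target, rel=1e-3)

    def test_zero_al_rejected(self, ucc):
        with pytest.raises(ZeroDivisionError):
            enrichment_factor(1.0, 0.0, "Ni", ucc)

    def test_absent_element_rejected(self, ucc):
        with pytest.raises(KeyError):
            enrichment_factor(1.0, 1.0, "Tc", ucc)

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3))
    def test_dilution_invariance(self, ucc, scale):
        base = enrichment_factor(10.0, 40000.0, "Ni", ucc)
        assert enrichment_factor(10.0 * scale, 40000.0 * scale, "Ni", ucc) \
            == pytest.approx(base, rel=1e-9)


class TestEuAnomaly:
    def test_flat_shale_pattern_is_unity(self, paas):
        assert eu_anomaly(paas["Eu"], paas["Sm"], paas["Gd"], paas) == pytest.approx(1.0)

    def test_hand_arithmetic(self, paas):
        # SN values Eu=2, Sm=1, Gd=1 -> 2*2/(1+1) = 2
        assert eu_anomaly(2 * paas["Eu"], paas["Sm"], paas["Gd"], paas) == pytest.approx(2.0)

    def test_oily_core_maximum_value_reachable(self, paas):
        # SN values Eu=4.7, Sm=Gd=1 reproduce the highest observed anomaly
        assert eu_anomaly(4.7 * paas["Eu"], paas["Sm"], paas["Gd"], paas) \
            == pytest.approx(4.7)

    def test_zero_denominator_undefined(self, paas):
        assert math.isnan(eu_anomaly(1.0, 0.0, 0.0, paas))

    @settings(deadline=None, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3))
    def test_common_rescaling_invariance(self, paas, scale):
        base = eu_anomaly(2.0, 5.0, 4.0, paas)
        assert eu_anomaly(2.0 * scale, 5.0 * scale, 4.0 * scale, paas) \
            == pytest.approx(base, rel=1e-9)


class TestReeSummary:
    def test_fourteen_ppm_total(self, paas):
        elements = {sym: 1.0 for sym in REE_ELEMENTS}
        total, _ = ree_summary(elements, paas)
        assert total == pytest.approx(14.0)

    def test_all_zero(self, paas):
        total, ratio = ree_summary({sym: 0.0 for sym in REE_ELEMENTS}, paas)
        assert total == 0.0
        assert math.isnan(ratio)  # Yb = 0 flags the ratio undefined

    def test_shale_normalized_ratio_identity(self, paas):
        _, ratio = ree_summary({"Pr": paas["Pr"], "Yb": paas["Yb"]}, paas)
        assert ratio == pytest.approx(1.0)


class TestCnRatios:
    def test_mass_ratio(self):
        cn, nc = cn_ratios(4.2, 0.2)
        assert cn == pytest.approx(21.0)
        assert nc == pytest.approx(1 / 21.0)

    def test_redfield_biomass_nc(self):
        """Fresh Redfield biomass (C:N 106:16 molar) has N/C ~ 0.176 g/g."""
        c = Constants()
        toc_mass = 106 * c.M_C
        tn_mass = 16 * c.M_N
        _, nc = cn_ratios(toc_mass, tn_mass)
        assert nc == pytest.approx(0.176, abs=5e-4)
        assert nc == pytest.approx(0.18, abs=5e-3)

    def test_molar_mode(self):
        c = Constants()
        cn_molar, _ = cn_ratios(106 * c.M_C, 16 * c.M_N, mode="molar")
        assert cn_molar == pytest.approx(106 / 16)

    def test_zero_tn_degenerate(self):
        cn, nc = cn_ratios(1.0, 0.0)
        assert math.isnan(cn)
        assert nc == 0.0

    def test_both_zero_undefined(self):
        cn, nc = cn_ratios(0.0, 0.0)
        assert math.isnan(cn) and math.isnan(nc)

    @settings(deadline=None, max_examples=50)
    @given(toc=st.floats(0.1, 50), tn=st.floats(0.01, 5))
    def test_reciprocal_identity(self, toc, tn):
        cn, nc = cn_ratios(toc, tn)
        assert cn * nc == pytest.approx(1.0, rel=1e-12)


class TestSaltCorrect:
    def test_zero_porewater_unchanged(self, seawater):
        val, flag = salt_correct(500.0, "K", 0.0, seawater)
        assert val == 500.0 and not flag

    def test_hand_arithmetic(self, seawater):
        val, flag = salt_correct(20000.0, "K", 1.0, seawater)
        assert val == pytest.approx(20000.0 - 399.0)
        assert not flag

    def test_floor_at_zero_with_flag(self, seawater):
        val, flag = salt_correct(100.0, "K", 1.0, seawater)
        assert val == 0.0 and flag

    def test_element_absent_is_flagged_noop(self, seawater):
        val, flag = salt_correct(50.0, "La", 1.0, seawater)
        assert val == 50.0 and flag

    @settings(deadline=None, max_examples=50)
    @given(pw=st.lists(st.floats(0, 3), min_size=2, max_size=2))
    def test_monotone_nonincreasing_in_porewater_fraction(self, seawater, pw):
        lo, hi = sorted(pw)
        v_lo, _ = salt_correct(1000.0, "K", lo, seawater)
        v_hi, _ = salt_correct(1000.0, "K", hi, seawater)
        assert v_hi <= v_lo


class TestIsotopeSummary:
    def test_constant_series(self):
        s = summarize_isotopes([8.0] * 6)
        assert s.mean == 8.0 and s.sd == 0.0 and not s.outliers

    def test_iqr_flags_single_outlier(self):
        s = summarize_isotopes([8, 8, 8, 8, 2])
        assert [v for _, v in s.outliers] == [2.0]
        assert s.mean == pytest.approx(8.0)
        assert s.n == 4

    def test_small_n_refuses_flagging(self):
        s = summarize_isotopes([5.0, 9.0])
        assert s.n == 2 and not s.outliers

    def test_joint_union_flagging(self):
        d15n = [8, 8, 8, 8, 8, 8]
        d13c = [-22, -22, -22, -22, -22, -30]   # outlier only in the partner
        s = summarize_isotopes(d15n, joint_with=d13c)
        assert len(s.outliers) == 1


class TestLinearR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        r2, sign = linear_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert sign == 1

    def test_symmetric_vee_has_zero_slope(self):
        r2, sign = linear_r2([0, 1, 2], [0, 1, 0])
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert sign == 0

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        r2, _ = linear_r2(x, y)
        assert r2 < 0.05

    def test_zero_variance_flagged(self):
        r2, sign = linear_r2([1, 1, 1], [2, 3, 4])
        assert math.isnan(r2)


class TestIndexTable:
    def test_rowwise_equals_tablewise(self, ucc, paas):
        """Indices have no cross-row coupling: single-row slices agree."""
        prof = make_sediment(GUAYMAS_DEMO)
        full = compute_indices(prof)
        from seepflux.refdata import SedimentProfile
        i = 3
        one = SedimentProfile(
            prof.core_id, prof.depth_cm[i:i + 1], prof.toc[i:i + 1],
            prof.tn[i:i + 1], prof.d13c[i:i + 1], prof.d15n[i:i + 1],
            {k: v[i:i + 1] for k, v in prof.elements.items()},
            prof.pw_mass_fraction[i:i + 1])
        row = compute_indices(one)
        for col in row.columns:
            a, b = row[col].iloc[0], full[col].iloc[i]
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b, rel=1e-12)

    def test_salt_correction_columns_appear(self):
        prof = make_sediment(GUAYMAS_DEMO)
        df = compute_indices(prof, apply_salt_correction=True)
        assert "K_corr_ppm" in df.columns
        assert (df["K_corr_ppm"] <= prof.elements["K"] + 1e-9).all()
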