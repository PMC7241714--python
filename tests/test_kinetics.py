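"""Kinetics: Beer–Lambert conversion, model fits, discrimination, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import malkit as mk
from malkit.errors import UsageError

CA_KCAT, CA_KM = 17.6, 1.00  # natural-substrate constants used throughout


def _dataset(model, ki=None, levels=(0.0,), cv=0.0, seed=0):
    cfg = mk.KineticSimConfig(
        model=model, kcat=CA_KCAT, Km=CA_KM, Ki=ki, I_levels=levels,
        noise_cv=cv, seed=seed,
    )
    return mk.generate_kinetics(cfg)[0]


class TestBeerLambert:
    def test_slope_to_velocity(self):
        assay = mk.AssaySpec(extinction_coefficient=3850.0)
        v = mk.rate_from_absorbance(0.00385, assay)
        assert v.M_per_min == pytest.approx(1e-6)
        assert v.mM_per_min == pytest.approx(1e-3)

    def test_zero_slope(self):
        assay = mk.AssaySpec(extinction_coefficient=2530.0)
        assert mk.rate_from_absorbance(0.0, assay).M_per_min == 0.0

    def test_path_length_proportionality(self):
        a1 = mk.AssaySpec(extinction_coefficient=5240.0, path_length=1.0)
        a2 = mk.AssaySpec(extinction_coefficient=5240.0, path_length=2.0)
        v1 = mk.rate_from_absorbance(0.1, a1).M_per_min
        v2 = mk.rate_from_absorbance(0.1, a2).M_per_min
        assert v2 == pytest.approx(v1 / 2)

    def test_per_enzyme_turnover(self):
        assay = mk.AssaySpec(extinction_coefficient=3850.0, enzyme_concentration=1e-7)
        v = mk.rate_from_absorbance(0.00385, assay)
        assert v.per_enzyme_s == pytest.approx(1e-6 / 1e-7 / 60.0)

    def test_extinction_inverse_relation(self):
        # ε reproduced from the absorbance it predicts (A = ε·c·l)
        eps = 5240.0
        c, l = 200e-6, 1.0
        a = eps * c * l
        assert mk.extinction_from_spectrum(a, c, l) == pytest.approx(eps)
        assert mk.extinction_from_spectrum(0.0, 1e-3) == 0.0
        with pytest.raises(UsageError):
            mk.extinction_from_spectrum(1.0, 0.0)


class TestMichaelisMentenFit:
    def test_noiseless_recovery_is_exact(self):
        fit = mk.fit_michaelis_menten(_dataset("mm"))
        assert fit.kcat == pytest.approx(CA_KCAT, rel=1e-6)
        assert fit.Km == pytest.approx(CA_KM, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_half_saturation_identity(self):
        fit = mk.fit_michaelis_menten(_dataset("mm"))
        assert fit.predict(fit.Km) == pytest.approx(fit.kcat / 2)

    def test_noisy_recovery_within_five_percent(self):
        fit = mk.fit_michaelis_menten(_dataset("mm", cv=0.02, seed=42))
        assert fit.kcat == pytest.approx(CA_KCAT, rel=0.05)
        assert fit.Km == pytest.approx(CA_KM, rel=0.05)

    def test_rejects_sparse_grids_and_inhibited_data(self):
        df = _dataset("mm")
        with pytest.raises(UsageError):
            mk.fit_michaelis_menten(df[df["substrate_mM"] < 5.0])
        with pytest.raises(UsageError):
            mk.fit_michaelis_menten(
                _dataset("competitive", ki=1.7, levels=(0.0, 5.0))
            )


class TestInhibitionFit:
    def test_noiseless_competitive_recovery(self):
        df = _dataset("competitive", ki=1.7, levels=(0, 2, 5, 10))
        fit = mk.fit_inhibition(df, "competitive")
        assert fit.kcat == pytest.approx(CA_KCAT, rel=1e-6)
        assert fit.Km == pytest.approx(CA_KM, rel=1e-6)
        assert fit.Ki == pytest.approx(1.7, rel=1e-6)
        assert fit.global_r_squared == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("ki,levels", [(71.0, (0, 25, 50, 100)), (128.0, (0, 50, 100, 150))])
    def test_noiseless_noncompetitive_recovery(self, ki, levels):
        df = _dataset("noncompetitive", ki=ki, levels=levels)
        fit = mk.fit_inhibition(df, "noncompetitive")
        assert fit.Ki == pytest.approx(ki, rel=1e-6)

    def test_uninhibited_data_flags_ki_unidentifiable(self):
        fit = mk.fit_inhibition(_dataset("mm"), "competitive")
        assert not fit.ki_identifiable
        assert fit.Ki is None
        assert fit.kcat == pytest.approx(CA_KCAT, rel=1e-6)

    def test_wrong_model_has_larger_residuals(self):
        df = _dataset("noncompetitive", ki=71.0, levels=(0, 25, 50, 100))
        right = mk.fit_inhibition(df, "noncompetitive")
        wrong = mk.fit_inhibition(df, "competitive")
        assert right.global_r_squared > wrong.global_r_squared

    def test_model_curves_monotone_in_s_and_inhibitor(self):
        S = np.linspace(0.1, 20, 50)
        for rate in (mk.competitive_rate, mk.noncompetitive_rate):
            v0 = rate(S, 0.0, CA_KCAT, CA_KM, 1.7)
            v5 = rate(S, 5.0, CA_KCAT, CA_KM, 1.7)
            assert np.all(v0 >= 0) and np.all(np.diff(v0) > 0)
            assert np.all(v5 < v0)


class TestClassification:
    def test_competitive_regime(self):
        df = _dataset("competitive", ki=1.7, levels=(0, 2, 5, 10), cv=0.02, seed=1)
        assert mk.classify_inhibition(df).model == "competitive"

    @pytest.mark.parametrize("ki,levels", [(71.0, (0, 25, 50, 100)), (128.0, (0, 50, 100, 150))])
    def test_noncompetitive_regimes(self, ki, levels):
        df = _dataset("noncompetitive", ki=ki, levels=levels, cv=0.02, seed=1)
        assert mk.classify_inhibition(df).model == "noncompetitive"

    def test_no_effect_limit_is_none(self):
        df = _dataset("competitive", ki=1e6, levels=(0, 25, 50, 100), cv=0.02, seed=4)
        fit = mk.classify_inhibition(df)
        assert fit.model == "none"
        assert fit.Ki is None

    def test_recovery_rate_across_seeds(self):
        hits = sum(
            mk.classify_inhibition(
                _dataset("competitive", ki=1.7, levels=(0, 2, 5, 10), cv=0.02, seed=s)
            ).model
            == "competitive"
            for s in range(30)
        )
        assert hits >= 29


class TestLineweaverBurk:
    def test_competitive_series_share_y_intercept(self):
        df = _dataset("competitive", ki=1.7, levels=(0, 2, 5, 10))
        lb = mk.lineweaver_burk(df)
        y = lb.series["y_intercept"].to_numpy()
        assert np.ptp(y) / np.abs(y).max() <= 1e-9
        assert lb.pattern == "competitive-pattern"
        assert y[0] == pytest.approx(1.0 / CA_KCAT)

    def test_noncompetitive_series_share_x_intercept(self):
        df = _dataset("noncompetitive", ki=71.0, levels=(0, 25, 50, 100))
        lb = mk.lineweaver_burk(df)
        x = lb.series["x_intercept"].to_numpy()
        assert np.ptp(x) / np.abs(x).max() <= 1e-9
        assert lb.pattern == "noncompetitive-pattern"
        assert x[0] == pytest.approx(-1.0 / CA_KM)

    @pytest.mark.parametrize("model,ki", [("competitive", 1.7), ("noncompetitive", 71.0)])
    def test_slopes_increase_with_inhibitor(self, model, ki):
        df = _dataset(model, ki=ki, levels=(0, 5, 10, 20))
        slopes = mk.lineweaver_burk(df).series["slope"].to_numpy()
        assert np.all(np.diff(slopes) > 0)

    def test_nonpositive_velocities_excluded_with_warning(self):
        df = _dataset("mm").copy()
        df.loc[df.index[0], "velocity"] = -0.1
        with pytest.warns(UserWarning, match="non-positive"):
            lb = mk.lineweaver_burk(df)
        assert len(lb.points) == len(df) - 1


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "kcat,km,printed,precision",
        [(66.0, 1.38, 47.8, 0.05), (4.4, 141.0, 0.031, 0.0005), (17.6, 1.00, 17.6, 0.05)],
    )
    def test_efficiency_reproduces_printed_cells(self, kcat, km, printed, precision):
        assert abs(mk.efficiency(kcat, km) - printed) <= precision

    def test_efficiency_from_fit_and_unit_case(self):
        fit = mk.fit_michaelis_menten(_dataset("mm"))
        assert mk.efficiency(fit) == pytest.approx(fit.kcat / fit.Km)
        assert mk.efficiency(2.5, 2.5) == 1.0

    @pytest.mark.parametrize("a,b,expected", [(141.0, 1.00, 141.0), (17.6, 4.4, 4.0), (3.0, 3.0, 1.0)])
    def test_fold_change(self, a, b, expected):
        assert mk.fold_change(a, b) == pytest.approx(expected)

    def test_fold_change_zero_denominator(self):
        with pytest.raises(UsageError):
            mk.fold_change(1.0, 0.0)
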