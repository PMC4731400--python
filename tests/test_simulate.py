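"""Generators: IRF shape, noise statistics, cohort structure, determinism."""

import numpy as np
import pytest

from thyrodos import DCSModelParams, OpticalProperties
from thyrodos.simulate import (
    CohortConfig,
    NoduleTemplate,
    generate_cohort,
    generate_irf,
    simulate_dtof,
    simulate_g2,
)
from thyrodos.stats import LOCATIONS, lme_contrast


def _fwhm(t, y):
    """Full width at half maximum with interpolated crossings."""
    half = y.max() / 2.0
    above = np.nonzero(y >= half)[0]
    i0, i1 = above[0], above[-1]
    left = np.interp(half, [y[i0 - 1], y[i0]], [t[i0 - 1], t[i0]])
    right = np.interp(half, [y[i1 + 1], y[i1]], [t[i1 + 1], t[i1]])
    return right - left


class TestGenerateIRF:
    @pytest.mark.parametrize("width_ps", [350.0, 400.0, 450.0])
    def test_fwhm_matches_nominal_width(self, width_ps, instrument):
        irf = generate_irf(width_ps, instrument.time_axis_ns)
        assert irf.counts.sum() == pytest.approx(1.0)
        got = _fwhm(irf.time_bins_ns, irf.counts) * 1000.0
        assert got == pytest.approx(width_ps, rel=0.02)

    def test_delta_shape_is_single_bin(self, instrument):
        irf = generate_irf(350, instrument.time_axis_ns, shape="delta", t0_ns=1.0)
        assert np.count_nonzero(irf.counts) == 1

    def test_gaussian_shape_is_symmetric_about_mode(self, instrument):
        irf = generate_irf(400, instrument.time_axis_ns, shape="gaussian", t0_ns=2.0)
        mode = np.argmax(irf.counts)
        k = 40
        np.testing.assert_allclose(
            irf.counts[mode - k: mode], irf.counts[mode + k: mode: -1], rtol=1e-8
        )

    def test_warns_on_coarse_axis(self):
        t = np.arange(100) * 0.2  # 200 ps bins vs 350 ps width
        with pytest.warns(UserWarning):
            generate_irf(350, t)


class TestSimulateDTOF:
    def test_expected_counts_mode_is_exact(self, irfs, tissue_props, medium):
        from thyrodos.trs import convolve_irf
        from thyrodos.forward import tr_reflectance

        irf = irfs[785.0]
        curve = simulate_dtof(tissue_props, 25.0, irf, 1e6, medium, noise=False)
        t = irf.time_bins_ns
        theory = np.zeros_like(t)
        theory[t > 0] = tr_reflectance(tissue_props, 25.0, t[t > 0], medium)
        expected = convolve_irf(theory, irf)
        expected *= 1e6 / expected.sum()
        np.testing.assert_allclose(curve.counts, expected, rtol=1e-12)

    def test_seed_determinism(self, irfs, tissue_props, medium):
        a = simulate_dtof(tissue_props, 25.0, irfs[785.0], 1e6, medium, seed=42)
        b = simulate_dtof(tissue_props, 25.0, irfs[785.0], 1e6, medium, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)
        c = simulate_dtof(tissue_props, 25.0, irfs[785.0], 1e6, medium, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_index_of_dispersion(self, irfs, tissue_props, medium):
        """Across seeds, each bin's variance matches its mean (Fano ~ 1)."""
        irf = irfs[785.0]
        draws = np.stack([
            simulate_dtof(tissue_props, 25.0, irf, 2e5, medium, seed=s).counts
            for s in range(300)
        ])
        mean = draws.mean(axis=0)
        var = draws.var(axis=0, ddof=1)
        big = mean > 200  # bins with enough counts for a stable ratio
        fano = var[big] / mean[big]
        assert abs(fano.mean() - 1.0) < 0.1


class TestSimulateG2:
    def test_infinite_integration_time_is_noiseless(self, tissue_props, medium):
        params = DCSModelParams(bfi=15e-9, beta=0.5)
        curve = simulate_g2(params, tissue_props, 25.0,
                            integration_time_s=np.inf, medium=medium)
        # first lag is 100 ns, so the intercept sits just below 1 + beta
        assert curve.g2[0] == pytest.approx(1.5, rel=5e-3)
        assert np.all(np.diff(curve.g2) <= 0)

    def test_seed_determinism(self, tissue_props, medium):
        params = DCSModelParams(bfi=15e-9, beta=0.5)
        a = simulate_g2(params, tissue_props, 25.0, seed=9, medium=medium)
        b = simulate_g2(params, tissue_props, 25.0, seed=9, medium=medium)
        np.testing.assert_array_equal(a.g2, b.g2)

    def test_noise_scales_down_with_integration_time(self, tissue_props, medium):
        params = DCSModelParams(bfi=15e-9, beta=0.5)
        ref = simulate_g2(params, tissue_props, 25.0,
                          integration_time_s=np.inf, medium=medium)

        def rms(t_int):
            devs = []
            for s in range(25):
                c = simulate_g2(params, tissue_props, 25.0, integration_time_s=t_int,
                                medium=medium, seed=s)
                devs.append(c.g2 - ref.g2)
            return np.sqrt(np.mean(np.square(devs)))

        assert rms(70.0) < rms(7.0) / 2.0  # ~sqrt(10) expected


class TestGenerateCohort:
    def test_structure_and_invariants(self):
        cohort = generate_cohort(seed=0)
        df = cohort.measurements
        assert len(df) == 22 * 6
        assert set(df["location"]) == set(LOCATIONS)
        np.testing.assert_allclose(df["TTD"], df["STT"] + df["TT"])
        assert (df.loc[df["organ"] == "muscle", "location"]
                .str.startswith("muscle").all())
        assert cohort.subjects["BMI"].equals(
            cohort.subjects["weight"] / (cohort.subjects["height"] / 100) ** 2
        )

    def test_bit_reproducible(self):
        a = generate_cohort(seed=33).measurements
        b = generate_cohort(seed=33).measurements
        assert a.equals(b)

    def test_grand_means_match_configuration(self):
        """Location means over 60 seeds stay within 2 SE of the configured means."""
        config = CohortConfig()
        n_rep = 60
        sums = None
        for s in range(n_rep):
            m = generate_cohort(config, seed=s).measurements
            g = m.groupby("location")[["THC", "StO2", "BFI"]].mean()
            sums = g if sums is None else sums + g
        grand = sums / n_rep
        for loc, entry in config.hemodynamics.items():
            for var in ("THC", "StO2", "BFI"):
                mean, sd = entry[var]
                se = sd / np.sqrt(config.n_subjects * n_rep)
                assert abs(grand.loc[loc, var] - mean) < 2.5 * se, (loc, var)

    def test_zero_variance_config_collapses_to_means(self):
        config = CohortConfig(
            hemodynamics={loc: {var: (m, 0.0) for var, (m, _) in entry.items()}
                          for loc, entry in CohortConfig().hemodynamics.items()},
            scattering={loc: tuple((m, 0.0) for m, _ in entry)
                        for loc, entry in CohortConfig().scattering.items()},
            icc=0.0,
            bmi_slopes={"THC": 0.0, "StO2": 0.0, "BFI": 0.0},
            lognormal_bfi_locations=(),
        )
        df = generate_cohort(config, seed=1).measurements
        for loc, entry in config.hemodynamics.items():
            sub = df[df["location"] == loc]
            for var in ("THC", "StO2", "BFI"):
                np.testing.assert_allclose(sub[var], entry[var][0], rtol=1e-12)

    def test_nodule_template_produces_positive_contrast(self):
        cohort = generate_cohort(CohortConfig(nodule=NoduleTemplate()), seed=4)
        df = cohort.measurements
        thyroid = df[df["organ"] == "thyroid"]
        assert thyroid["nodule_index"].sum() > 0
        for var in ("THC", "BFI"):
            est = lme_contrast(thyroid, var, "nodule_index")
            assert est.significant
            assert est.level_estimates["slope"] > 0

    def test_nodule_on_muscle_is_config_error(self):
        with pytest.raises(ValueError):
            NoduleTemplate(locations=("muscle_left",))

    def test_lognormal_locations_are_right_skewed(self):
        """BFI residuals are right-skewed exactly at the configured locations.

        Subject variance and BMI slopes are switched off so the skew of
        the location-level draw itself is visible.
        """
        from scipy.stats import skew
        config = CohortConfig(icc=0.0,
                              bmi_slopes={"THC": 0.0, "StO2": 0.0, "BFI": 0.0})
        vals = {loc: [] for loc in LOCATIONS}
        for s in range(30):
            m = generate_cohort(config, seed=s).measurements
            for loc in LOCATIONS:
                grp = m[m["location"] == loc]
                vals[loc].extend(grp["BFI"] - grp["BFI"].mean())
        for loc in config.lognormal_bfi_locations:
            assert skew(np.array(vals[loc])) > 0.3, loc
        for loc in set(LOCATIONS) - set(config.lognormal_bfi_locations):
            assert abs(skew(np.array(vals[loc]))) < 0.3, loc
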