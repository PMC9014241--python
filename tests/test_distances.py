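"""Distance distributions, quadrature moments and the derived FRET-lines."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import fretlines as fl
from fretlines.core import MomentPair, ObservablePair
from fretlines.distances import (
    DistanceDistribution,
    fret_lifetime_of_distance,
    lifetime_moments_from_distribution,
)
from helpers import chord_residual


class TestChiDensity:
    def test_normalization(self):
        val = quad(lambda r: fl.chi_pdf(r, 50.0, 7.5), 0.0, 200.0)[0]
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_central_limit_is_gaussian_chain(self):
        R = np.linspace(0.0, 60.0, 500)
        np.testing.assert_allclose(
            fl.chi_pdf(R, 0.0, 10.0), fl.gaussian_chain_pdf(R, 10.0), atol=1e-14
        )
        # continuity: tiny Rmp stays within numerical reach of the limit
        np.testing.assert_allclose(
            fl.chi_pdf(R, 1e-8, 10.0), fl.gaussian_chain_pdf(R, 10.0), atol=1e-10
        )

    def test_narrow_limit_tends_to_normal(self):
        """sigma/Rmp -> 0: the chi density approaches the normal density,
        with the maximum absolute deviation shrinking as sigma/Rmp (the
        order of the (R/Rmp) prefactor correction)."""

        def max_dev(Rmp):
            R = np.linspace(Rmp - 10.0, Rmp + 10.0, 2001)
            return np.abs(fl.chi_pdf(R, Rmp, 1.0) - norm.pdf(R, Rmp, 1.0)).max()

        d100, d1000 = max_dev(100.0), max_dev(1000.0)
        assert d100 < 3e-3  # ~ pdf_max * sigma/Rmp
        assert d1000 < 3e-4
        assert d1000 == pytest.approx(d100 / 10, rel=0.2)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            fl.chi_pdf(10.0, 50.0, 0.0)
        with pytest.raises(ValueError):
            fl.chi_pdf(10.0, -1.0, 5.0)


class TestTruncatedNormal:
    @pytest.mark.parametrize("Rmp, sigma", [(60.0, 6.0), (15.0, 15.0), (2.0, 10.0)])
    def test_always_normalized(self, Rmp, sigma):
        val = quad(lambda r: fl.truncated_normal_pdf(r, Rmp, sigma), 0.0,
                   Rmp + 12 * sigma)[0]
        assert val == pytest.approx(1.0, abs=1e-10)

    def test_negligible_renormalization_far_from_zero(self):
        # Rmp = 60, sigma = 6: truncation mass is ~1e-23
        assert fl.truncated_normal_pdf(60.0, 60.0, 6.0) == pytest.approx(
            norm.pdf(0.0, scale=6.0), rel=1e-12
        )

    def test_overweights_small_distances_vs_chi(self):
        # broad linker: the truncated normal puts more density at R = 5 Å
        assert fl.truncated_normal_pdf(5.0, 15.0, 15.0) > fl.chi_pdf(5.0, 15.0, 15.0)


class TestWlcDensity:
    def test_normalization(self):
        val = quad(lambda r: fl.wlc_pdf(r, 120.0, 0.3), 0.0, 120.0, limit=200)[0]
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_zero_beyond_contour_length(self):
        assert fl.wlc_pdf(120.0, 120.0, 0.3) == 0.0
        assert fl.wlc_pdf(150.0, 120.0, 0.3) == 0.0

    def test_rod_limit(self):
        mean = quad(lambda r: r * fl.wlc_pdf(r, 100.0, 10.0), 0.0, 100.0,
                    limit=200)[0]
        assert mean > 95.0

    def test_flexible_limit_ideal_chain_scaling(self):
        """kappa << 1: <R²> approaches the ideal-chain value 2 l_p L."""
        kappa, L = 0.05, 100.0
        r2 = quad(lambda r: r**2 * fl.wlc_pdf(r, L, kappa), 0.0, L, limit=200)[0]
        assert r2 == pytest.approx(2 * kappa * L**2, rel=0.15)


class TestLifetimeMoments:
    def test_delta_limit(self, ctx):
        dist = DistanceDistribution.chi(50.0, 1e-6)
        m = lifetime_moments_from_distribution(dist, ctx)
        assert m.m1 == pytest.approx(2.0, abs=1e-6)  # E = 0.5 point

    def test_gaussian_chain_mean_square_identity(self, ctx):
        dist = DistanceDistribution.gaussian_chain(10.0)
        lo, hi = dist.support()
        r2 = quad(lambda r: r**2 * dist.pdf(r), lo, hi)[0]
        assert r2 == pytest.approx(300.0, rel=1e-6)

    @pytest.mark.parametrize(
        "dist",
        [
            DistanceDistribution.chi(57.5, 7.5),
            DistanceDistribution.truncated_normal(45.0, 12.0),
            DistanceDistribution.gaussian_chain(30.0),
            DistanceDistribution.wlc(120.0, 0.3),
            DistanceDistribution.mixture(
                [DistanceDistribution.chi(52.0, 6.0),
                 DistanceDistribution.wlc(120.0, 0.25)],
                [0.4, 0.6],
            ),
        ],
        ids=["chi", "truncnorm", "gc", "wlc", "mixture"],
    )
    def test_quadrature_matches_monte_carlo(self, ctx, dist):
        """Quadrature moments agree with a 10^6-sample MC oracle to 3 SE."""
        rng = np.random.default_rng(2024)
        R = dist.sample(10**6, rng)
        tau = fret_lifetime_of_distance(R, ctx)
        m = lifetime_moments_from_distribution(dist, ctx)
        for mc, exact in ((tau, m.m1), (tau**2, m.m2)):
            se = mc.std(ddof=1) / np.sqrt(mc.size)
            assert abs(mc.mean() - exact) < 3 * se


class TestStaticLineLinker:
    def test_zero_width_is_ideal(self, ctx):
        curve = fl.static_line_linker("chi", 0.0, ctx)
        s = curve.samples
        np.testing.assert_allclose(s["E"], 1 - s["tauF_ns"] / 4, atol=1e-6)

    def test_right_shift_monotone_in_width(self, ctx):
        """At matched E, tau_F grows with the linker width sigma."""
        grid = np.linspace(25.0, 90.0, 41)
        curves = {
            sig: fl.static_line_linker("chi", sig, ctx, grid).samples
            for sig in (3.0, 6.0, 10.0)
        }
        for E in (0.2, 0.5, 0.8):
            taus = [
                np.interp(-E, -c["E"].to_numpy(), c["tauF_ns"].to_numpy())
                for c in curves.values()
            ]
            ideal = (1 - E) * 4
            assert ideal < taus[0] < taus[1] < taus[2]

    def test_line_passes_through_quadrature_point(self, ctx):
        curve = fl.static_line_linker("chi", 6.0, ctx, np.linspace(48, 52, 5)).samples
        m = lifetime_moments_from_distribution(DistanceDistribution.chi(50.0, 6.0),
                                               ctx)
        row = curve.iloc[2]  # Rmp = 50
        assert row["m1_ns"] == pytest.approx(m.m1, rel=1e-8)
        assert row["m2_ns2"] == pytest.approx(m.m2, rel=1e-8)

    def test_chi_vs_truncated_normal_deviation_grows_with_width(self, ctx):
        """Model choice matters most for broad linkers: the max |dE| at
        matched tau_F is larger at sigma = 20 Å than at sigma = 5 Å."""
        grid = np.linspace(20.0, 100.0, 33)

        def max_dE(sigma):
            chi = fl.static_line_linker("chi", sigma, ctx, grid).samples
            tn = fl.static_line_linker("truncated_normal", sigma, ctx, grid).samples
            tf = np.linspace(0.5, 3.0, 50)
            o_c = chi["tauF_ns"].argsort()
            o_t = tn["tauF_ns"].argsort()
            Ec = np.interp(tf, chi["tauF_ns"].to_numpy()[o_c],
                           chi["E"].to_numpy()[o_c])
            Et = np.interp(tf, tn["tauF_ns"].to_numpy()[o_t],
                           tn["E"].to_numpy()[o_t])
            return np.abs(Ec - Et).max()

        small, big = max_dE(5.0), max_dE(20.0)
        assert small < 0.02
        assert big > 3 * small


class TestLinkerAveragedStates:
    def test_fixed_dye(self, ctx):
        st = fl.linker_averaged_state(fl.FretState("a", E=0.5), ctx)
        assert (st.moments.m1, st.moments.m2) == (pytest.approx(2.0),
                                                  pytest.approx(4.0))
        assert st.moments.variance >= 0

    def test_model_and_observable_paths_agree(self, ctx):
        """Moments from the distance model equal moments recovered from the
        (E, tauF) observables that the model itself generates."""
        dist = DistanceDistribution.chi(57.5, 7.5)
        state = fl.FretState("c1", R_mp=57.5, distance_model=dist)
        via_model = fl.linker_averaged_state(state, ctx)
        m = via_model.moments
        obs = ObservablePair(1 - m.m1 / 4, m.m2 / m.m1)
        via_obs = fl.linker_averaged_state(state, ctx, observed=obs)
        assert via_obs.moments.m1 == pytest.approx(m.m1, abs=1e-12)
        assert via_obs.moments.m2 == pytest.approx(m.m2, abs=1e-10)


class TestDynamicLineWithLinkers:
    @pytest.fixture(scope="class")
    def states(self, ctx):
        d1 = DistanceDistribution.chi(57.5, 7.5)
        d2 = DistanceDistribution.chi(34.5, 7.5)
        s1 = fl.linker_averaged_state(fl.FretState("1", R_mp=57.5,
                                                   distance_model=d1), ctx)
        s2 = fl.linker_averaged_state(fl.FretState("2", R_mp=34.5,
                                                   distance_model=d2), ctx)
        return s1, s2

    def test_endpoints(self, ctx, states):
        s1, s2 = states
        s = fl.dynamic_line_with_linkers(s1, s2, ctx).samples
        assert s.iloc[-1]["m1_ns"] == pytest.approx(s1.moments.m1)
        assert s.iloc[0]["m1_ns"] == pytest.approx(s2.moments.m1)

    def test_midpoint_equals_mixture_quadrature(self, ctx, states):
        """x = 0.5 equals the full quadrature over the two-component
        mixture distance distribution."""
        s1, s2 = states
        curve = fl.dynamic_line_with_linkers(s1, s2, ctx, n_points=3)
        mid = curve.samples.iloc[1]
        mix = DistanceDistribution.mixture(
            [DistanceDistribution.chi(57.5, 7.5),
             DistanceDistribution.chi(34.5, 7.5)],
            [0.5, 0.5],
        )
        m = lifetime_moments_from_distribution(mix, ctx)
        assert mid["m1_ns"] == pytest.approx(m.m1, rel=1e-8)
        assert mid["m2_ns2"] == pytest.approx(m.m2, rel=1e-8)

    def test_endpoints_right_shifted_vs_fixed_dyes(self, ctx, states):
        """Linker broadening moves both pure states toward longer tau_F."""
        s1, s2 = states
        curve = fl.dynamic_line_with_linkers(s1, s2, ctx)
        for st, idx, Rmp in ((s1, -1, 57.5), (s2, 0, 34.5)):
            row = curve.samples.iloc[idx]
            tau_fixed = fret_lifetime_of_distance(Rmp, ctx)
            assert row["tauF_ns"] > tau_fixed

    def test_collinear_in_moment_representation(self, ctx, states):
        assert chord_residual(fl.dynamic_line_with_linkers(*states, ctx)) < 1e-9


class TestVarianceDecomposition:
    def test_single_state(self, ctx):
        st = fl.linker_averaged_state(
            fl.FretState("a", R_mp=50.0,
                         distance_model=DistanceDistribution.chi(50.0, 6.0)), ctx
        )
        total, conf, link = fl.variance_decomposition([st], [1.0])
        assert conf == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(link)

    def test_zero_width_reduces_to_two_state_formula(self, ctx):
        s1 = fl.linker_averaged_state(fl.FretState("a", E=0.8), ctx)
        s2 = fl.linker_averaged_state(fl.FretState("b", E=0.2), ctx)
        x = 0.3
        total, conf, link = fl.variance_decomposition([s1, s2], [x, 1 - x])
        t1, t2 = 0.8, 3.2
        assert link == pytest.approx(0.0, abs=1e-12)
        assert total == pytest.approx(x * (1 - x) * (t1 - t2) ** 2)

    def test_matches_direct_mixture_quadrature(self, ctx):
        d1 = DistanceDistribution.chi(57.5, 7.5)
        d2 = DistanceDistribution.chi(40.0, 5.0)
        s1 = fl.linker_averaged_state(fl.FretState("1", R_mp=57.5,
                                                   distance_model=d1), ctx)
        s2 = fl.linker_averaged_state(fl.FretState("2", R_mp=40.0,
                                                   distance_model=d2), ctx)
        total, conf, link = fl.variance_decomposition([s1, s2], [0.3, 0.7])
        mix = DistanceDistribution.mixture([d1, d2], [0.3, 0.7])
        m = lifetime_moments_from_distribution(mix, ctx)
        assert total == pytest.approx(m.m2 - m.m1**2, rel=1e-8)
        assert total == pytest.approx(conf + link, rel=1e-10)

    def test_additivity_random_mixtures(self, ctx):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = rng.integers(2, 5)
            states = [
                fl.linker_averaged_state(
                    fl.FretState(f"s{i}", E=float(rng.uniform(0.05, 0.95)),
                                 linker_moments=None), ctx,
                    observed=None,
                )
                for i in range(n)
            ]
            # give each state synthetic linker variance via explicit moments
            states = [
                fl.LinkerAveragedState(
                    s.label,
                    MomentPair(s.moments.m1,
                               s.moments.m2 + float(rng.uniform(0, 0.5))),
                )
                for s in states
            ]
            x = rng.dirichlet(np.ones(n))
            total, conf, link = fl.variance_decomposition(states, x.tolist())
            assert total == pytest.approx(conf + link, rel=1e-10, abs=1e-12)


class TestPolymerLines:
    def test_gaussian_chain_limits(self, ctx):
        curve = fl.polymer_lines(ctx, "gc_sweep_sigma",
                                 np.geomspace(1.0, 500.0, 41))
        s = curve.samples
        assert s.iloc[0]["E"] > 0.99 and s.iloc[0]["tauF_ns"] < 0.1
        assert s.iloc[-1]["E"] < 0.01 and s.iloc[-1]["tauF_ns"] == pytest.approx(
            4.0, abs=0.05
        )

    def test_gaussian_chain_reference_point(self, ctx):
        """At sigma = R0/sqrt(3) (so <R²> = R0²) the moments match direct
        quadrature."""
        sigma = 50.0 / np.sqrt(3.0)
        curve = fl.polymer_lines(ctx, "gc_sweep_sigma", [sigma])
        m = lifetime_moments_from_distribution(
            DistanceDistribution.gaussian_chain(sigma), ctx
        )
        row = curve.samples.iloc[0]
        assert row["m1_ns"] == pytest.approx(m.m1, rel=1e-10)
        assert row["m2_ns2"] == pytest.approx(m.m2, rel=1e-10)

    def test_wlc_rod_limit_approaches_static_line(self, ctx):
        """kappa -> infinity concentrates p(R) at R = L: the L-swept line
        converges to the ideal static line."""
        grid = np.linspace(30.0, 80.0, 11)
        curve = fl.polymer_lines(ctx, "wlc_sweep_L_fixed_kappa", grid, kappa=50.0)
        s = curve.samples
        np.testing.assert_allclose(s["tauF_ns"], (1 - s["E"]) * 4, rtol=0.05)

    def test_wlc_degenerate_efficiency_resolved_by_lifetime(self, ctx):
        """Different (kappa, L) pairs with matching E differ in tau_F."""
        c1 = fl.polymer_lines(ctx, "wlc_sweep_kappa_fixed_L",
                              np.geomspace(0.05, 5.0, 31), L=90.0).samples
        c2 = fl.polymer_lines(ctx, "wlc_sweep_kappa_fixed_L",
                              np.geomspace(0.05, 5.0, 31), L=140.0).samples
        E0 = 0.55
        o1, o2 = c1["E"].argsort(), c2["E"].argsort()
        t1 = np.interp(E0, c1["E"].to_numpy()[o1], c1["tauF_ns"].to_numpy()[o1])
        t2 = np.interp(E0, c2["E"].to_numpy()[o2], c2["tauF_ns"].to_numpy()[o2])
        assert abs(t1 - t2) > 0.05

    def test_unknown_mode(self, ctx):
        with pytest.raises(ValueError):
            fl.polymer_lines(ctx, "nope", [1.0])


class TestOrderDisorderLine:
    @pytest.fixture(scope="class")
    def ctx52(self):
        return fl.FretContext(R0=52.0, tauD0=4.0)

    @pytest.fixture(scope="class")
    def parts(self):
        return (DistanceDistribution.chi(52.0, 6.0),
                DistanceDistribution.wlc(120.0, 0.3))

    def test_endpoints(self, ctx52, parts):
        folded, unfolded = parts
        curve = fl.order_disorder_line(folded, unfolded, ctx52)
        mf = lifetime_moments_from_distribution(folded, ctx52)
        mu = lifetime_moments_from_distribution(unfolded, ctx52)
        assert curve.samples.iloc[-1]["m1_ns"] == pytest.approx(mf.m1)
        assert curve.samples.iloc[0]["m1_ns"] == pytest.approx(mu.m1)

    def test_midpoint_matches_mixed_density_quadrature(self, ctx52, parts):
        folded, unfolded = parts
        curve = fl.order_disorder_line(folded, unfolded, ctx52, n_points=3)
        mid = curve.samples.iloc[1]
        mix = DistanceDistribution.mixture(list(parts), [0.5, 0.5])
        m = lifetime_moments_from_distribution(mix, ctx52)
        assert mid["m1_ns"] == pytest.approx(m.m1, rel=1e-8)
        assert mid["m2_ns2"] == pytest.approx(m.m2, rel=1e-8)

    def test_straight_in_moment_representation(self, ctx52, parts):
        assert chord_residual(fl.order_disorder_line(*parts, ctx52)) < 1e-9
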