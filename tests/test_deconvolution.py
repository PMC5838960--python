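import itertools

import numpy as np
import pandas as pd
import pytest

from mixqc.deconvolution import (
    estimate_proportions,
    proportion_uncertainty,
    solve_simplex_lstsq,
    target_geometry,
)
from mixqc.design import MixtureDesign, make_default_design
from mixqc.selectivity import PureProfile


def random_profile(rng, n=12):
    vals = rng.gamma(1.0, 200.0, (n, 3)) + 1.0
    return PureProfile(
        pd.DataFrame(vals, columns=["liver", "brain", "placenta"],
                     index=[f"m{i}" for i in range(n)])
    )


def exact_mixtures(profile, design):
    sig = profile.linear_means.to_numpy() @ design.phi
    return pd.DataFrame(sig, index=profile.linear_means.index,
                        columns=list(design.mixture_ids))


def grid_search_simplex(A, b, step=1e-3):
    """Exhaustive oracle over the 3-simplex at the given resolution."""
    best, best_obj = None, np.inf
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    for x in ticks:
        for y in np.arange(0.0, 1.0 - x + step / 2, step):
            z = 1.0 - x - y
            phi = np.array([x, y, z])
            obj = np.sum((A @ phi - b) ** 2)
            if obj < best_obj:
                best_obj, best = obj, phi
    return best


class TestEstimateProportions:
    def test_noise_free_recovery_of_default_design(self, default_design):
        rng = np.random.default_rng(20)
        profile = random_profile(rng)
        est = estimate_proportions(profile, exact_mixtures(profile, default_design),
                                   default_design)
        np.testing.assert_allclose(
            est.phi_hat["mix1"].to_numpy(), [0.25, 0.25, 0.5], atol=1e-6
        )
        np.testing.assert_allclose(
            est.phi_hat["mix2"].to_numpy(), [0.25, 0.5, 0.25], atol=1e-6
        )
        assert est.length_sum == pytest.approx(0.0, abs=1e-6)

    def test_pure_column_recovers_simplex_vertex(self, default_design):
        rng = np.random.default_rng(21)
        profile = random_profile(rng)
        mixes = pd.DataFrame(
            {
                "mix1": profile.linear_means["brain"],
                "mix2": profile.linear_means["placenta"],
            }
        )
        est = estimate_proportions(profile, mixes, default_design)
        np.testing.assert_allclose(est.phi_hat["mix1"].to_numpy(), [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(est.phi_hat["mix2"].to_numpy(), [0, 0, 1], atol=1e-9)

    def test_estimates_sum_to_one_and_nonnegative(self, default_design):
        rng = np.random.default_rng(22)
        profile = random_profile(rng, n=50)
        noisy = exact_mixtures(profile, default_design) * rng.lognormal(
            0, 0.4, (50, 1)
        )
        est = estimate_proportions(profile, noisy, default_design)
        assert (est.phi_hat.to_numpy() >= 0).all()
        np.testing.assert_allclose(est.phi_hat.sum(axis=0), 1.0, atol=1e-9)

    def test_rank_deficient_profile_diagnosed(self, default_design):
        col = np.linspace(1, 20, 10)
        profile = PureProfile(
            pd.DataFrame(
                {"liver": col, "brain": 2 * col, "placenta": 3 * col},
                index=[f"m{i}" for i in range(10)],
            )
        )
        mixes = exact_mixtures(profile, default_design)
        with pytest.raises(ValueError, match="condition"):
            estimate_proportions(profile, mixes, default_design)

    @pytest.mark.parametrize("seed", [30, 31, 32])
    def test_matches_simplex_grid_search(self, seed, default_design):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        A = rng.gamma(1.0, 50.0, (n, 3)) + 1.0
        b = A @ np.array([0.3, 0.25, 0.45]) * rng.lognormal(0, 0.3, n)
        ours = solve_simplex_lstsq(A, b)
        grid = grid_search_simplex(A, b, step=1e-3)
        assert np.abs(ours - grid).max() <= 2e-3

    def test_boundary_solution_found_exactly(self):
        # target outside the simplex: optimum lies on a face
        A = np.eye(3)
        b = np.array([1.2, -0.1, 0.3])
        x = solve_simplex_lstsq(A, b)
        grid = grid_search_simplex(A, b, step=1e-3)
        assert np.abs(x - grid).max() <= 2e-3
        assert x[1] == pytest.approx(0.0, abs=1e-12)

    def test_length_sum_invariant_to_component_order(self):
        rng = np.random.default_rng(23)
        vals = rng.gamma(1.0, 100.0, (15, 3)) + 1.0
        ids = [f"m{i}" for i in range(15)]
        results = []
        for perm in itertools.permutations(["liver", "brain", "placenta"]):
            design = MixtureDesign.from_proportions(
                perm,
                {
                    "mix1": [{"liver": 1, "brain": 1, "placenta": 2}[c] for c in perm],
                    "mix2": [{"liver": 1, "brain": 2, "placenta": 1}[c] for c in perm],
                },
            )
            profile = PureProfile(
                pd.DataFrame(vals, columns=["liver", "brain", "placenta"], index=ids)
            )
            mixes = exact_mixtures(
                PureProfile(profile.linear_means[list(perm)]), design
            ) * 1.07  # mild global distortion so lengths are nonzero
            est = estimate_proportions(profile, mixes, design)
            results.append(est.length_sum)
        np.testing.assert_allclose(results, results[0], atol=1e-9)


class TestTargetGeometry:
    def test_perfect_recovery_zero_lengths(self, default_design):
        est_frame = pd.DataFrame(
            default_design.phi, index=list(default_design.component_ids),
            columns=list(default_design.mixture_ids),
        )
        from mixqc.deconvolution import ProportionEstimate

        geom = target_geometry(
            default_design, ProportionEstimate(est_frame, default_design)
        )
        assert geom.length_sum == 0.0

    def test_single_displaced_component(self, default_design):
        phi = default_design.phi.copy()
        est_frame = pd.DataFrame(
            phi, index=list(default_design.component_ids),
            columns=list(default_design.mixture_ids),
        )
        est_frame.loc["liver", "mix1"] = 0.30
        from mixqc.deconvolution import ProportionEstimate

        geom = target_geometry(
            default_design, ProportionEstimate(est_frame, default_design)
        )
        assert geom.lengths["liver"] == pytest.approx(0.05)
        assert geom.length_sum == pytest.approx(0.05)
        assert geom.length_sum >= geom.lengths.max()


class TestProportionUncertainty:
    def test_noise_free_ellipse_degenerates(self, default_design):
        rng = np.random.default_rng(24)
        profile = random_profile(rng, n=20)
        mixes = exact_mixtures(profile, default_design)
        unc = proportion_uncertainty(profile, mixes, default_design,
                                     n_boot=50, seed=0)
        for ell in unc.ellipses.values():
            # resampling variance collapses in the exact-fit limit
            assert np.abs(ell.cov).max() < 1e-12
            assert ell.degenerate

    def test_tiny_n_boot_rejected(self, default_design):
        rng = np.random.default_rng(25)
        profile = random_profile(rng)
        mixes = exact_mixtures(profile, default_design)
        with pytest.raises(ValueError, match="n_boot"):
            proportion_uncertainty(profile, mixes, default_design, n_boot=2)

    def test_deterministic_given_seed(self, default_design):
        rng = np.random.default_rng(26)
        profile = random_profile(rng, n=30)
        mixes = exact_mixtures(profile, default_design) * np.random.default_rng(
            1
        ).lognormal(0, 0.3, (30, 1))
        a = proportion_uncertainty(profile, mixes, default_design, n_boot=40, seed=5)
        b = proportion_uncertainty(profile, mixes, default_design, n_boot=40, seed=5)
        for comp in a.ellipses:
            np.testing.assert_array_equal(a.ellipses[comp].cov, b.ellipses[comp].cov)
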