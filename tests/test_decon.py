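import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodecon.core import (
    CellTypeHierarchy,
    ProportionSet,
    ReferenceBasis,
    build_reference_basis,
)
from bloodecon.decon import (
    FitResult,
    build_model,
    constrained_ls,
    deconvolute_full,
    estimate_main,
    estimate_subtypes,
    partition_profile,
    refine_pair,
)
from bloodecon.features import CpGPanel
from bloodecon.sim import (
    compose_mixture,
    default_simulation_spec,
    generate_synthetic_reference,
    simulate_truth,
)
from .conftest import make_beta
from ._oracles import grid_min_objective


class TestConstrainedLS:
    def test_pure_column_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 3))
        p = constrained_ls(X[:, 1], X)
        np.testing.assert_allclose(p, [0, 1, 0], atol=1e-8)

    def test_exact_mixture_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 2))
        y = 0.3 * X[:, 0] + 0.7 * X[:, 1]
        p = constrained_ls(y, X)
        np.testing.assert_allclose(p, [0.3, 0.7], atol=1e-6)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_objective_beats_simplex_grid(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((12, 3))
        y = rng.random(12) * 1.5  # push toward an active sum constraint
        p = constrained_ls(y, X)
        obj = float(((y - X @ p) ** 2).sum())
        assert obj <= grid_min_objective(X, y) + 1e-9

    def test_constraints_satisfied_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            d = rng.integers(2, 5)
            rows = rng.integers(d + 1, 16)
            X = rng.random((rows, d))
            y = rng.random(rows) * 2.0
            p = constrained_ls(y, X)
            assert (p >= -1e-12).all()
            assert p.sum() <= 1 + 1e-9

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_feasibility_and_convex_recovery(self, seed):
        """Solutions always satisfy the constraints, and any feasible
        convex combination of the columns is recovered exactly."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 5))
        X = rng.random((3 * d + 2, d))
        w = rng.dirichlet(np.ones(d)) * rng.uniform(0.3, 1.0)
        p = constrained_ls(X @ w, X)
        assert (p >= -1e-12).all() and p.sum() <= 1 + 1e-9
        np.testing.assert_allclose(p, w, atol=1e-5)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(2)
        X = rng.random((12, 2))
        y = 0.4 * X[:, 0] + 0.6 * X[:, 1]
        y[3] = np.nan
        p = constrained_ls(y, X)
        np.testing.assert_allclose(p, [0.4, 0.6], atol=1e-6)

    def test_too_few_rows_rejected(self):
        X = np.random.default_rng(0).random((3, 3))
        with pytest.raises(ValueError, match="usable rows"):
            constrained_ls(np.array([0.1, 0.2, 0.3]), X)

    def test_rank_deficient_warns(self):
        col = np.random.default_rng(0).random(8)
        X = np.column_stack([col, col])
        with pytest.warns(UserWarning, match="rank-deficient"):
            constrained_ls(col, X)


def _noise_free_setup(seed=11, n_cpgs=900, n_diff=40):
    hier = CellTypeHierarchy(["A", "B", "C"])
    ref = generate_synthetic_reference(
        n_cpgs, hier, n_diff_per_type=n_diff, n_samples_per_type=3,
        noise_sd=0.0, seed=seed,
    )
    basis, _ = build_reference_basis(ref.samples)
    planted = sorted(set().union(*ref.planted.values()))
    panel = CpGPanel(planted, ["anova"] * len(planted), m=len(planted), n=0)
    return hier, ref, basis, panel


class TestEstimateMain:
    def test_noise_free_weights_recovered(self):
        hier, ref, basis, panel = _noise_free_setup()
        rng = np.random.default_rng(1)
        W = rng.dirichlet(np.ones(3), size=8)
        mix = make_beta(
            basis.profiles @ W.T, cpg_ids=ref.cpg_ids,
            sample_ids=[f"m{j}" for j in range(8)],
        )
        fit = estimate_main(mix, basis, panel)
        np.testing.assert_allclose(fit.proportions.proportions, W, atol=1e-6)
        assert (fit.residual_norm < 1e-12).all()

    def test_pure_sample_gives_unit_vector(self):
        hier, ref, basis, panel = _noise_free_setup()
        mix = make_beta(
            basis.profiles[:, [0]], cpg_ids=ref.cpg_ids, sample_ids=["pure"]
        )
        fit = estimate_main(mix, basis, panel)
        np.testing.assert_allclose(
            fit.proportions.proportions[0], [1, 0, 0], atol=1e-8
        )

    def test_absent_panel_cpgs_rejected(self):
        hier, ref, basis, panel = _noise_free_setup()
        bad = CpGPanel(["nope1", "nope2", "nope3", "nope4"], ["anova"] * 4,
                       m=4, n=0)
        with pytest.raises((ValueError, KeyError)):
            estimate_main(
                make_beta(basis.profiles[:, [0]], cpg_ids=ref.cpg_ids),
                basis, bad,
            )


class TestPartitionProfile:
    def test_zero_excluded_estimates_is_identity(self):
        hier, ref, basis, panel = _noise_free_setup()
        mix = make_beta(
            basis.profiles[:, [0]], cpg_ids=ref.cpg_ids, sample_ids=["m0"]
        )
        fit = estimate_main(mix, basis, panel)  # pure A: B and C are 0
        part = partition_profile(mix, basis, fit, keep={"A"})
        np.testing.assert_allclose(
            part.to_numpy().ravel(), mix.values.ravel(), atol=1e-8
        )

    def test_algebraic_identity_on_noise_free_mixture(self):
        hier, ref, basis, panel = _noise_free_setup()
        W = np.array([[0.5, 0.3, 0.2]])
        mix = make_beta(
            basis.profiles @ W.T, cpg_ids=ref.cpg_ids, sample_ids=["m0"]
        )
        fit = estimate_main(mix, basis, panel)
        part = partition_profile(mix, basis, fit, keep={"A", "B"})
        expected = basis.profiles[:, :2] @ W[:, :2].T
        np.testing.assert_allclose(part.to_numpy(), expected, atol=1e-6)

    def test_matches_direct_recomputation(self):
        hier, ref, basis, panel = _noise_free_setup()
        rng = np.random.default_rng(4)
        mix = make_beta(
            rng.random((basis.profiles.shape[0], 2)), cpg_ids=ref.cpg_ids,
            sample_ids=["m0", "m1"],
        )
        fit = estimate_main(mix, basis, panel)
        part = partition_profile(mix, basis, fit, keep={"C"})
        P = fit.proportions.to_frame()[["A", "B"]].to_numpy()
        expected = mix.values - basis.profiles[:, :2] @ P.T
        np.testing.assert_allclose(part.to_numpy(), expected, atol=1e-12)

    def test_keep_must_be_strict_subset(self):
        hier, ref, basis, panel = _noise_free_setup()
        mix = make_beta(basis.profiles[:, [0]], cpg_ids=ref.cpg_ids)
        fit = estimate_main(mix, basis, panel)
        with pytest.raises(ValueError):
            partition_profile(mix, basis, fit, keep=set())
        with pytest.raises(ValueError):
            partition_profile(mix, basis, fit, keep={"A", "B", "C"})


def _pair_fixture(seed=13):
    """Mixture that is exactly 0.2*X_A + 0.2*X_B, with a fabricated main
    fit claiming (0.15, 0.15) for the pair and zero for the third type."""
    hier, ref, basis, panel = _noise_free_setup(seed=seed)
    mix_vals = 0.2 * basis.profiles[:, 0] + 0.2 * basis.profiles[:, 1]
    mix = make_beta(mix_vals[:, None], cpg_ids=ref.cpg_ids, sample_ids=["m0"])
    main_fit = FitResult(
        proportions=ProportionSet(["m0"], ["A", "B", "C"], [[0.15, 0.15, 0.0]]),
        residual_norm=pd.Series([0.0], index=["m0"]),
        panel_used=panel,
        stage="main",
    )
    pair_basis = basis.select_types(["A", "B"])
    pair_planted = sorted(set(ref.planted["A"]) | set(ref.planted["B"]))
    pair_panel = CpGPanel(
        pair_planted, [f"pair:A-B"] * len(pair_planted), m=0, n=len(pair_planted)
    )
    return hier, ref, basis, pair_basis, pair_panel, mix, main_fit


class TestRefinePair:
    def test_rescale_matches_stated_rule(self):
        # second-stage fit recovers (0.2, 0.2); main pair sum is 0.3,
        # so the refined estimates are (0.15, 0.15)
        hier, ref, basis, pair_basis, pair_panel, mix, main_fit = _pair_fixture()
        fit = refine_pair(mix, basis, pair_basis, main_fit, pair_panel)
        out = fit.proportions.to_frame().loc["m0"]
        assert out["A"] == pytest.approx(0.15, abs=1e-8)
        assert out["B"] == pytest.approx(0.15, abs=1e-8)
        assert out["C"] == 0.0

    def test_already_consistent_estimates_unchanged(self):
        hier, ref, basis, pair_basis, pair_panel, mix, main_fit = _pair_fixture()
        main_fit.proportions.proportions[0] = [0.2, 0.2, 0.0]
        fit = refine_pair(mix, basis, pair_basis, main_fit, pair_panel)
        out = fit.proportions.to_frame().loc["m0"]
        assert out["A"] == pytest.approx(0.2, abs=1e-8)
        assert out["B"] == pytest.approx(0.2, abs=1e-8)

    def test_zero_refit_falls_back_to_main(self):
        hier, ref, basis, pair_basis, pair_panel, mix, main_fit = _pair_fixture()
        zero_mix = make_beta(
            np.zeros((len(ref.cpg_ids), 1)), cpg_ids=ref.cpg_ids,
            sample_ids=["m0"],
        )
        with pytest.warns(UserWarning, match="identically zero"):
            fit = refine_pair(zero_mix, basis, pair_basis, main_fit, pair_panel)
        out = fit.proportions.to_frame().loc["m0"]
        assert out["A"] == pytest.approx(0.15)
        assert out["B"] == pytest.approx(0.15)

    def test_non_target_types_untouched(self):
        hier, ref, basis, pair_basis, pair_panel, mix, main_fit = _pair_fixture()
        main_fit.proportions.proportions[0] = [0.1, 0.1, 0.37]
        fit = refine_pair(mix, basis, pair_basis, main_fit, pair_panel)
        assert fit.proportions.to_frame().loc["m0", "C"] == 0.37


class TestDeconvoluteFull:
    @pytest.fixture(scope="class")
    def noise_free_study(self, hierarchy):
        ref = generate_synthetic_reference(
            3000, hierarchy, n_diff_per_type=80, n_samples_per_type=4,
            noise_sd=0.0, seed=19,
        )
        bases, panels = build_model(
            ref.samples, hierarchy, m=480, n=40, pair_n=160,
            subtype_m=240, subtype_n=0, two_subtype_n=160,
        )
        return ref, bases, panels

    def test_noise_free_nested_truth_recovered_exactly(
        self, hierarchy, noise_free_study
    ):
        ref, bases, panels = noise_free_study
        rng = np.random.default_rng(20)
        spec = default_simulation_spec(n_samples=12)
        truth = simulate_truth(spec, rng, hierarchy)
        mix = compose_mixture(truth, ref.samples, rng, hierarchy)
        res = deconvolute_full(mix, bases, panels, hierarchy)
        est = res.table.to_frame()
        tm = truth.main.to_frame()
        ts = truth.merged_subtypes(hierarchy).to_frame()
        assert np.abs(est[tm.columns] - tm).to_numpy().max() < 1e-6
        assert np.abs(est[ts.columns] - ts).to_numpy().max() < 1e-6

    def test_zero_b_cells_give_zero_b_subtypes(
        self, hierarchy, noise_free_study
    ):
        ref, bases, panels = noise_free_study
        rng = np.random.default_rng(21)
        spec = default_simulation_spec(n_samples=4)
        spec.main_params["CD19"] = (0.0, 0.0)
        truth = simulate_truth(spec, rng, hierarchy)
        mix = compose_mixture(truth, ref.samples, rng, hierarchy)
        res = deconvolute_full(mix, bases, panels, hierarchy)
        est = res.table.to_frame()
        assert (est[["CD19", "Bnaive", "Bmem"]].to_numpy() < 1e-6).all()

    def test_subtype_sums_equal_parent_estimates(
        self, hierarchy, noise_free_study
    ):
        ref, bases, panels = noise_free_study
        rng = np.random.default_rng(22)
        spec = default_simulation_spec(n_samples=6)
        truth = simulate_truth(spec, rng, hierarchy)
        mix = compose_mixture(truth, ref.samples, rng, hierarchy)
        res = deconvolute_full(mix, bases, panels, hierarchy)
        est = res.table.to_frame()
        refined = res.fits["pair:CD4-CD8"].proportions.to_frame()
        for parent, cols in [
            ("CD4", ["Tmem", "Tnaive", "Treg"]),
            ("CD8", ["CD8naive", "CD8mem"]),
            ("CD19", ["Bnaive", "Bmem"]),
        ]:
            np.testing.assert_allclose(
                est[cols].sum(axis=1), refined[parent], atol=1e-12
            )


class TestEstimateSubtypesSortedMode:
    def test_pure_parent_sample_subtype_recovery(self, hierarchy):
        # a sorted CD4 sample that is 100% Tnaive
        ref = generate_synthetic_reference(
            1500, hierarchy, n_diff_per_type=40, n_samples_per_type=3,
            noise_sd=0.0, seed=23,
        )
        bases, panels = build_model(
            ref.samples, hierarchy, m=240, n=20, pair_n=80,
            subtype_m=120, subtype_n=0, two_subtype_n=80,
        )
        mix = make_beta(
            ref.profiles["Tnaive"][:, None], cpg_ids=ref.cpg_ids,
            sample_ids=["pure"],
        )
        res = deconvolute_full(mix, bases, panels, hierarchy)
        est = res.table.to_frame().loc["pure"]
        assert est["CD4"] == pytest.approx(1.0, abs=1e-6)
        assert est["Tnaive"] == pytest.approx(1.0, abs=1e-6)
        assert est["Tmem"] == pytest.approx(0.0, abs=1e-6)
        assert est["Treg"] == pytest.approx(0.0, abs=1e-6)

    def test_unknown_parent_rejected(self, hierarchy):
        hier, ref, basis, panel = _noise_free_setup()
        mix = make_beta(basis.profiles[:, [0]], cpg_ids=ref.cpg_ids)
        fit = estimate_main(mix, basis, panel)
        with pytest.raises(ValueError, match="unknown parent"):
            estimate_subtypes(
                mix, basis, basis.select_types(["A", "B"]), fit, panel,
                parent="XX",
            )
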