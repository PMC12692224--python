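"""Scheffe model matrix construction, OLS fitting, prediction and ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermix.mixture_design import augment_design, generate_simplex_lattice, validate_composition
from fermix.scheffe import (
    InsufficientDataError,
    ResponseTable,
    ScheffeModel,
    SingularDesignError,
    anova,
    build_model_matrix,
    fit_scheffe,
    model_from_json,
    model_to_json,
    predict,
    predict_many,
    response_table_from_csv,
    response_table_to_csv,
    term_names,
)
from fermix.synthetic import SyntheticSpec, gen_mixture_responses


def normal_equations_fit(X, y):
    """Independent oracle: direct solve of X'X b = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def make_table(model, noise_sd=0.0, replicates=1, seed=0, degree=3, centroid=True):
    design = generate_simplex_lattice(3, degree)
    if centroid:
        design = augment_design(design, centroid=True)
    spec = SyntheticSpec(
        true_model=model, design=design, noise_sd=noise_sd,
        replicates=replicates, seed=seed,
    )
    return gen_mixture_responses(spec)


class TestModelMatrix:
    def test_vertex_row(self):
        row = build_model_matrix([validate_composition((1, 0, 0))], "special_cubic")[0]
        assert np.array_equal(row, [1, 0, 0, 0, 0, 0, 0])

    def test_centroid_row(self):
        row = build_model_matrix([validate_composition([1 / 3] * 3)], "special_cubic")[0]
        expected = [1 / 3] * 3 + [1 / 9] * 3 + [1 / 27]
        assert np.allclose(row, expected, atol=1e-12)

    def test_edge_midpoint_row(self):
        row = build_model_matrix([validate_composition((0.5, 0.5, 0))], "special_cubic")[0]
        assert np.allclose(row, [0.5, 0.5, 0, 0.25, 0, 0, 0])

    def test_term_order_and_names(self):
        assert term_names(("X1", "X2", "X3"), "special_cubic") == [
            "X1", "X2", "X3", "X1*X2", "X1*X3", "X2*X3", "X1*X2*X3",
        ]

    def test_special_cubic_needs_three_components(self):
        with pytest.raises(ValueError):
            build_model_matrix([validate_composition((0.5, 0.5))], "special_cubic")


class TestPredict:
    def test_vertex_identity_exact(self, tpc_model, lactic_model):
        for model in (tpc_model, lactic_model):
            for i in range(3):
                e = np.zeros(3); e[i] = 1.0
                assert predict(model, e) == model.beta_linear[i]

    def test_published_tpc_centroid_value(self, tpc_model):
        # hand evaluation: 3.551/3 + 1.029/9 + 3.100/27
        expected = 3.551 / 3 + 1.029 / 9 + 3.100 / 27
        assert predict(model=tpc_model, x=[1 / 3] * 3) == pytest.approx(expected, abs=1e-12)

    def test_lactic_pure_third_strain(self, lactic_model):
        assert predict(lactic_model, (0, 0, 1)) == 4.215

    def test_dimension_mismatch(self, tpc_model):
        with pytest.raises(ValueError):
            predict(tpc_model, (0.5, 0.5))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, tpc_model, seed):
        rng = np.random.default_rng(seed)
        x = rng.dirichlet(np.ones(3))
        perm = rng.permutation(3)
        # permute the model's coefficients consistently with the components
        b1 = np.array(tpc_model.beta_linear)[perm]
        pairs = {frozenset(p): c for p, c in zip(
            [(0, 1), (0, 2), (1, 2)], tpc_model.beta_pair)}
        new_pairs = tuple(
            pairs[frozenset((perm[a], perm[b]))] for a, b in [(0, 1), (0, 2), (1, 2)]
        )
        permuted = ScheffeModel(
            q=3, order="special_cubic", beta_linear=tuple(b1),
            beta_pair=new_pairs, beta_triple=tpc_model.beta_triple,
        )
        # relabeled model evaluated on relabeled input gives the same prediction
        assert predict(permuted, x[perm]) == pytest.approx(predict(tpc_model, x), abs=1e-12)


class TestFit:
    def test_noise_free_recovery_exact(self, tpc_model):
        table = make_table(tpc_model, noise_sd=0.0)
        fitted, diag = fit_scheffe(table, "special_cubic")
        assert np.max(np.abs(fitted.coefficients - tpc_model.coefficients)) <= 1e-8
        assert diag.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle_random_designs(self, tpc_model):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(8, 20)
            pts = [validate_composition(p) for p in rng.dirichlet(np.ones(3), size=n)]
            from fermix.mixture_design import MixtureDesign

            design = MixtureDesign(q=3, m=0, points=tuple(pts))
            y = predict_many(tpc_model, design.as_matrix()) + rng.normal(0, 0.05, n)
            table = ResponseTable(design=design, response_name="y", values=tuple(y))
            fitted, _ = fit_scheffe(table, "special_cubic")
            X = build_model_matrix(design.as_matrix(), "special_cubic")
            oracle = normal_equations_fit(X, np.asarray(y))
            assert np.max(np.abs(fitted.coefficients - oracle)) <= 1e-8

    def test_noisy_fit_beats_nothing_and_close_to_truth(self, tpc_model):
        table = make_table(tpc_model, noise_sd=0.02, replicates=3, seed=7)
        fitted, diag = fit_scheffe(table, "special_cubic")
        # with SD 0.02 over 42 runs the coefficients stay in the right ballpark
        assert np.max(np.abs(np.array(fitted.beta_linear) - tpc_model.beta_linear)) < 0.1
        assert diag.r2 > 0.8

    def test_insufficient_rows(self, tpc_model):
        from fermix.mixture_design import MixtureDesign

        pts = tuple(generate_simplex_lattice(3, 2).points[:4])
        design = MixtureDesign(q=3, m=0, points=pts)
        table = ResponseTable(design=design, response_name="y", values=(1.0,) * 4)
        with pytest.raises(InsufficientDataError):
            fit_scheffe(table, "special_cubic")

    def test_singular_design_names_columns(self):
        from fermix.mixture_design import MixtureDesign

        # seven copies of compositions on one edge: ternary terms all zero
        edge = [(a, 1 - a, 0.0) for a in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)]
        design = MixtureDesign(
            q=3, m=0, points=tuple(validate_composition(e) for e in edge)
        )
        table = ResponseTable(design=design, response_name="y", values=(1.0,) * 7)
        with pytest.raises(SingularDesignError, match="X"):
            fit_scheffe(table, "special_cubic")


class TestAnova:
    def test_constant_response_zero_r2(self):
        design = augment_design(generate_simplex_lattice(3, 3), centroid=True)
        table = ResponseTable(
            design=design, response_name="y", values=(2.5,) * len(design)
        )
        _, diag = fit_scheffe(table, "special_cubic")
        assert diag.r2 == pytest.approx(0.0, abs=1e-9)

    def test_no_replicates_no_lack_of_fit(self, tpc_model):
        table = make_table(tpc_model, noise_sd=0.01, replicates=1, seed=1)
        diag = anova(tpc_model, table)
        assert diag.lof_f is None and diag.lof_p is None

    def test_replicates_give_lack_of_fit(self, tpc_model):
        table = make_table(tpc_model, noise_sd=0.02, replicates=3, seed=1)
        diag = anova(tpc_model, table)
        assert diag.lof_f is not None and 0.0 <= diag.lof_p <= 1.0

    def test_well_specified_model_is_significant(self, lactic_model):
        table = make_table(lactic_model, noise_sd=0.01, replicates=3, seed=2)
        _, diag = fit_scheffe(table, "special_cubic")
        assert diag.model_p < 0.05
        assert diag.adj_r2 <= diag.r2

    def test_mean_r2_decreases_with_noise(self, tpc_model):
        """Monte-Carlo: noisier synthetic data fit strictly worse on average."""
        r2 = {}
        for sd in (0.01, 0.2):
            vals = []
            for rep in range(100):
                table = make_table(tpc_model, noise_sd=sd, replicates=1, seed=1000 + rep)
                _, diag = fit_scheffe(table, "special_cubic")
                vals.append(diag.r2)
            r2[sd] = np.mean(vals)
        assert r2[0.01] > r2[0.2]


class TestSerialization:
    def test_model_json_roundtrip_bit_exact(self, tmp_path, tpc_model):
        path = tmp_path / "m.json"
        model_to_json(tpc_model, path)
        back = model_from_json(path)
        assert back.coefficients.tolist() == tpc_model.coefficients.tolist()
        assert back.units == tpc_model.units

    def test_response_csv_roundtrip(self, tmp_path, tpc_model):
        table = make_table(tpc_model, noise_sd=0.02, replicates=3, seed=5)
        path = tmp_path / "resp.csv"
        response_table_to_csv(table, path)
        back = response_table_from_csv(path)
        assert back.design.replicates == 3
        assert np.allclose(back.values, table.values)
        assert np.allclose(back.run_matrix(), table.run_matrix())
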