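"""Clock engine: mixture EM, BMIQ, deconvolution, correction, age transforms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from somnoclock.clock import (
    BetaMatrix,
    BmiqParams,
    CellReference,
    ClockModel,
    ProbeAnnotation,
    age_forward,
    age_inverse,
    bmiq_normalize,
    celltype_correct,
    clock_age,
    estimate_cell_proportions,
    fit_beta_mixture,
    read_beta_tsv,
    read_clock_csv,
    write_beta_tsv,
    write_clock_csv,
)
from somnoclock.errors import (
    DegenerateInputError,
    NoDataError,
    ValidationError,
)
from somnoclock.simulate import simulate_type_shift_batch


class TestBetaMixture:
    def test_recovers_known_three_state_mixture(self, rng):
        x = np.concatenate(
            [rng.beta(2, 20, 1000), rng.beta(5, 5, 1000), rng.beta(20, 2, 1000)]
        )
        mix = fit_beta_mixture(x)
        np.testing.assert_allclose(mix.means, [2 / 22, 0.5, 20 / 22], atol=0.05)
        np.testing.assert_allclose(mix.weights, [1 / 3] * 3, atol=0.05)

    def test_log_likelihood_monotone_and_responsibilities_normalised(self, rng):
        x = np.concatenate([rng.beta(1, 9, 400), rng.beta(9, 1, 400)])
        mix = fit_beta_mixture(x)
        assert np.all(np.diff(mix.ll_path) > -1e-6)
        np.testing.assert_allclose(mix.responsibilities.sum(axis=1), 1.0, atol=1e-12)

    def test_all_low_values_concentrate_mass_in_unmethylated_region(self, rng):
        # every observation below 0.05: the fitted mixture must place
        # essentially all its probability mass in the unmethylated region
        x = np.clip(rng.beta(2, 60, 500), 1e-6, 0.049)
        mix = fit_beta_mixture(x)
        from scipy.stats import beta as beta_dist

        mass_below = sum(
            w * beta_dist.cdf(0.1, a, b)
            for w, a, b in zip(mix.weights, mix.a, mix.b)
        )
        assert mass_below > 0.95
        assert mix.means.max() < 0.1

    def test_dominant_low_component_weight_recovered(self, rng):
        # 95/5 low/high mixture: the low states carry ~95% of the weight
        x = np.concatenate([rng.beta(2, 40, 950), rng.beta(40, 2, 50)])
        mix = fit_beta_mixture(x)
        low_weight = float(mix.weights[mix.means < 0.5].sum())
        assert low_weight == pytest.approx(0.95, abs=0.03)

    def test_input_guards(self, rng):
        with pytest.raises(ValidationError):
            fit_beta_mixture(rng.random(10))
        with pytest.raises(DegenerateInputError):
            fit_beta_mixture(np.array([0.2, 0.8] * 20))


def _two_type_matrix(t1, t2):
    probes = [f"a{i}" for i in range(len(t1))] + [f"b{i}" for i in range(len(t2))]
    ann = ProbeAnnotation(
        {p: ("I" if p.startswith("a") else "II") for p in probes}
    )
    bm = BetaMatrix(probes, ["s1"], np.concatenate([t1, t2])[:, None])
    return bm, ann


class TestBmiq:
    def test_reduces_type_distribution_gap(self):
        t1, t2 = simulate_type_shift_batch(3000, 3000, shift=0.25, seed=7)
        bm, ann = _two_type_matrix(t1, t2)
        out = bmiq_normalize(bm, ann)
        n1 = len(t1)
        ks_pre = ks_2samp(t1, t2).statistic
        ks_post = ks_2samp(t1, out.values[n1:, 0]).statistic
        assert ks_post < ks_pre

    def test_same_distribution_is_nearly_identity(self):
        t1, t2 = simulate_type_shift_batch(4000, 4000, shift=0.0, seed=11)
        bm, ann = _two_type_matrix(t1, t2)
        out = bmiq_normalize(bm, ann)
        moved = np.abs(out.values[len(t1):, 0] - t2)
        assert np.median(moved) < 0.02

    def test_type_one_probes_untouched_and_ranks_preserved(self):
        t1, t2 = simulate_type_shift_batch(2000, 2000, shift=0.2, seed=3)
        bm, ann = _two_type_matrix(t1, t2)
        out = bmiq_normalize(bm, ann)
        n1 = len(t1)
        np.testing.assert_array_equal(out.values[:n1, 0], t1)
        order_pre = np.argsort(np.argsort(t2))
        order_post = np.argsort(np.argsort(out.values[n1:, 0], kind="stable"))
        # a monotone within-state map cannot reorder probes within a state;
        # global rank changes only where transformed states interleave
        assert np.mean(order_pre == order_post) > 0.95
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_type_one_only_matrix_passthrough(self, rng):
        vals = rng.random((50, 2))
        bm = BetaMatrix([f"p{i}" for i in range(50)], ["s1", "s2"], vals)
        ann = ProbeAnnotation({f"p{i}": "I" for i in range(50)})
        with pytest.raises(ValidationError):
            bmiq_normalize(bm, ann)
        out = bmiq_normalize(bm, ann, BmiqParams(allow_passthrough=True))
        np.testing.assert_array_equal(out.values, vals)


def _toy_reference(rng, n_probes=60, k=3):
    R = rng.random((n_probes, k))
    probes = [f"cg{i}" for i in range(n_probes)]
    return CellReference(probes, [f"CT{j}" for j in range(k)], R)


def grid_search_proportions(R, x, step=0.01):
    """Oracle: exhaustive search over the sub-simplex grid (sum <= 1),
    renormalised to proportions — the same problem the estimator solves."""
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    W = np.array(
        [
            (w1, w2, w3)
            for w1 in ticks
            for w2 in ticks
            for w3 in ticks
            if w1 + w2 + w3 <= 1 + 1e-12
        ]
    )
    err = np.sum((W @ R.T - x) ** 2, axis=1)
    best = W[np.argmin(err)]
    return best / best.sum()


class TestDeconvolution:
    def test_pure_reference_column_recovered(self, rng):
        ref = _toy_reference(rng)
        bm = BetaMatrix(ref.probe_ids, ["s"], ref.values[:, [1]])
        props = estimate_cell_proportions(bm, ref)
        np.testing.assert_allclose(props.table.to_numpy()[0], [0, 1, 0], atol=1e-6)

    def test_noiseless_half_half_mixture_exact(self, rng):
        ref = _toy_reference(rng)
        x = 0.5 * ref.values[:, 0] + 0.5 * ref.values[:, 2]
        bm = BetaMatrix(ref.probe_ids, ["s"], x[:, None])
        props = estimate_cell_proportions(bm, ref)
        np.testing.assert_allclose(props.table.to_numpy()[0], [0.5, 0, 0.5], atol=1e-6)

    def test_agrees_with_simplex_grid_oracle_on_toy_problems(self, rng):
        for trial in range(5):
            R = rng.random((5, 3))
            w_true = rng.dirichlet([1, 1, 1])
            x = np.clip(R @ w_true + rng.normal(0, 0.02, 5), 0, 1)
            bm = BetaMatrix([f"cg{i}" for i in range(5)], ["s"],
                            np.clip(x, 0, 1)[:, None])
            ref = CellReference([f"cg{i}" for i in range(5)], list("abc"), R)
            est = estimate_cell_proportions(bm, ref).table.to_numpy()[0]
            oracle = grid_search_proportions(R, x)
            oracle = oracle / oracle.sum()
            np.testing.assert_allclose(est, oracle, atol=0.011)

    def test_noisy_mixture_recovered_within_tolerance(self, rng):
        R = rng.random((400, 3))
        w_true = np.array([0.2, 0.5, 0.3])
        x = np.clip(R @ w_true + rng.normal(0, 0.01, 400), 0, 1)
        probes = [f"cg{i}" for i in range(400)]
        bm = BetaMatrix(probes, ["s"], x[:, None])
        ref = CellReference(probes, list("abc"), R)
        est = estimate_cell_proportions(bm, ref).table.to_numpy()[0]
        np.testing.assert_allclose(est, w_true, atol=0.05)

    def test_rank_deficient_reference_names_collinear_types(self, rng):
        R = rng.random((20, 2))
        R3 = np.column_stack([R, R[:, 1]])
        ref = CellReference([f"cg{i}" for i in range(20)], ["a", "b", "b_copy"], R3)
        bm = BetaMatrix(ref.probe_ids, ["s"], R3[:, [0]])
        with pytest.raises(ValidationError, match="b.*b_copy"):
            estimate_cell_proportions(bm, ref)

    def test_too_few_shared_probes(self, rng):
        ref = _toy_reference(rng, n_probes=60)
        bm = BetaMatrix(["cg0", "other"], ["s"], rng.random((2, 1)))
        with pytest.raises(NoDataError):
            estimate_cell_proportions(bm, ref)


class TestCellTypeCorrection:
    def _props(self, P, ctypes=("a", "b", "c")):
        import pandas as pd
        from somnoclock.clock import CellProportions

        return CellProportions(
            pd.DataFrame(P, index=[f"s{i}" for i in range(len(P))], columns=ctypes)
        )

    def test_identical_proportions_are_a_noop(self, rng):
        # constant composition offers no removable between-sample variance
        S = 6
        vals = rng.random((10, S))
        bm = BetaMatrix([f"p{i}" for i in range(10)], [f"s{i}" for i in range(S)], vals)
        out = celltype_correct(bm, self._props(np.tile([0.3, 0.3, 0.4], (S, 1))))
        np.testing.assert_allclose(out.values, vals, atol=1e-10)

    def test_too_few_samples_errors(self, rng):
        vals = rng.random((10, 3))
        bm = BetaMatrix([f"p{i}" for i in range(10)], ["s0", "s1", "s2"], vals)
        with pytest.raises(ValidationError):
            celltype_correct(bm, self._props(np.tile([0.3, 0.3, 0.4], (3, 1))))

    def test_exactly_linear_betas_become_constant(self, rng):
        S = 8
        P = rng.dirichlet([3, 3, 3], size=S)
        coef = rng.normal(0, 0.2, (3,))
        y = 0.5 + P @ coef  # one probe, exactly linear in composition
        bm = BetaMatrix(["p0"], [f"s{i}" for i in range(S)],
                        np.clip(y, 0, 1)[None, :])
        out = celltype_correct(bm, self._props(P))
        expected = 0.5 + P.mean(axis=0) @ coef
        np.testing.assert_allclose(out.values[0], expected, atol=1e-10)

    def test_output_clamped_to_unit_interval(self, rng):
        S = 12
        P = rng.dirichlet([2, 2, 2], size=S)
        vals = rng.random((30, S))
        bm = BetaMatrix([f"p{i}" for i in range(30)], [f"s{i}" for i in range(S)], vals)
        out = celltype_correct(bm, self._props(P))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0


class TestAgeTransform:
    def test_branch_values(self):
        assert age_forward(20.0, 20.0) == pytest.approx(0.0)
        assert age_forward(41.0, 20.0) == pytest.approx(1.0)
        assert age_forward(0.0, 20.0) == pytest.approx(-np.log(21.0))
        assert age_inverse(0.0, 20.0) == pytest.approx(20.0)
        assert age_inverse(1.0, 20.0) == pytest.approx(41.0)

    def test_round_trip_identity_over_age_grid(self):
        ages = np.linspace(-0.9, 120.0, 1000)
        np.testing.assert_allclose(age_inverse(age_forward(ages), 20.0), ages, atol=1e-9)

    def test_strictly_increasing_and_continuous_at_branch(self):
        ages = np.linspace(0, 60, 601)
        m = age_forward(ages)
        assert np.all(np.diff(m) > 0)
        assert age_forward(20.0 - 1e-9) == pytest.approx(age_forward(20.0 + 1e-9), abs=1e-6)

    def test_age_must_exceed_minus_one(self):
        with pytest.raises(ValidationError):
            age_forward(-1.0)


class TestClockAge:
    def test_intercept_only_clock(self):
        bm = BetaMatrix(["p0"], ["s1", "s2"], np.array([[0.3, 0.7]]))
        clock = ClockModel(intercept=age_forward(30.0), weights={"p0": 0.0})
        assert clock_age(bm, clock).tolist() == pytest.approx([30.0, 30.0])

    def test_single_probe_linear_branch(self):
        bm = BetaMatrix(["p0"], ["s1"], np.array([[0.5]]))
        clock = ClockModel(intercept=0.0, weights={"p0": 1.0}, adult_age=20.0)
        assert clock_age(bm, clock)["s1"] == pytest.approx(30.5)

    def test_missing_weighted_probe_errors_with_names(self):
        bm = BetaMatrix(["p0"], ["s1"], np.array([[0.5]]))
        clock = ClockModel(intercept=0.0, weights={"p0": 1.0, "pX": 2.0})
        with pytest.raises(ValidationError, match="pX"):
            clock_age(bm, clock)

    def test_monotone_in_positively_weighted_probe(self):
        clock = ClockModel(intercept=0.0, weights={"p0": 1.0, "p1": -0.5})
        lo = clock_age(BetaMatrix(["p0", "p1"], ["s"], np.array([[0.2], [0.5]])), clock)
        hi = clock_age(BetaMatrix(["p0", "p1"], ["s"], np.array([[0.6], [0.5]])), clock)
        assert hi["s"] > lo["s"]


def test_beta_and_clock_file_round_trip(tmp_path, rng):
    bm = BetaMatrix([f"p{i}" for i in range(5)], ["s1", "s2"], rng.random((5, 2)))
    write_beta_tsv(bm, tmp_path / "b.tsv")
    back = read_beta_tsv(tmp_path / "b.tsv")
    assert back.probe_ids == bm.probe_ids and back.sample_ids == bm.sample_ids
    np.testing.assert_allclose(back.values, bm.values)
    clock = ClockModel(intercept=0.7, weights={"p0": 1.5, "p3": -0.2}, adult_age=18.0)
    write_clock_csv(clock, tmp_path / "c.csv")
    back_clock = read_clock_csv(tmp_path / "c.csv")
    assert back_clock.intercept == clock.intercept
    assert back_clock.adult_age == clock.adult_age
    assert back_clock.weights == clock.weights


def test_beta_matrix_validation(rng):
    with pytest.raises(ValidationError):
        BetaMatrix(["p", "p"], ["s"], np.array([[0.1], [0.2]]))
    with pytest.raises(ValidationError):
        BetaMatrix(["p"], ["s"], np.array([[1.2]]))
    with pytest.raises(ValidationError):
        BetaMatrix(["p"], ["s"], np.array([[np.nan]]))
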