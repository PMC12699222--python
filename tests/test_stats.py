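"""Group-level statistics: condition means, mixed ANOVA, t-tests, Spearman."""

import numpy as np
import pandas as pd
import pytest

from cuehgf import cohort, design, stats
from cuehgf.stats import (
    gg_epsilon,
    mauchly_test,
    mixed_anova,
    one_sample_t,
    rt_condition_means,
    spearman,
    t_from_summary,
    two_sample_t,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle for the balanced mixed ANOVA:
# orthonormal Kronecker bases of the effect subspaces; SS = ||B' y||^2
# ---------------------------------------------------------------------------


def _mean_basis(k):
    return np.full((k, 1), 1.0 / np.sqrt(k))


def _contrast_basis(k):
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q[:, : k - 1]


def anova_oracle(Y):
    """SS per effect for Y with shape (groups a, subjects n, b, c)."""
    a, n, b, c = Y.shape
    y = Y.reshape(-1)
    Ja, Ka = _mean_basis(a), _contrast_basis(a)
    Jn, Kn = _mean_basis(n), _contrast_basis(n)
    Jb, Kb = _mean_basis(b), _contrast_basis(b)
    Jc, Kc = _mean_basis(c), _contrast_basis(c)
    Ia = np.eye(a)
    bases = {
        "group": (Ka, Jn, Jb, Jc),
        "subj(group)": (Ia, Kn, Jb, Jc),
        "validity": (Ja, Jn, Kb, Jc),
        "group*validity": (Ka, Jn, Kb, Jc),
        "validity*subj(group)": (Ia, Kn, Kb, Jc),
        "predictability": (Ja, Jn, Jb, Kc),
        "group*predictability": (Ka, Jn, Jb, Kc),
        "predictability*subj(group)": (Ia, Kn, Jb, Kc),
        "validity*predictability": (Ja, Jn, Kb, Kc),
        "group*validity*predictability": (Ka, Jn, Kb, Kc),
        "validity*predictability*subj(group)": (Ia, Kn, Kb, Kc),
    }
    out = {}
    for name, mats in bases.items():
        B = np.kron(np.kron(np.kron(mats[0], mats[1]), mats[2]), mats[3])
        out[name] = float(np.sum((B.T @ y) ** 2))
    return out


def long_table(Y):
    a, n, b, c = Y.shape
    rows = []
    for g in range(a):
        for s in range(n):
            for j in range(b):
                for k in range(c):
                    rows.append({"subject": f"g{g}s{s}", "validity": j,
                                 "p_valid": (0.5, 0.7, 0.9)[k],
                                 "mean_rt_s": Y[g, s, j, k]})
    groups = {f"g{g}s{s}": f"group{g}" for g in range(a) for s in range(n)}
    return pd.DataFrame(rows), groups


class TestConditionMeans:
    def test_constant_rt_all_cells(self, canonical_seq):
        beh = pd.DataFrame({
            "trial_index": canonical_seq["trial_index"],
            "validity": canonical_seq["validity"],
            "rt_s": 0.4, "rs": 2.5, "correct": 1, "missed": 0,
        })
        cells = rt_condition_means(beh, canonical_seq)
        assert np.allclose(cells["mean_rt_s"], 0.4)
        assert np.allclose(cells["accuracy_pct"], 100.0)

    def test_incorrect_trial_excluded_from_rt(self, canonical_seq):
        beh = pd.DataFrame({
            "trial_index": canonical_seq["trial_index"],
            "validity": canonical_seq["validity"],
            "rt_s": 0.4, "rs": 2.5, "correct": 1, "missed": 0,
        })
        beh.loc[0, ["correct", "rt_s"]] = [0, 99.0]
        cells = rt_condition_means(beh, canonical_seq)
        assert np.allclose(cells["mean_rt_s"], 0.4)

    def test_control_cohort_shows_validity_effect_at_high_predictability(self):
        subs = cohort.generate_cohort(cohort.default_cohort_config(10, 21))
        controls = {s.subject_id: s.behavior for s in subs if s.group == "control"}
        cells = rt_condition_means(controls, subs[0].sequence)
        by = cells.groupby(["validity", "p_valid"])["mean_rt_s"].mean()
        assert by[(0, 0.9)] > by[(1, 0.9)]

    def test_low_accuracy_flagging(self, canonical_seq):
        behaviors = {}
        rng = np.random.default_rng(0)
        for i in range(12):
            correct = (rng.uniform(size=len(canonical_seq)) > 0.03).astype(int)
            if i == 0:
                correct = (rng.uniform(size=len(canonical_seq)) > 0.4).astype(int)
            behaviors[f"s{i}"] = pd.DataFrame({
                "trial_index": canonical_seq["trial_index"],
                "validity": canonical_seq["validity"],
                "rt_s": 0.4, "rs": 2.5, "correct": correct, "missed": 0,
            })
        cells = rt_condition_means(behaviors, canonical_seq)
        flagged = cells.groupby("subject")["low_accuracy"].first()
        assert flagged["s0"] and not flagged.drop("s0").any()


class TestMixedAnova:
    def test_matches_projection_oracle_on_handcrafted_data(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(0.45, 0.05, size=(2, 4, 2, 3))
        Y[1] += 0.03  # group offset
        Y[:, :, 1, :] += 0.02  # validity effect
        cells, groups = long_table(Y)
        table = mixed_anova(cells, groups).set_index("effect")
        oracle = anova_oracle(Y)
        for effect in table.index:
            assert table.loc[effect, "SS"] == pytest.approx(
                oracle[effect], abs=1e-10)
            assert table.loc[effect, "error_SS"] == pytest.approx(
                oracle[table.loc[effect, "error_term"]], abs=1e-10)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((2, 6, 2, 3))
        oracle = anova_oracle(Y)
        grand = Y.mean()
        total = float(np.sum((Y - grand) ** 2))
        assert sum(oracle.values()) == pytest.approx(total, abs=1e-10)

    def test_all_equal_cells_give_zero_F(self):
        Y = np.full((2, 4, 2, 3), 0.4)
        cells, groups = long_table(Y)
        table = mixed_anova(cells, groups)
        assert (table["F"] == 0).all()
        assert (table["p"] == 1).all()

    def test_two_level_factor_epsilon_is_one(self):
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((2, 6, 2, 3))
        cells, groups = long_table(Y)
        table = mixed_anova(cells, groups,
                            sphericity_correction="always").set_index("effect")
        assert table.loc["validity", "gg_epsilon"] == 1.0

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            Y = rng.standard_normal((2, 5, 2, 3))
            cells, groups = long_table(Y)
            table = mixed_anova(cells, groups, sphericity_correction="always")
            eps = table.set_index("effect").loc["predictability", "gg_epsilon"]
            assert 1.0 / 2.0 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_compound_symmetry_gives_epsilon_one(self):
        # contrast covariance of a compound-symmetric matrix is spherical
        k = 3
        S_cells = 0.4 * np.eye(k) + 0.6
        C = stats._orthonormal_contrasts(k)
        assert gg_epsilon(C @ S_cells @ C.T) == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.standard_normal((12, 3)), columns=list("abc"))
        expected = float(pingouin.epsilon(data, correction="gg"))
        Z = data.to_numpy()[None, :, :]  # one group
        C = stats._orthonormal_contrasts(3)
        scores = Z @ C.T
        centered = scores - scores.mean(axis=1, keepdims=True)
        S = centered[0].T @ centered[0] / (len(data) - 1)
        assert gg_epsilon(S) == pytest.approx(expected, abs=1e-8)

    def test_mauchly_identity_covariance_accepts_sphericity(self):
        W, p = mauchly_test(np.eye(2), n_error_df=20)
        assert W == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_missing_cell_raises(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((2, 4, 2, 3))
        cells, groups = long_table(Y)
        cells = cells.iloc[1:]
        with pytest.raises(ValueError, match="missing cells"):
            mixed_anova(cells, groups)


class TestTTests:
    def test_symmetric_values_give_t0(self):
        res = one_sample_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_identical_samples_give_t0(self):
        x = [1.0, 2.0, 3.0]
        assert two_sample_t(x, list(x)).t == 0.0

    def test_one_sample_matches_textbook_formula(self):
        x = np.array([0.3, 0.5, 0.2, 0.6, 0.4])
        res = one_sample_t(x)
        manual_t = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(manual_t, abs=1e-12)
        assert res.df == 4

    def test_summary_t_closed_form(self):
        res = t_from_summary(1.0, 1.0, 30, 0.0, 1.0, 30)
        assert res.t == pytest.approx(np.sqrt(15), abs=1e-12)
        assert res.df == 58

    def test_summary_t_equals_raw_two_sample(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(1, 2, 20), rng.normal(0, 1.5, 25)
        raw = two_sample_t(a, b)
        summ = t_from_summary(a.mean(), a.std(ddof=1), 20,
                              b.mean(), b.std(ddof=1), 25)
        assert summ.t == pytest.approx(raw.t, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)

    def test_identical_summaries_give_t0(self):
        assert t_from_summary(5.0, 2.0, 10, 5.0, 2.0, 10).t == 0.0

    def test_zero_variance_nonzero_mean(self):
        res = one_sample_t([2.0, 2.0, 2.0])
        assert res.p < 1e-300


class TestSpearman:
    def test_monotone_increasing_rho_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 35, 40, 80])
        assert rho == pytest.approx(1.0)

    def test_reversed_rho_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [80, 40, 35, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0])
        # midranks by hand: x -> 1, 2.5, 2.5, 4, 5, 6 ; y -> 2, 1, 3.5, 3.5, 6, 5
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        ry = np.array([2.0, 1.0, 3.5, 3.5, 6.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])
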