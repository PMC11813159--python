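import itertools

import numpy as np
import pytest
from scipy import stats as sps

from fruitspec.spectra import TraitTable
from fruitspec.stats import (
    anova_oneway,
    describe_by_stage,
    duncan_mrt,
    pearson_matrix,
)


# ---------------------------------------------------------------------------
# Independent Duncan oracle: recursive underlining over consecutive spans
# ---------------------------------------------------------------------------

def duncan_pairwise_oracle(values, groups, alpha=0.05):
    """Which group pairs differ, by the classical recursive procedure: test
    the full span; if non-significant stop (underline all); otherwise recurse
    into the two spans dropping one extreme mean each."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = list(dict.fromkeys(groups))
    means = np.array([values[groups == g].mean() for g in labels])
    sizes = np.array([np.sum(groups == g) for g in labels], dtype=float)
    order = np.argsort(-means, kind="stable")
    labels = [labels[i] for i in order]
    means, sizes = means[order], sizes[order]

    a = anova_oneway(values, groups)
    g = len(labels)
    not_different: set[tuple[int, int]] = set()

    def critical(i, j):
        p = j - i + 1
        alpha_p = 1 - (1 - alpha) ** (p - 1)
        n_h = p / np.sum(1.0 / sizes[i:j + 1])
        q = sps.studentized_range.ppf(1 - alpha_p, p, a.df_error)
        return q * np.sqrt(a.ms_within / n_h)

    def visit(i, j):
        if i >= j:
            return
        if a.ms_within == 0:
            significant = means[i] != means[j]
        else:
            significant = (means[i] - means[j]) > critical(i, j)
        if not significant:
            for x, yy in itertools.combinations(range(i, j + 1), 2):
                not_different.add((x, yy))
            return
        visit(i + 1, j)
        visit(i, j - 1)

    visit(0, g - 1)
    differs = {}
    for x, yy in itertools.combinations(range(g), 2):
        differs[(labels[x], labels[yy])] = (x, yy) not in not_different
    return differs


def letters_to_pairwise(letters: dict[str, str]) -> dict[tuple[str, str], bool]:
    labs = list(letters)
    out = {}
    for a, b in itertools.combinations(labs, 2):
        out[(a, b)] = not (set(letters[a]) & set(letters[b]))
    return out


class TestAnova:
    def test_equal_group_means_give_zero_F(self):
        res = anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_within_variance_separated_means(self):
        res = anova_oneway([0, 0, 0, 10, 10, 10], ["a"] * 3 + ["b"] * 3)
        assert np.isinf(res.F)
        assert res.p == 0.0

    def test_all_identical_F_undefined(self):
        res = anova_oneway([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert np.isnan(res.F)

    def test_sums_of_squares_against_hand_computation(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=20)
        groups = np.array(["a", "b", "c", "d"] * 5)
        res = anova_oneway(values, groups)
        grand = values.mean()
        ss_b = sum((values[groups == g].size) * (values[groups == g].mean() - grand) ** 2
                   for g in "abcd")
        ss_w = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                   for g in "abcd")
        assert res.ss_between == pytest.approx(ss_b, rel=1e-12)
        assert res.ss_within == pytest.approx(ss_w, rel=1e-12)
        assert res.ss_total == pytest.approx(ss_b + ss_w, rel=1e-9)
        F, p = sps.f_oneway(*[values[groups == g] for g in "abcd"])
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)


class TestDuncan:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 10)
        values = np.concatenate([base, base + 0.01, base - 0.01])
        groups = ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10
        res = duncan_mrt(values, groups)
        assert set(res.letters.values()) == {"a"}

    def test_extreme_separation_letters_descending_mean_convention(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 0.1, 10),
                                 rng.normal(10, 0.1, 10),
                                 rng.normal(20, 0.1, 10)])
        groups = ["low"] * 10 + ["mid"] * 10 + ["high"] * 10
        res = duncan_mrt(values, groups)
        assert res.letters == {"high": "a", "mid": "b", "low": "c"}

    def test_letters_match_span_enumeration_oracle(self):
        """Letter partitions agree with the recursive span oracle over many
        random instances with 3-5 groups of up to 10 observations."""
        rng = np.random.default_rng(42)
        for trial in range(60):
            g = int(rng.integers(3, 6))
            sizes = rng.integers(3, 11, size=g)
            spread = rng.uniform(0.2, 4.0)
            values, groups = [], []
            for gi in range(g):
                mu = rng.uniform(0, 10)
                values.append(rng.normal(mu, spread, sizes[gi]))
                groups += [f"g{gi}"] * sizes[gi]
            values = np.concatenate(values)
            res = duncan_mrt(values, groups)
            assert letters_to_pairwise(res.letters) == \
                duncan_pairwise_oracle(values, groups), f"trial {trial}"

    def test_letters_order_consistent(self):
        """If two groups share a letter, any group with intermediate mean
        shares it too."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            values = rng.normal(0, 2, 40)
            groups = np.repeat([f"g{i}" for i in range(4)], 10)
            res = duncan_mrt(values, groups)
            means = res.group_means
            labs = list(means)
            for a, b in itertools.combinations(labs, 2):
                shared = set(res.letters[a]) & set(res.letters[b])
                if not shared:
                    continue
                for c in labs:
                    if min(means[a], means[b]) < means[c] < max(means[a], means[b]):
                        assert set(res.letters[c]) & shared

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 8),
                                 rng.normal(2.4, 1, 8)])
        groups = np.repeat(["g1", "g2", "g3"], 8)
        n_letters = []
        for alpha in (1e-6, 0.05, 0.9999):
            res = duncan_mrt(values, groups, alpha=alpha)
            n_letters.append(len(set("".join(res.letters.values()))))
        assert n_letters[0] <= n_letters[1] <= n_letters[2]
        assert n_letters[0] == 1  # alpha -> 0: all share one letter
        assert n_letters[2] == 3  # alpha -> 1: all separate


class TestDescribeByStage:
    def test_arithmetic_on_simple_values(self):
        t = TraitTable(
            sample_ids=[f"s{i}" for i in range(9)],
            stage=["unripe"] * 3 + ["ripe"] * 3 + ["overripe"] * 3,
            traits={"TSS": np.array([2.0, 4, 6, 12, 14, 16, 22, 24, 26])},
        )
        out = describe_by_stage(t, "TSS")
        row = out[out.stage == "unripe"].iloc[0]
        assert (row["min"], row["max"], row["mean"]) == (2.0, 6.0, 4.0)
        assert row["sd"] == pytest.approx(2.0)  # sample SD
        assert list(out.stage) == ["unripe", "ripe", "overripe"]
        # clear separation: letters follow the largest-mean-is-a convention
        assert out.set_index("stage").letter.to_dict() == {
            "unripe": "c", "ripe": "b", "overripe": "a"}

    def test_single_sample_stage_warns_sd_zero(self):
        t = TraitTable(
            sample_ids=["a", "b", "c", "d", "e"],
            stage=["unripe", "ripe", "ripe", "ripe", "ripe"],
            traits={"TSS": np.array([1.0, 2.0, 3.0, 4.0, 5.0])},
        )
        with pytest.warns(UserWarning, match="single sample"):
            out = describe_by_stage(t, "TSS")
        assert out[out.stage == "unripe"].iloc[0]["sd"] == 0.0

    def test_missing_stage_omitted_with_warning(self):
        t = TraitTable(
            sample_ids=["a", "b", "c", "d"],
            stage=["unripe", "unripe", "ripe", "ripe"],
            traits={"TSS": np.array([1.0, 2.0, 3.0, 4.0])},
        )
        with pytest.warns(UserWarning, match="absent"):
            out = describe_by_stage(t, "TSS")
        assert list(out.stage) == ["unripe", "ripe"]


class TestPearson:
    def test_self_correlation_and_sign_flip(self):
        x = np.random.default_rng(0).normal(size=12)
        t = TraitTable(sample_ids=[f"s{i}" for i in range(12)], stage=["ripe"] * 12,
                       traits={"x": x, "negx": -x, "y": x + 1e-3})
        m = pearson_matrix(t)
        assert m.loc["x", "x"] == pytest.approx(1.0)
        assert m.loc["x", "negx"] == pytest.approx(-1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T)

    def test_matches_scalar_loop_oracle(self, mango_dataset):
        t = mango_dataset.traits
        m = pearson_matrix(t)
        for a in t.trait_names:
            for b in t.trait_names:
                x, y = t.values(a), t.values(b)
                xc, yc = x - x.mean(), y - y.mean()
                r = float(xc @ yc) / np.sqrt(float(xc @ xc) * float(yc @ yc))
                assert m.loc[a, b] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_trait_flagged(self):
        t = TraitTable(sample_ids=["a", "b", "c"], stage=["ripe"] * 3,
                       traits={"x": np.array([1.0, 2, 3]), "const": np.ones(3)})
        m = pearson_matrix(t)
        assert m.loc["const"].isna().all()
        assert np.isnan(m.loc["x", "const"])
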