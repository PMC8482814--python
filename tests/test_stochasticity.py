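import itertools

import numpy as np
import pandas as pd
import pytest

from comecol import (
    CohortDesign,
    FeatureTable,
    NullModelConfig,
    bray_curtis,
    expected_similarity,
    null_community,
    selection_strength,
    stochasticity_ratio,
)
from comecol.stochasticity import _null_matrix


def _table(counts, prefix="s"):
    counts = np.asarray(counts, dtype=float)
    ids = [f"{prefix}{i}" for i in range(counts.shape[0])]
    cols = [f"f{j}" for j in range(counts.shape[1])]
    return FeatureTable(data=pd.DataFrame(counts, index=ids, columns=cols))


def _toy_cohort(rng, n_samples=6, n_features=30, depth=400):
    pool = rng.dirichlet(np.full(n_features, 0.4))
    counts = rng.multinomial(depth, pool, size=n_samples)
    counts[counts.sum(axis=1) == 0, 0] = 1
    return _table(counts)


class TestBrayCurtis:
    def test_direct_sum_example(self):
        assert bray_curtis([6, 2, 0], [2, 2, 4]) == pytest.approx(0.5)

    def test_identity_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([5, 0], [0, 3]) == 1.0

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestSelectionStrength:
    @pytest.mark.parametrize(
        "c, e, ss",
        [
            (0.4, 0.4, 0.0),
            (0.9, 0.45, 0.5),
            (0.2, 0.5, 0.375),  # divergence branch: (0.8 - 0.5) / 0.8
            (0.0, 0.0, 0.0),
            (1.0, 0.3, 0.7),
        ],
    )
    def test_branch_arithmetic(self, c, e, ss):
        assert selection_strength(c, e) == pytest.approx(ss)

    def test_bounded_on_random_inputs(self, rng):
        for _ in range(1000):
            c, e = rng.random(2)
            assert 0 <= selection_strength(c, e) <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            selection_strength(1.2, 0.5)


class TestNullCommunity:
    def test_totals_conserved_every_draw(self, rng):
        table = _toy_cohort(rng)
        pool = table.subset_samples(table.sample_ids, drop_empty_features=True)
        cfg = NullModelConfig(n_randomizations=100, seed=3)
        totals = table.data.sum(axis=1)
        for d in range(50):
            null = null_community(table, table.sample_ids, cfg, draw_index=d)
            assert (null.data.sum(axis=1) == totals).all()
            # regional pool identity preserved
            assert set(null.feature_ids) == set(pool.feature_ids)

    def test_fixed_richness_exact(self, rng):
        table = _toy_cohort(rng)
        cfg = NullModelConfig(n_randomizations=100, richness_constraint="fixed", seed=1)
        obs_rich = (table.data > 0).sum(axis=1)
        for d in range(20):
            null = null_community(table, table.sample_ids, cfg, draw_index=d)
            assert ((null.data > 0).sum(axis=1) == obs_rich).all()

    def test_reproducible_from_seed_and_draw(self, rng):
        table = _toy_cohort(rng)
        cfg = NullModelConfig(n_randomizations=100, seed=9)
        a = null_community(table, table.sample_ids, cfg, draw_index=4)
        b = null_community(table, table.sample_ids, cfg, draw_index=4)
        c = null_community(table, table.sample_ids, cfg, draw_index=5)
        assert a == b
        assert a != c

    def test_selected_features_get_at_least_one_count(self, rng):
        table = _toy_cohort(rng)
        cfg = NullModelConfig(n_randomizations=100, seed=2)
        null = null_community(table, table.sample_ids, cfg)
        vals = null.counts
        assert np.all(vals[vals > 0] >= 1)

    def test_inclusion_matches_exact_enumeration(self):
        """On a 5-feature pool with 2 picks, empirical inclusion frequencies
        match the exactly-enumerated successive-sampling probabilities."""
        w = np.array([5.0, 3.0, 1.0, 0.5, 0.5])
        W = w.sum()
        exact = np.zeros(5)
        for t in range(5):
            p = w[t] / W  # picked first
            p += sum(w[s] / W * w[t] / (W - w[s]) for s in range(5) if s != t)
            exact[t] = p
        from comecol.stochasticity import _weighted_sample_without_replacement

        rng = np.random.default_rng(42)
        n_draws = 20_000
        freq = np.zeros(5)
        for _ in range(n_draws):
            freq[_weighted_sample_without_replacement(rng, w, 2)] += 1
        freq /= n_draws
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert np.all(np.abs(freq - exact) < 3.5 * se)

    def test_inclusion_calibrated_against_sequential_oracle(self):
        """Feature inclusion frequencies under the proportional-frequency
        mode match an independent sequential weighted sampler within
        Monte-Carlo error."""
        rng = np.random.default_rng(7)
        n_samples = 12
        table = _toy_cohort(rng, n_samples, 40, depth=300)
        # restrict to the regional pool (features observed at least once)
        table = table.subset_samples(table.sample_ids, drop_empty_features=True)
        n_features = table.n_features
        counts = table.counts
        occurrence = (counts > 0).sum(axis=0).astype(float)
        richness = (counts > 0).sum(axis=1)
        cfg = NullModelConfig(n_randomizations=100, richness_constraint="fixed", seed=11)

        n_draws = 600
        incl = np.zeros(n_features)
        for d in range(n_draws):
            null = null_community(table, table.sample_ids, cfg, draw_index=d)
            incl += (null.counts > 0).sum(axis=0)
        incl /= n_draws * n_samples

        # oracle: sequential renormalizing picks, same fixed per-sample richness
        orng = np.random.default_rng(1001)
        oracle = np.zeros(n_features)
        for _ in range(n_draws):
            for k in richness:
                w = occurrence.copy()
                for _pick in range(int(k)):
                    p = w / w.sum()
                    j = orng.choice(n_features, p=p)
                    oracle[j] += 1
                    w[j] = 0.0
        oracle /= n_draws * n_samples

        p = (incl + oracle) / 2
        se = np.sqrt(2 * p * (1 - p) / n_draws / n_samples)
        z = np.abs(incl - oracle) / np.maximum(se, 1e-9)
        # 3 SE per feature, allowing a single chance exceedance among 40
        assert (z > 3).sum() <= 1
        assert z.mean() < 1.5


class TestExpectedSimilarity:
    def test_single_randomization_reproduces_one_draw(self, rng):
        table = _toy_cohort(rng, n_samples=4)
        cfg = NullModelConfig(n_randomizations=1, seed=6)
        e = expected_similarity(table, table.sample_ids, cfg)
        null = null_community(table, table.sample_ids, cfg, draw_index=0)
        for (si, sj), val in e.items():
            direct = 1.0 - bray_curtis(
                null.data.loc[si].to_numpy(), null.data.loc[sj].to_numpy()
            )
            assert val == pytest.approx(direct, abs=1e-12)

    def test_values_in_unit_interval(self, rng):
        table = _toy_cohort(rng, n_samples=5)
        e = expected_similarity(table, table.sample_ids, NullModelConfig(n_randomizations=100, seed=0))
        assert all(0 <= v <= 1 for v in e.values())

    def test_doubling_randomizations_halves_standard_error(self, rng):
        """Monte-Carlo SE of E_ij scales as 1/sqrt(n_randomizations)."""
        table = _toy_cohort(rng, n_samples=3, n_features=15, depth=120)
        pair = (table.sample_ids[0], table.sample_ids[1])

        def replicate_sd(n_rand, n_rep=150):
            vals = []
            for rep in range(n_rep):
                cfg = NullModelConfig(n_randomizations=n_rand, seed=5000 + rep * 977 + n_rand)
                vals.append(expected_similarity(table, table.sample_ids, cfg)[pair])
            return np.std(vals)

        # quadrupling the randomizations halves the SE twice
        ratio = replicate_sd(25) / replicate_sd(100)
        assert ratio == pytest.approx(2.0, rel=0.20)


class TestStochasticityRatio:
    def test_identical_samples_with_imperfect_null(self, rng):
        counts = np.tile([30, 20, 10, 5], (2, 1))
        table = _table(counts)
        design = CohortDesign({s: "c" for s in table.sample_ids}, ["c"])
        cfg = NullModelConfig(n_randomizations=100, seed=0)
        res = stochasticity_ratio(table, design, cfg)["c"]
        row = res.pairs.iloc[0]
        assert row["observed"] == pytest.approx(1.0)
        assert row["expected"] < 1.0
        assert row["selection_strength"] > 0

    def test_summaries_in_percent_range(self, rng):
        table = _toy_cohort(rng, n_samples=6)
        design = CohortDesign({s: "c" for s in table.sample_ids}, ["c"])
        res = stochasticity_ratio(table, design, NullModelConfig(n_randomizations=100, seed=1))["c"]
        assert 0 <= res.mean_st_pct <= 100
        assert (res.pairs["stochasticity"] >= 0).all()
        assert (res.pairs["stochasticity"] <= 1).all()
        assert len(res.pairs) == 15  # C(6, 2)

    def test_bit_identical_given_same_inputs(self, rng):
        table = _toy_cohort(rng, n_samples=5)
        design = CohortDesign({s: "c" for s in table.sample_ids}, ["c"])
        cfg = NullModelConfig(n_randomizations=100, seed=77)
        r1 = stochasticity_ratio(table, design, cfg)["c"]
        r2 = stochasticity_ratio(table, design, cfg)["c"]
        assert r1.mean_st_pct == r2.mean_st_pct
        assert r1.pairs.equals(r2.pairs)

    def test_small_n_randomizations_warns(self):
        with pytest.warns(UserWarning, match="below 100"):
            NullModelConfig(n_randomizations=10)

    def test_json_serialization_has_pairs_and_summary(self, rng, tmp_path):
        import json

        from comecol import write_results

        table = _toy_cohort(rng, n_samples=4)
        design = CohortDesign({s: "c" for s in table.sample_ids}, ["c"])
        res = stochasticity_ratio(table, design, NullModelConfig(n_randomizations=100, seed=0))
        path = tmp_path / "st.json"
        write_results(res["c"], path, format="json")
        doc = json.loads(path.read_text())
        assert len(doc["pairs"]) == 6
        assert {"sample_i", "sample_j", "observed", "expected",
                "selection_strength", "stochasticity"} <= set(doc["pairs"][0])
        assert 0 <= doc["mean_st_pct"] <= 100
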