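"""NIL pipeline: mixed-model adjustment, pairwise MANOVA, permutation p."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import linkedpolygene as lp
from linkedpolygene.datatypes import EffectLadder, ValidationError, wells_to_frame
from linkedpolygene.nil import ReplicatePhenotypes, _two_group_lambda_batch
from linkedpolygene.simulate import AssayDesign, make_nil_ladder


def _reps_from_arrays(groups: dict[str, np.ndarray]) -> ReplicatePhenotypes:
    rows = []
    for strain, arr in groups.items():
        for i, row in enumerate(np.atleast_2d(arr)):
            rows.append(
                {"strain": strain, "day": "d1", "passage": f"r{i}",
                 "S": row[0], "M": row[1], "N": row[2]}
            )
    return ReplicatePhenotypes(table=pd.DataFrame(rows))


class TestReplicateExtraction:
    def test_full_design_bookkeeping(self, nil_study):
        d = nil_study["design"]
        assert len(nil_study["reps"].table) == d.n_days * d.n_strains * d.n_passage_reps

    def test_adjusted_values_near_replicate_means_with_tiny_nuisance(self):
        """With nuisance variation off (only well-to-well residual noise) the
        adjusted phenotype is close to the replicate population's raw mean:
        BLUP shrinkage stays small when each population is measured ~6x."""
        ladder = make_nil_ladder(3)
        effects = np.zeros((3, 3))
        effects[:, 2] = [4.0, -3.0, 5.0]
        zero = (0.0, 0.0, 0.0)
        design = AssayDesign(
            n_days=2, n_strains=4, n_passage_reps=3, n_plates_per_day=6,
            sd_day=zero, sd_plate=zero, sd_well=zero,
            sd_passage=(0.0, 0.0, 1.0), sd_resid=(0.02, 0.02, 1.0),
            n_well_positions=12, seed=31,
        )
        wells = lp.simulate_nil_assay(ladder, EffectLadder(effects=effects), design)
        reps = lp.extract_replicate_phenotypes(wells)
        df = wells_to_frame(wells)
        df["rep"] = df.strain + "|" + df.day + "|" + df.passage
        raw = df.groupby("rep")["N"].mean()
        adj = reps.table.assign(
            rep=reps.table.strain + "|" + reps.table.day + "|" + reps.table.passage
        ).set_index("rep")["N"]
        raw = raw[adj.index]
        assert np.corrcoef(raw, adj)[0, 1] > 0.95
        # strain-level signal survives adjustment: strain means near truth
        strain_adj = (
            reps.table.groupby("strain")["N"].mean().reindex(ladder.strains).to_numpy()
        )
        truth = ladder.membership() @ effects[:, 2] + 45.0
        assert np.allclose(strain_adj, truth, atol=1.5)

    def test_day_effects_removed(self, nil_study):
        """Simulated day shifts on N are absorbed: adjusted values correlate
        strongly with the true latent replicate means."""
        reps = nil_study["reps"].table
        ladder = nil_study["ladder"]
        truth = ladder.membership() @ nil_study["true_effects"].effects
        strain_adj = reps.groupby("strain")["N"].mean().reindex(ladder.strains).to_numpy()
        assert np.corrcoef(strain_adj, truth[:, 2])[0, 1] > 0.95

    def test_too_few_factor_levels_rejected(self):
        ladder = make_nil_ladder(1)
        wells = lp.simulate_nil_assay(
            ladder,
            EffectLadder(effects=np.zeros((1, 3))),
            AssayDesign(n_days=1, n_strains=2, n_passage_reps=2, n_plates_per_day=2, seed=0),
        )
        with pytest.raises(ValidationError, match="fewer than 2 levels"):
            lp.extract_replicate_phenotypes(wells)


class TestPairwiseManova:
    def test_identical_groups_lambda_one(self):
        arr = np.tile([0.2, 0.3, 40.0], (5, 1)) + np.random.default_rng(0).normal(
            size=(5, 3), scale=0.01
        )
        reps = _reps_from_arrays({"a": arr, "b": arr})
        res = lp.pairwise_multivariate_test(reps, "a", "b")
        assert res.statistic == pytest.approx(1.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_univariate_projection_equals_pooled_t(self):
        """With one trait varying, the MANOVA F on that axis equals the
        squared two-sample pooled-variance t statistic."""
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(1)
        a = np.zeros((8, 3)); b = np.zeros((9, 3))
        a[:, 2] = rng.normal(40, 3, 8)
        b[:, 2] = rng.normal(44, 3, 9)
        # make S, M constant so the multivariate test reduces to N
        a[:, 0] = b[:, 0] = 0.2
        a[:, 1] = b[:, 1] = 0.3
        reps = _reps_from_arrays({"a": a, "b": b})
        res = lp.pairwise_multivariate_test(reps, "a", "b")
        t = ttest_ind(a[:, 2], b[:, 2], equal_var=True).statistic
        # with two degenerate axes the Lambda F reduces to the univariate F
        Y = np.vstack([a, b])[:, 2:]
        n = len(Y)
        lam, F = _two_group_lambda_batch(
            np.vstack([a, b]), np.r_[np.ones(8), np.zeros(9)].astype(bool)[None, :]
        )
        assert F[0, 2] == pytest.approx(t**2, rel=1e-10)

    def test_statsmodels_manova_oracle(self):
        """Wilks' Lambda and its F match the statsmodels MANOVA implementation
        (independent oracle) on a random two-group instance."""
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(12, 3)) + [0.5, 0.0, 0.2]
        reps = _reps_from_arrays({"a": a, "b": b})
        res = lp.pairwise_multivariate_test(reps, "a", "b")
        Y = np.vstack([a, b])
        X = np.r_[np.zeros(10), np.ones(12)]
        mv = MANOVA(endog=Y, exog=np.column_stack([np.ones(22), X]))
        tbl = mv.mv_test(hypotheses=[("x", np.array([[0.0, 1.0]]), None)])
        stat = tbl.results["x"]["stat"]
        assert res.statistic == pytest.approx(stat.loc["Wilks' lambda", "Value"], rel=1e-9)
        assert res.p_value == pytest.approx(stat.loc["Wilks' lambda", "Pr > F"], rel=1e-7)

    def test_invariance_under_trait_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3)); b = rng.normal(size=(7, 3)) + 0.4
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        r1 = lp.pairwise_multivariate_test(_reps_from_arrays({"a": a, "b": b}), "a", "b")
        r2 = lp.pairwise_multivariate_test(
            _reps_from_arrays({"a": a @ A.T, "b": b @ A.T}), "a", "b"
        )
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_fewer_than_three_observations_rejected(self):
        reps = _reps_from_arrays(
            {"a": np.zeros((2, 3)), "b": np.random.default_rng(0).normal(size=(5, 3))}
        )
        with pytest.raises(ValidationError, match=">= 3"):
            lp.pairwise_multivariate_test(reps, "a", "b")


class TestPermutationP:
    def test_three_vs_three_matches_exhaustive_enumeration(self):
        """Monte-Carlo label permutation agrees with exhaustive enumeration of
        all 20 assignments on random 3-vs-3 instances."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            b = rng.normal(size=(3, 3)) + rng.normal(scale=0.8, size=3)
            reps = _reps_from_arrays({"a": a, "b": b})
            n_perm = 4000
            p_mc, _ = lp.permutation_pvalue(reps, "a", "b", n_perm=n_perm, seed=9)
            Y = np.vstack([a, b])
            masks = np.zeros((20, 6), dtype=bool)
            for i, combo in enumerate(combinations(range(6), 3)):
                masks[i, list(combo)] = True
            lam, _ = _two_group_lambda_batch(Y, masks)
            obs = lam[0] if masks[0, :3].all() else None
            lam_obs, _ = _two_group_lambda_batch(
                Y, np.r_[np.ones(3), np.zeros(3)].astype(bool)[None, :]
            )
            p_exact = (lam <= lam_obs[0] + 1e-12).mean()
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(p_mc - p_exact) < 3 * se + 2 / n_perm

    def test_identical_groups_p_one(self):
        arr = np.tile([0.2, 0.3, 40.0], (4, 1))
        arr = arr + np.random.default_rng(5).normal(size=(4, 3), scale=1e-6)
        reps = _reps_from_arrays({"a": arr, "b": arr})
        p, p_uni = lp.permutation_pvalue(reps, "a", "b", n_perm=500, seed=0)
        assert p == 1.0

    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3)) + 50.0  # overwhelming separation
        reps = _reps_from_arrays({"a": a, "b": b})
        n_perm = 200
        p, p_uni = lp.permutation_pvalue(reps, "a", "b", n_perm=n_perm, seed=1)
        assert p >= 1 / (n_perm + 1)
        assert all(v >= 1 / (n_perm + 1) for v in p_uni.values())

    def test_small_permutation_count_rejected(self):
        reps = _reps_from_arrays(
            {"a": np.zeros((3, 3)), "b": np.ones((3, 3))}
        )
        with pytest.raises(ValidationError):
            lp.permutation_pvalue(reps, "a", "b", n_perm=50, seed=0)

    def test_null_rejection_rate_calibrated(self):
        """Two identically distributed strains: permutation p <= 0.05 in ~5%
        of simulated pairs."""
        rng = np.random.default_rng(7)
        n_pairs, n_perm = 400, 400
        rej = 0
        for _ in range(n_pairs):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            reps = _reps_from_arrays({"a": a, "b": b})
            p, _ = lp.permutation_pvalue(reps, "a", "b", n_perm=n_perm, seed=int(rng.integers(2**31)))
            rej += p <= 0.05
        rate = rej / n_pairs
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_pairs) + 0.01


class TestEffectLadder:
    def test_telescoping_identity(self, nil_study):
        reps, ladder = nil_study["reps"], nil_study["ladder"]
        el = lp.interval_effect_ladder(reps, ladder)
        total = el.effects.sum(axis=0)
        parental_diff = (
            reps.for_strain(ladder.strains[-1]).mean(axis=0)
            - reps.for_strain(ladder.strains[0]).mean(axis=0)
        )
        assert np.allclose(total, parental_diff, atol=1e-10)

    def test_noise_free_ladder_recovered_exactly(self):
        ladder = make_nil_ladder(4)
        effects = np.array(
            [[0.0, 0.1, 3.0], [0.05, -0.1, -2.0], [0.0, 0.0, 0.0], [-0.02, 0.0, 5.0]]
        )
        truth = ladder.membership() @ effects
        groups = {
            s: np.tile(truth[k], (3, 1)) for k, s in enumerate(ladder.strains)
        }
        reps = _reps_from_arrays(groups)
        el = lp.interval_effect_ladder(reps, ladder)
        assert np.allclose(el.effects, effects, atol=1e-10)

    def test_identical_strains_zero_effects(self):
        ladder = make_nil_ladder(3)
        groups = {s: np.tile([0.2, 0.3, 40.0], (3, 1)) for s in ladder.strains}
        el = lp.interval_effect_ladder(_reps_from_arrays(groups), ladder)
        assert np.allclose(el.effects, 0.0)

    def test_missing_strain_rejected(self, nil_study):
        reps = nil_study["reps"]
        sub = ReplicatePhenotypes(
            table=reps.table[reps.table["strain"] != "NIL03"].reset_index(drop=True)
        )
        with pytest.raises(ValidationError, match="NIL03"):
            lp.interval_effect_ladder(sub, nil_study["ladder"])


class TestBonferroni:
    def test_threshold_for_15_intervals(self):
        flags, thr = lp.bonferroni_flags([0.5] * 15, family_alpha=0.05)
        assert thr == pytest.approx(0.05 / 15)
        assert round(thr, 3) == 0.003

    def test_boundary_cases(self):
        flags, thr = lp.bonferroni_flags([0.0030, 0.0034] + [0.5] * 13)
        assert flags[0] and not flags[1]

    def test_single_test_threshold_is_alpha(self):
        flags, thr = lp.bonferroni_flags([0.04])
        assert thr == 0.05 and flags[0]


class TestIntervalTable:
    def test_table_shape_and_consistency(self, nil_study):
        tbl = lp.test_intervals(nil_study["reps"], nil_study["ladder"], n_perm=300, seed=2)
        df = tbl.table
        assert list(df["interval"]) == list(nil_study["ladder"].interval_labels)
        assert ((df["p_perm"] > 0) & (df["p_perm"] <= 1)).all()
        assert (df["bonferroni_significant"] == (df["p_perm"] <= tbl.bonferroni_threshold)).all()

    def test_strong_intervals_detected(self, nil_study):
        """The three large planted progeny effects (|e| >= 2.5) are detected
        at the Bonferroni threshold in the small study."""
        tbl = lp.test_intervals(nil_study["reps"], nil_study["ladder"], n_perm=2000, seed=3)
        df = tbl.table.set_index("interval")
        big = np.abs(nil_study["true_effects"].effects[:, 2]) >= 2.5
        labels = np.array(nil_study["ladder"].interval_labels)[big]
        assert df.loc[labels, "bonferroni_significant"].sum() >= len(labels) - 1
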