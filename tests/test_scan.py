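"""RIAIL scan: day adjustment, filtering, marker regression, forward search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import f_oneway

import linkedpolygene as lp
from linkedpolygene.datatypes import ValidationError
from linkedpolygene.scan import PermutationSettings
from linkedpolygene.simulate import NormalEffects, RIAILPanelSpec, default_marker_map


def _table(values, prefix="L", scale="residual"):
    values = np.asarray(values, dtype=float)
    return lp.PhenotypeTable(
        lines=tuple(f"{prefix}{i:03d}" for i in range(len(values))),
        values=values,
        scale=scale,
    )


def _geno(calls):
    calls = np.asarray(calls, dtype=float)
    return lp.GenotypeMatrix(
        lines=tuple(f"L{i:03d}" for i in range(calls.shape[0])),
        markers=lp.unlinked_marker_map(calls.shape[1]),
        calls=calls,
    )


class TestDayAdjustment:
    def test_single_day_is_global_centering(self):
        rng = np.random.default_rng(0)
        raw = _table(rng.normal(size=(10, 3)))
        labels = {ln: "d1" for ln in raw.lines}
        adj = lp.adjust_for_assay_day(raw, labels)
        assert np.allclose(adj.values, raw.values - raw.values.mean(axis=0))
        assert adj.scale == "residual"

    def test_matches_ols_factor_regression(self):
        """Per-day centering equals the residuals of a multivariate OLS fit on
        the day factor (independent statsmodels oracle)."""
        import statsmodels.api as sm
        import pandas as pd

        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 3))
        values[15:, 2] += 10.0  # day-mean shift on N
        raw = _table(values)
        labels = {ln: ("d1" if i < 15 else "d2") for i, ln in enumerate(raw.lines)}
        adj = lp.adjust_for_assay_day(raw, labels)
        day = pd.get_dummies([labels[ln] for ln in raw.lines], drop_first=False).to_numpy(float)
        for t in range(3):
            resid = sm.OLS(values[:, t], day).fit().resid
            assert np.allclose(adj.values[:, t], resid, atol=1e-10)

    def test_residuals_sum_to_zero_per_day(self):
        rng = np.random.default_rng(2)
        raw = _table(rng.normal(size=(40, 3)))
        labels = {ln: f"d{i % 4}" for i, ln in enumerate(raw.lines)}
        adj = lp.adjust_for_assay_day(raw, labels)
        for d in set(labels.values()):
            idx = [i for i, ln in enumerate(raw.lines) if labels[ln] == d]
            assert np.allclose(adj.values[idx].sum(axis=0), 0.0, atol=1e-10)

    def test_single_line_day_rejected(self):
        raw = _table(np.zeros((3, 3)))
        labels = {raw.lines[0]: "d1", raw.lines[1]: "d1", raw.lines[2]: "d2"}
        with pytest.raises(ValidationError, match="single line"):
            lp.adjust_for_assay_day(raw, labels)


class TestLowFecundityFilter:
    def test_panel_of_282_with_10_failing_retains_272(self):
        rng = np.random.default_rng(3)
        values = np.zeros((282, 3))
        values[:, 2] = rng.uniform(20, 80, size=282)
        low = rng.choice(282, size=10, replace=False)
        values[low, 2] = rng.uniform(0, 5, size=10)
        filtered = lp.filter_low_fecundity(_table(values, scale="raw"))
        assert filtered.n_lines == 272

    def test_boundary_exactly_five_excluded(self):
        values = np.array([[0.1, 0.2, 5.0], [0.1, 0.2, 5.0001]])
        filtered = lp.filter_low_fecundity(_table(values, scale="raw"))
        assert filtered.n_lines == 1
        assert filtered.values[0, 2] == 5.0001

    def test_no_failing_lines_is_identity(self):
        values = np.tile([0.1, 0.2, 50.0], (5, 1))
        raw = _table(values, scale="raw")
        assert lp.filter_low_fecundity(raw).lines == raw.lines


class TestMarkerScan:
    def test_univariate_f_equals_anova(self, small_genotypes):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(60, 3))
        Y[:, 2] += small_genotypes.calls[:, 7] * 1.5
        prof = lp.marker_scan(_table(Y), small_genotypes, traits=("N",))
        for j in [0, 7, 20]:
            x = small_genotypes.calls[:, j]
            f_ref = f_oneway(Y[x == 0, 2], Y[x == 1, 2]).statistic
            assert prof.table["F"][j] == pytest.approx(f_ref, rel=1e-10)

    def test_monomorphic_marker_flagged(self):
        calls = np.array([[0, 1], [0, 0], [0, 1], [0, 0], [0, 1], [0, 0], [0, 1]])
        g = _geno(calls)
        Y = np.random.default_rng(5).normal(size=(7, 3))
        prof = lp.marker_scan(_table(Y), g)
        assert prof.table["flagged"][0]
        assert np.isnan(prof.table["wilks_lambda"][0])
        assert not prof.table["flagged"][1]

    def test_wilks_invariant_to_trait_transform(self, small_genotypes):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(60, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        p1 = lp.marker_scan(_table(Y), small_genotypes).table["wilks_lambda"]
        p2 = lp.marker_scan(_table(Y @ A.T), small_genotypes).table["wilks_lambda"]
        assert np.allclose(p1, p2, atol=1e-10)

    def test_pillai_equals_one_minus_lambda_for_rank_one(self, small_genotypes):
        Y = np.random.default_rng(7).normal(size=(60, 3))
        w = lp.marker_scan(_table(Y), small_genotypes)
        p = lp.marker_scan(_table(Y), small_genotypes, statistic="pillai")
        assert np.allclose(
            p.table["pillai_trace"], 1 - w.table["wilks_lambda"], atol=1e-12
        )
        assert np.allclose(p.table["F"], w.table["F"], atol=1e-10)

    def test_missing_genotypes_listwise_per_marker(self, small_genotypes):
        calls = small_genotypes.calls.copy()
        calls[:5, 3] = np.nan
        g = _geno(calls)
        Y = np.random.default_rng(8).normal(size=(60, 3))
        prof = lp.marker_scan(_table(Y), g)
        # marker 3 scanned on the 55 complete lines only
        sub = ~np.isnan(calls[:, 3])
        prof_sub = lp.marker_scan(
            lp.PhenotypeTable(
                lines=tuple(np.array(g.lines)[sub]), values=Y[sub], scale="residual"
            ),
            lp.GenotypeMatrix(
                lines=tuple(np.array(g.lines)[sub]),
                markers=g.markers,
                calls=calls[sub],
            ),
        )
        assert prof.table["wilks_lambda"][3] == pytest.approx(
            prof_sub.table["wilks_lambda"][3], rel=1e-10
        )

    def test_covariates_excluded_from_scan(self, small_genotypes):
        Y = np.random.default_rng(9).normal(size=(60, 3))
        m0 = small_genotypes.markers.marker_id[0]
        prof = lp.marker_scan(_table(Y), small_genotypes, covariate_markers=[m0])
        assert prof.table["flagged"][0]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_lambda_invariant_to_line_reordering(self, seed):
        rng = np.random.default_rng(seed)
        calls = (rng.random((25, 4)) < 0.5).astype(float)
        if any(np.ptp(calls[:, j]) == 0 for j in range(4)):
            calls[0] = 1 - calls[1]
        g = _geno(calls)
        Y = rng.normal(size=(25, 3))
        base = lp.marker_scan(_table(Y), g).table["wilks_lambda"].to_numpy()
        perm = rng.permutation(25)
        g2 = lp.GenotypeMatrix(
            lines=tuple(g.lines[i] for i in perm), markers=g.markers, calls=calls[perm]
        )
        t2 = lp.PhenotypeTable(
            lines=tuple(g.lines[i] for i in perm), values=Y[perm], scale="residual"
        )
        reord = lp.marker_scan(t2, g2).table["wilks_lambda"].to_numpy()
        assert np.allclose(base, reord, atol=1e-10, equal_nan=True)


class TestThreshold:
    def test_alpha_monotonicity_same_draws(self, small_genotypes):
        Y = np.random.default_rng(10).normal(size=(60, 3))
        t = _table(Y)
        thr05 = lp.residual_empirical_threshold(
            t, small_genotypes,
            settings=PermutationSettings(n_permutations=200, genomewide_alpha=0.05, seed=1),
        )
        thr01 = lp.residual_empirical_threshold(
            t, small_genotypes,
            settings=PermutationSettings(n_permutations=200, genomewide_alpha=0.01, seed=1),
        )
        assert thr01 >= thr05

    def test_sidak_oracle_for_independent_markers(self):
        """With independent markers and Gaussian null traits, the threshold
        approximates the Sidak cutoff -log10(1 - 0.95^(1/m))."""
        rng = np.random.default_rng(11)
        m, n = 40, 300
        g = _geno((rng.random((n, m)) < 0.5).astype(float))
        thrs = []
        for rep in range(8):
            Y = rng.normal(size=(n, 3))
            thrs.append(
                lp.residual_empirical_threshold(
                    _table(Y), g,
                    settings=PermutationSettings(
                        n_permutations=500, genomewide_alpha=0.05, seed=rep
                    ),
                )
            )
        sidak = -np.log10(1 - 0.95 ** (1 / m))
        assert np.mean(thrs) == pytest.approx(sidak, rel=0.12)

    def test_fixed_seed_reproducible(self, small_genotypes):
        Y = np.random.default_rng(12).normal(size=(60, 3))
        kw = dict(settings=PermutationSettings(n_permutations=150, seed=3))
        a = lp.residual_empirical_threshold(_table(Y), small_genotypes, **kw)
        b = lp.residual_empirical_threshold(_table(Y), small_genotypes, **kw)
        assert a == b


class TestEffectEstimation:
    def test_noise_free_balanced_design_exact_recovery(self):
        """Planted effect vectors recovered exactly from a noise-free
        orthogonal (full factorial) design."""
        from itertools import product

        calls = np.array(list(product([0.0, 1.0], repeat=3)))
        calls = np.tile(calls, (4, 1))
        g = _geno(calls)
        B = np.array([[0.1, -0.2, 5.0], [0.0, 0.3, -2.0], [-0.05, 0.0, 1.0]])
        Y = calls @ B
        est = lp.estimate_effects(_table(Y), g, list(g.markers.marker_id))
        assert np.allclose(est.effects, B, atol=1e-10)
        assert all(r == pytest.approx(1.0) for r in est.r_squared.values())

    def test_monomorphic_marker_rejected(self):
        calls = np.column_stack([np.zeros(10), np.r_[np.zeros(5), np.ones(5)]])
        g = _geno(calls)
        Y = np.random.default_rng(13).normal(size=(10, 3))
        with pytest.raises(ValidationError, match="monomorphic"):
            lp.estimate_effects(_table(Y), g, list(g.markers.marker_id))

    def test_collinear_pair_named(self):
        x = np.random.default_rng(14).integers(0, 2, 12).astype(float)
        calls = np.column_stack([x, x, 1 - x])[:, :2]
        g = _geno(calls)
        Y = np.random.default_rng(15).normal(size=(12, 3))
        with pytest.raises(ValidationError, match="collinear"):
            lp.estimate_effects(_table(Y), g, list(g.markers.marker_id))

    def test_orthogonal_effectless_marker_leaves_estimates(self):
        from itertools import product

        calls = np.array(list(product([0.0, 1.0], repeat=2)))
        calls = np.tile(calls, (5, 1))
        g = _geno(calls)
        b = np.array([[0.0, 0.1, 3.0]])
        Y = calls[:, :1] @ b
        est1 = lp.estimate_effects(_table(Y), g, [g.markers.marker_id[0]])
        est2 = lp.estimate_effects(_table(Y), g, list(g.markers.marker_id))
        assert np.allclose(est2.effects[0], est1.effects[0], atol=1e-10)
        assert np.allclose(est2.effects[1], 0.0, atol=1e-10)


class TestForwardSearch:
    def test_planted_qtl_recovered(self):
        """A strong planted QTL (n = 250 lines, 100 linked markers) is
        retained at or within 2 markers of the true position."""
        mm = default_marker_map(n_markers=100, n_chromosomes=6)
        hits = 0
        for rep in range(10):
            g = lp.simulate_riail_genotypes(
                RIAILPanelSpec(n_lines=250, marker_map=mm, seed=900 + rep)
            )
            rng = np.random.default_rng(rep)
            true_j = 47
            Y = rng.normal(size=(250, 3))
            x = g.calls[:, true_j]
            Y += np.outer(x - x.mean(), [0.6, 0.6, 0.6]) / np.std(x)
            model = lp.forward_search(
                lp.PhenotypeTable(lines=g.lines, values=Y, scale="residual"),
                g,
                PermutationSettings(n_permutations=200, seed=rep),
            )
            idx = [g.markers.marker_id.index(m) for m in model.markers]
            if any(abs(j - true_j) <= 2 for j in idx):
                hits += 1
        assert hits >= 9

    def test_deterministic_given_seed(self, small_genotypes):
        Y = np.random.default_rng(16).normal(size=(60, 3))
        Y[:, 0] += small_genotypes.calls[:, 5] * 2
        t = _table(Y)
        s = PermutationSettings(n_permutations=150, seed=4)
        a = lp.forward_search(t, small_genotypes, s)
        b = lp.forward_search(t, small_genotypes, s)
        assert a.markers == b.markers and a.thresholds == b.thresholds


class TestEpistasis:
    def test_single_qtl_rejected(self, small_genotypes):
        Y = np.random.default_rng(17).normal(size=(60, 3))
        with pytest.raises(ValidationError):
            lp.epistasis_test(_table(Y), small_genotypes, [small_genotypes.markers.marker_id[0]])

    def test_additive_null_rejection_rate(self, small_genotypes):
        """Under a purely additive model the pairwise interaction test
        rejects at ~the nominal rate."""
        rng = np.random.default_rng(18)
        markers = list(small_genotypes.markers.marker_id[:3])
        X = small_genotypes.calls[:, :3]
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            Y = rng.normal(size=(60, 3)) + X @ rng.normal(size=(3, 3))
            p_pair, _ = lp.epistasis_test(_table(Y), small_genotypes, markers)
            rejections += p_pair < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_planted_interaction_detected(self):
        """A strong pairwise interaction at n = 250 is detected (p < 0.01)
        in at least 90% of replicates."""
        rng = np.random.default_rng(19)
        detected = 0
        n_rep = 20
        for _ in range(n_rep):
            calls = (rng.random((250, 4)) < 0.5).astype(float)
            g = _geno(calls)
            Y = rng.normal(size=(250, 3))
            Y[:, 2] += 2.5 * calls[:, 0] * calls[:, 1]
            p_pair, _ = lp.epistasis_test(
                _table(Y), g, list(g.markers.marker_id[:2])
            )
            detected += p_pair < 0.01
        assert detected >= 0.9 * n_rep
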