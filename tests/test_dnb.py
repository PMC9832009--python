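import itertools

import numpy as np
import pytest

import dnbtrack as dt
from dnbtrack.dnb import composite_index, detect_modules, dnb_scan, pairwise_pcc, sliding_window_scan
from dnbtrack.errors import AnalysisError, ConfigError, InsufficientReplicatesError
from tests.conftest import lineage_subspace_for, make_expr


def pearson_oracle(x, y):
    """Closed-form Pearson correlation, plain loops."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def composite_index_oracle(values, module_idx, epsilon=1e-6):
    """Naive double-loop (PCC_i, PCC_o, SD_i, CI) on a genes x replicates array."""
    g = values.shape[0]
    inside = list(module_idx)
    outside = [i for i in range(g) if i not in module_idx]
    pcc_i = np.mean(
        [abs(pearson_oracle(values[a], values[b])) for a, b in itertools.combinations(inside, 2)]
    )
    pcc_o = np.mean(
        [abs(pearson_oracle(values[a], values[b])) for a in inside for b in outside]
    )
    sd_i = np.mean([np.std(values[i], ddof=1) for i in inside])
    return pcc_i, pcc_o, sd_i, (pcc_i / max(pcc_o, epsilon)) * sd_i


class TestPairwisePCC:
    def test_perfect_linear_pairs(self):
        e = make_expr([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        net = pairwise_pcc(e, e.sample_ids)
        assert net.matrix[0, 1] == pytest.approx(1.0)
        assert net.matrix[0, 2] == pytest.approx(-1.0)

    def test_closed_form_oracle(self):
        e = make_expr([[1, 2, 4], [1, 3, 3]])
        net = pairwise_pcc(e, e.sample_ids)
        assert net.matrix[0, 1] == pytest.approx(pearson_oracle([1, 2, 4], [1, 3, 3]), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(6, 5))
        e1 = make_expr(x)
        x2 = x.copy()
        x2[2] = 3.5 * x2[2] + 11.0  # positive-scale affine transform of one gene
        e2 = make_expr(x2)
        np.testing.assert_allclose(
            pairwise_pcc(e1, e1.sample_ids).matrix,
            pairwise_pcc(e2, e2.sample_ids).matrix,
            atol=1e-10,
        )

    def test_zero_variance_gene_flagged_with_zero_correlation(self):
        e = make_expr([[1, 1, 1], [1, 2, 3]])
        net = pairwise_pcc(e, e.sample_ids)
        assert net.zero_variance_genes == {"g0"}
        assert net.matrix[0, 1] == 0.0
        assert net.matrix[0, 0] == 1.0

    def test_too_few_replicates_redirects_to_sliding_window(self):
        e = make_expr([[1, 2], [3, 4]])
        with pytest.raises(InsufficientReplicatesError, match="sliding_window"):
            pairwise_pcc(e, e.sample_ids)


class TestDetectModules:
    def _net(self, r, ids=None):
        ids = ids or [f"g{i}" for i in range(r.shape[0])]
        return dt.CorrelationNetwork(gene_ids=ids, matrix=r)

    def test_two_perfect_blocks_rank_first(self):
        r = np.eye(12)
        r[:5, :5] = 1.0
        r[5:10, 5:10] = 1.0
        mods = detect_modules(self._net(r), min_size=5, max_size=6)
        assert set(mods[0].members) == {f"g{i}" for i in range(5)}
        assert set(mods[1].members) == {f"g{i}" for i in range(5, 10)}

    def test_identity_network_is_deterministic(self):
        r = np.eye(10)
        m1 = detect_modules(self._net(r))
        m2 = detect_modules(self._net(r))
        assert [m.members for m in m1] == [m.members for m in m2]

    def test_planted_block_beats_exhaustive_size6_search(self):
        # 20 genes, one 6-gene block at |PCC| = 0.9, background 0.1
        rng = np.random.default_rng(2)
        n, k = 20, 6
        r = np.full((n, n), 0.1)
        block = [3, 5, 8, 11, 15, 19]
        for a in block:
            for b in block:
                r[a, b] = 0.9
        np.fill_diagonal(r, 1.0)
        mods = detect_modules(self._net(r), min_size=k, max_size=k)
        top = mods[0]
        # brute-force oracle: the size-6 subset maximizing mean |PCC|
        best, best_val = None, -1
        for sub in itertools.combinations(range(n), k):
            idx = np.array(sub)
            s = np.abs(r[np.ix_(idx, idx)])
            val = (s.sum() - k) / (k * (k - 1))
            if val > best_val:
                best_val, best = val, sub
        assert set(best) == set(block)
        assert set(top.members) == {f"g{i}" for i in block}

    def test_small_network_returns_empty(self):
        assert detect_modules(self._net(np.eye(3)), min_size=5) == []

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigError):
            detect_modules(self._net(np.eye(10)), min_size=1)


class TestCompositeIndex:
    def test_constant_module_gives_zero_ci(self):
        vals = np.ones((4, 4))
        vals[3] = [1, 2, 3, 4]  # one varying non-module gene
        e = make_expr(vals)
        m = dt.GeneModule(("g0", "g1", "g2"))
        pcc_i, pcc_o, sd_i, ci = composite_index(m, e, e.sample_ids)
        assert sd_i == 0.0 and ci == 0.0

    def test_printed_toy_matches_loop_oracle(self):
        vals = np.array(
            [
                [2.0, 3.5, 1.0, 4.0],
                [2.2, 3.1, 1.4, 3.9],
                [1.8, 3.9, 0.7, 4.2],
                [5.0, 1.0, 2.0, 2.0],
                [0.5, 0.6, 0.9, 0.2],
                [3.3, 3.1, 3.2, 3.0],
            ]
        )
        e = make_expr(vals)
        m = dt.GeneModule(("g0", "g1", "g2"))
        got = composite_index(m, e, e.sample_ids, min_replicates=3)
        want = composite_index_oracle(vals, [0, 1, 2])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_fuzz_against_double_loop_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            g = rng.integers(4, 16)
            vals = rng.normal(size=(g, 8))
            k = rng.integers(2, g)
            idx = sorted(rng.choice(g, size=k, replace=False))
            e = make_expr(vals)
            m = dt.GeneModule(tuple(f"g{i}" for i in idx))
            got = composite_index(m, e, e.sample_ids)
            want = composite_index_oracle(vals, idx)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_module_spanning_subspace_rejected(self):
        e = make_expr(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(AnalysisError):
            composite_index(dt.GeneModule(("g0", "g1", "g2")), e, e.sample_ids)

    def test_ci_zero_iff_sd_zero(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vals = rng.normal(size=(6, 5))
            e = make_expr(vals)
            m = dt.GeneModule(("g0", "g1"))
            _pi, _po, sd_i, ci = composite_index(m, e, e.sample_ids)
            assert ci >= 0
            assert (ci == 0) == (sd_i == 0)


class TestDnbScan:
    def test_null_data_has_no_reproducible_tipping_point(self):
        tips = []
        for seed in range(6):
            cfg = dt.SyntheticConfig(
                seed=seed, sd_inflation=1.0, rho_peak=0.2, rho_base=0.2, n_genes=150,
                module_size=10, switch_magnitude=0.0, module_switch_magnitude=0.0,
            )
            counts, design, _truth = dt.generate_timecourse(cfg)
            prof = dnb_scan(dt.normalize_rle(counts), design)
            tips.append(prof.tipping_point_index)
        assert len(set(tips)) > 1

    def test_default_config_recovers_planted_tipping_point(self, default_expression):
        expr, design, truth = default_expression
        prof = dnb_scan(expr, design)
        assert prof.tipping_point_index == truth.t_star_index

    def test_subspace_restriction_keeps_tipping_point(self, default_timecourse, default_expression):
        cfg, _c, _d, _t = default_timecourse
        expr, design, truth = default_expression
        full = dnb_scan(expr, design)
        rng = np.random.default_rng(1)
        bg = [g for g in expr.gene_ids if g.startswith("BG")]
        sub = truth.module_gene_ids + list(rng.choice(bg, 50, replace=False))
        restricted = dnb_scan(expr, design, subspace=sub)
        assert restricted.tipping_point_time == full.tipping_point_time

    def test_differential_subspace_recovers_module(self, default_timecourse, default_expression):
        # study-style scan: candidate space = lineage-differential genes from
        # an independent cohort; the dominant module is the planted one
        cfg, _c, _d, _t = default_timecourse
        expr, design, truth = default_expression
        sub = lineage_subspace_for(cfg, expr)
        prof = dnb_scan(expr, design, subspace=sub)
        assert prof.tipping_point_index == truth.t_star_index
        dom = set(prof.dominant_modules[prof.tipping_point_index].members)
        mod = set(truth.module_gene_ids)
        # the dominant group is essentially made of planted-module genes;
        # exact membership is resolution-limited at 6 replicates
        assert len(dom & mod) / len(dom) >= 0.8

    def test_scan_is_deterministic(self, default_expression):
        expr, design, _truth = default_expression
        p1, p2 = dnb_scan(expr, design), dnb_scan(expr, design)
        assert p1.ci == p2.ci
        assert [m.members for m in p1.dominant_modules] == [m.members for m in p2.dominant_modules]
        assert p1.tipping_point_index == p2.tipping_point_index

    def test_insufficient_replicates_raises(self):
        cfg = dt.SyntheticConfig(seed=1, replicates_per_timepoint=2, n_genes=120, module_size=10)
        counts, design, _ = dt.generate_timecourse(cfg)
        with pytest.raises(InsufficientReplicatesError, match="sliding_window"):
            dnb_scan(dt.normalize_rle(counts), design)


class TestSlidingWindow:
    def test_window_one_equals_plain_scan(self, default_expression):
        expr, design, _truth = default_expression
        a = dnb_scan(expr, design)
        b = sliding_window_scan(expr, design, window=1)
        assert a.ci == b.ci and a.time_points == b.time_points
        assert a.tipping_point_index == b.tipping_point_index

    def test_full_window_pools_everything(self, default_expression):
        expr, design, _truth = default_expression
        prof = sliding_window_scan(expr, design, window=len(design.time_points))
        assert len(prof.ci) == 1

    def test_oversized_window_rejected(self, default_expression):
        expr, design, _truth = default_expression
        with pytest.raises(ConfigError):
            sliding_window_scan(expr, design, window=len(design.time_points) + 1)

    def test_two_replicates_recovered_at_window_resolution(self):
        # pooling blurs the exact week by design; the recovered window must
        # contain the planted transition in a majority of runs
        hits = 0
        for seed in range(5):
            cfg = dt.SyntheticConfig(seed=seed, replicates_per_timepoint=2)
            counts, design, truth = dt.generate_timecourse(cfg)
            expr = dt.normalize_rle(counts)
            sub = lineage_subspace_for(cfg, expr)
            prof = sliding_window_scan(expr, design, subspace=sub, window=3)
            times = design.time_points
            i = times.index(prof.tipping_point_time)
            pooled = set(times[max(0, i - 1) : i + 2])
            hits += int(truth.t_star_weeks in pooled)
        assert hits >= 3
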