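"""Hierarchical heteroplasmy simulator: operators against closed-form and
recursion oracles, conservation laws, and whole-lifecycle properties."""

import numpy as np
import pytest

from mlsel import (
    CellState,
    MechanismConfig,
    MtPool,
    Organism,
    apoptosis_filter,
    asymmetric_inheritance,
    divide_mitochondria,
    germline_transmission,
    make_population,
    mitophagy,
    replicate_mtdna,
    run_multilevel,
    selective_import,
)
from mlsel.mito import constant, linear_fecundity, logistic_apoptosis, step_apoptosis


def polya_urn_mean_dysfunctional(f0: int, d0: int, delta: float, target: int) -> float:
    """Exact weighted-urn recursion: expected final dysfunctional fraction.

    Tracks the full probability distribution over dysfunctional counts as
    copies are added one at a time with weights 1 (functional) vs
    1+delta (dysfunctional)."""
    total0 = f0 + d0
    probs = {d0: 1.0}
    for t in range(target - total0):
        nxt: dict[int, float] = {}
        for d, p in probs.items():
            f = total0 + t - d
            w = d * (1 + delta)
            p_d = w / (w + f)
            nxt[d + 1] = nxt.get(d + 1, 0.0) + p * p_d
            nxt[d] = nxt.get(d, 0.0) + p * (1 - p_d)
        probs = nxt
    return sum(d * p for d, p in probs.items()) / target


class TestReplication:
    def test_neutral_replication_preserves_expected_heteroplasmy(self):
        rng = np.random.default_rng(0)
        hs = np.array(
            [replicate_mtdna(MtPool(30, 30), 0.0, 120, rng).heteroplasmy for _ in range(2000)]
        )
        se = hs.std(ddof=1) / np.sqrt(len(hs))
        assert abs(hs.mean() - 0.5) < 3 * se

    def test_biased_replication_matches_urn_recursion(self):
        """delta=1 doubling of a 50/50 pool: simulated mean dysfunctional
        fraction agrees with the exact urn recursion."""
        rng = np.random.default_rng(1)
        expected = polya_urn_mean_dysfunctional(50, 50, 1.0, 200)
        hs = np.array(
            [replicate_mtdna(MtPool(50, 50), 1.0, 200, rng).heteroplasmy for _ in range(2000)]
        )
        se = hs.std(ddof=1) / np.sqrt(len(hs))
        assert expected > 0.5  # the advantage is real
        assert abs(hs.mean() - expected) < 3 * se

    def test_all_dysfunctional_pool_is_absorbing(self):
        rng = np.random.default_rng(2)
        out = replicate_mtdna(MtPool(0, 10), 0.5, 40, rng)
        assert (out.functional, out.dysfunctional) == (0, 40)

    def test_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            replicate_mtdna(MtPool(0, 0), 0.0, 10, rng)
        with pytest.raises(ValueError):
            replicate_mtdna(MtPool(5, 5), 0.0, 8, rng)


class TestMitochondrialDivision:
    def test_constant_fitness_preserves_composition(self):
        """Uncapped division only partitions copies, so the cell's pooled
        counts are conserved exactly; the two homoplasmic mito classes are
        equally represented on average."""
        cell = CellState(np.array([[10, 0]] * 20 + [[0, 10]] * 20))
        class_diff = []
        for s in range(500):
            out = divide_mitochondria(cell, constant(0.5), np.random.default_rng(s))
            assert out.pool == cell.pool
            n_func = (out.counts[:, 1] == 0).sum()
            n_dys = (out.counts[:, 0] == 0).sum()
            class_diff.append(n_func - n_dys)
        class_diff = np.array(class_diff, dtype=float)
        se = class_diff.std(ddof=1) / np.sqrt(len(class_diff))
        assert abs(class_diff.mean()) < 3 * se

    def test_quality_dependent_division_matches_branching_expectation(self):
        """Two-type branching oracle: a mitochondrion of class i leaves
        1 + p_i daughters in expectation.  A division step alone conserves
        the cell's copy composition (it only partitions copies); the
        functional fraction rises once daughters regrow their copy number,
        by exactly the branching weights."""
        counts = np.array([[10, 0]] * 50 + [[0, 10]] * 50)
        cell = CellState(counts)
        fitness = lambda ff: 0.2 + 0.6 * ff
        # expectations: 50*(1+0.8)=90 functional mitos, 50*(1+0.2)=60 dysfunctional;
        # after neutral regrowth to 10 copies each: 900 of 1500 copies functional.
        from mlsel.mito import _replicate_counts

        n_func, f_copies, ffrac_after = [], [], []
        for s in range(800):
            rng = np.random.default_rng(s)
            out = divide_mitochondria(cell, fitness, rng)
            assert out.pool == cell.pool  # division conserves copies
            n_func.append((out.counts[:, 1] == 0).sum())
            grown = _replicate_counts(out.counts, 0.0, 10, rng)
            f_copies.append(grown[:, 0].sum())
            ffrac_after.append(grown[:, 0].sum() / grown.sum())
        n_func = np.array(n_func, dtype=float)
        se = n_func.std(ddof=1) / np.sqrt(len(n_func))
        assert abs(n_func.mean() - 90.0) < 3 * se
        f_copies = np.array(f_copies, dtype=float)
        se_f = f_copies.std(ddof=1) / np.sqrt(len(f_copies))
        assert abs(f_copies.mean() - 900.0) < 3 * se_f
        assert np.mean(ffrac_after) > 0.5

    def test_capacity_cap_enforced(self):
        cell = CellState(np.array([[4, 4]] * 30))
        out = divide_mitochondria(cell, constant(1.0), np.random.default_rng(0), capacity=30)
        assert out.n_mitochondria <= 30


class TestMitophagy:
    def test_unselective_turnover_preserves_expected_heteroplasmy(self):
        cell = CellState(np.array([[10, 0]] * 50 + [[0, 10]] * 50))
        hs = []
        for s in range(800):
            out = mitophagy(cell, selectivity=0.0, rate=0.3, rng=np.random.default_rng(s))
            if out.pool.total:
                hs.append(out.heteroplasmy)
        hs = np.array(hs)
        assert abs(hs.mean() - 0.5) < 3 * hs.std(ddof=1) / np.sqrt(len(hs))

    def test_selective_mitophagy_matches_survival_odds_oracle(self):
        """Polarized cell at h=0.5: the post-mitophagy mean h follows from
        each class's survival probability (odds-multiplied destruction)."""
        rate, sel = 0.5, 1.0
        base_odds = rate / (1 - rate)
        p_f = base_odds / (1 + base_odds)                     # functional mito
        odds_d = base_odds * (1 + sel)                        # fully dysfunctional
        p_d = odds_d / (1 + odds_d)
        q_f, q_d = 1 - p_f, 1 - p_d
        expected = q_d / (q_f + q_d)                          # equal class sizes
        cell = CellState(np.array([[10, 0]] * 50 + [[0, 10]] * 50))
        hs = []
        for s in range(2000):
            out = mitophagy(cell, selectivity=sel, rate=rate, rng=np.random.default_rng(s))
            if out.pool.total:
                hs.append(out.heteroplasmy)
        hs = np.array(hs)
        se = hs.std(ddof=1) / np.sqrt(len(hs))
        assert expected < 0.5
        assert abs(hs.mean() - expected) < 3 * se

    def test_all_functional_cell_unchanged_in_composition(self):
        cell = CellState(np.array([[10, 0]] * 40))
        out = mitophagy(cell, 1.0, 0.4, np.random.default_rng(3))
        assert (out.counts[:, 1] == 0).all()


class TestAsymmetricInheritance:
    def test_symmetric_split_gives_equal_expected_heteroplasmy(self):
        cell = CellState(np.array([[10, 0]] * 30 + [[0, 10]] * 30))
        diffs = []
        for s in range(600):
            d1, d2 = asymmetric_inheritance(cell, 0.0, np.random.default_rng(s))
            if d1.pool.total and d2.pool.total:
                diffs.append(d1.heteroplasmy - d2.heteroplasmy)
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_full_bias_sorts_mitochondria_deterministically(self):
        cell = CellState(np.array([[10, 0]] * 5 + [[0, 10]] * 5))
        d1, d2 = asymmetric_inheritance(cell, 1.0, np.random.default_rng(0))
        assert d1.pool.dysfunctional == 0 and d1.pool.functional == 50
        assert d2.pool.functional == 0 and d2.pool.dysfunctional == 50

    def test_partial_bias_matches_binomial_assignment_expectation(self):
        """bias=0.5: each functional mito reaches the favored daughter
        independently w.p. 0.75, each dysfunctional one w.p. 0.25, so the
        favored daughter's class counts are Binomial(20, 0.75) and
        Binomial(20, 0.25); her mean heteroplasmy sits below the cell's."""
        nf = nd = 20
        cell = CellState(np.array([[10, 0]] * nf + [[0, 10]] * nd))
        got_f, got_d, h1s, h2s = [], [], [], []
        for s in range(2000):
            d1, d2 = asymmetric_inheritance(cell, 0.5, np.random.default_rng(s))
            got_f.append((d1.counts[:, 1] == 0).sum())
            got_d.append((d1.counts[:, 0] == 0).sum())
            if d1.pool.total and d2.pool.total:
                h1s.append(d1.heteroplasmy)
                h2s.append(d2.heteroplasmy)
        got_f, got_d = np.array(got_f, dtype=float), np.array(got_d, dtype=float)
        se_f = got_f.std(ddof=1) / np.sqrt(len(got_f))
        se_d = got_d.std(ddof=1) / np.sqrt(len(got_d))
        assert abs(got_f.mean() - 0.75 * nf) < 3 * se_f
        assert abs(got_d.mean() - 0.25 * nd) < 3 * se_d
        assert np.mean(h1s) < 0.5 < np.mean(h2s)

    def test_partition_conserves_every_mtdna(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(0, 10, size=(15, 2))
            counts = counts[counts.sum(1) > 0]
            cell = CellState(counts)
            d1, d2 = asymmetric_inheritance(cell, 0.3, rng)
            merged = np.concatenate([d1.counts, d2.counts])
            assert merged.sum(0).tolist() == counts.sum(0).tolist()


class TestApoptosis:
    def _cells(self, hs):
        return [CellState(np.array([[round(10 * (1 - h)), round(10 * h)]])) for h in hs]

    def test_null_rule_is_identity(self):
        cells = self._cells([0.2, 0.5, 0.9])
        out = apoptosis_filter(cells, constant(0.0), np.random.default_rng(0))
        assert out == cells

    def test_step_rule_removes_high_load_cells(self):
        cells = self._cells([0.2, 0.5, 0.9])
        out = apoptosis_filter(cells, step_apoptosis(0.6), np.random.default_rng(0))
        assert [c.heteroplasmy for c in out] == [0.2, 0.5]

    def test_logistic_rule_matches_importance_weighted_mean(self):
        """Survivor mean h equals the survival-probability-weighted mean."""
        rng = np.random.default_rng(11)
        hs = rng.integers(0, 11, size=10000) / 10
        cells = self._cells(hs)
        rule = logistic_apoptosis(0.5, 6.0)
        survive_p = 1 - rule(hs)
        expected = (hs * survive_p).sum() / survive_p.sum()
        out = apoptosis_filter(cells, rule, np.random.default_rng(12))
        got = np.array([c.heteroplasmy for c in out])
        se = got.std(ddof=1) / np.sqrt(len(got))
        assert abs(got.mean() - expected) < 3 * se
        assert got.mean() < hs.mean()


class TestGermlineTransmission:
    def test_full_pool_bottleneck_has_zero_variance(self):
        pool = MtPool(60, 40)
        founders = germline_transmission(pool, 100, 50, np.random.default_rng(0))
        assert all((p.functional, p.dysfunctional) == (60, 40) for p in founders)

    def test_single_copy_bottleneck_fixes_each_offspring(self):
        founders = germline_transmission(MtPool(50, 50), 1, 200, np.random.default_rng(1))
        assert set(p.heteroplasmy for p in founders) <= {0.0, 1.0}

    def test_founder_variance_follows_hypergeometric_law(self):
        pool = MtPool(5000, 5000)
        founders = germline_transmission(pool, 10, 20000, np.random.default_rng(2))
        h = np.array([p.heteroplasmy for p in founders])
        target = 0.5 * 0.5 / 10
        m = h - h.mean()
        se_var = np.sqrt((np.mean(m**4) - np.var(h) ** 2) / len(h))
        assert abs(h.var() - target) < 3 * se_var

    def test_binomial_sampling_option(self):
        founders = germline_transmission(
            MtPool(500, 500), 10, 5000, np.random.default_rng(3), sampling="binomial"
        )
        h = np.array([p.heteroplasmy for p in founders])
        assert abs(h.var() - 0.025) < 0.004

    def test_amplification_reaches_adult_copy_number(self):
        pools = germline_transmission(
            MtPool(50, 50), 5, 20, np.random.default_rng(4), amplify_to=100
        )
        assert all(p.total == 100 for p in pools)

    def test_bottleneck_larger_than_pool_rejected(self):
        with pytest.raises(ValueError):
            germline_transmission(MtPool(3, 3), 10, 1, np.random.default_rng(0))


class TestSelectiveImport:
    def test_zero_selectivity_is_hypergeometric(self):
        rng = np.random.default_rng(6)
        d = np.array(
            [selective_import(MtPool(50, 50), 10, 0.0, rng).dysfunctional for _ in range(3000)]
        )
        assert abs(d.mean() - 5.0) < 3 * d.std(ddof=1) / np.sqrt(len(d))

    def test_full_selectivity_prefers_functional_copies(self):
        rng = np.random.default_rng(7)
        out = selective_import(MtPool(20, 20), 10, 1.0, rng)
        assert out.dysfunctional == 0 and out.functional == 10

    def test_partial_selectivity_shifts_mean_down(self):
        rng = np.random.default_rng(8)
        d = np.array(
            [selective_import(MtPool(50, 50), 10, 0.5, rng).dysfunctional for _ in range(2000)]
        )
        assert d.mean() < 5.0


class TestRunMultilevel:
    def test_neutral_model_shows_no_systematic_trend(self):
        """All mechanisms off, delta=0: mean heteroplasmy drifts without a
        directional trend across seeds."""
        cfg = MechanismConfig()
        deltas = []
        for s in range(60):
            res = run_multilevel(cfg, 4, seed=s, initial_h=0.5)
            h = res.history.mean_h.dropna()
            if len(h):
                deltas.append(h.iloc[-1] - 0.5)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(len(deltas))
        assert abs(deltas.mean()) < 3 * se

    def test_replication_advantage_alone_drives_takeover(self):
        cfg = MechanismConfig(replication_advantage=0.5)
        finals = []
        for s in range(40):
            res = run_multilevel(cfg, 5, seed=s, initial_h=0.3)
            h = res.history.mean_h.dropna()
            if len(h):
                finals.append(h.iloc[-1])
        assert np.mean(finals) > 0.3 + 3 * np.std(finals, ddof=1) / np.sqrt(len(finals))

    def test_homoplasmic_states_are_absorbing(self):
        cfg = MechanismConfig(replication_advantage=0.4, mitophagy_rate=0.2,
                              mitophagy_selectivity=0.5, segregation_bias=0.3)
        for h0 in (0.0, 1.0):
            res = run_multilevel(cfg, 3, seed=1, initial_h=h0)
            h = res.history.mean_h.dropna()
            assert np.allclose(h, h0)

    def test_small_bottleneck_with_selection_purges_better_than_large(self):
        """Paired seeds: a tight bottleneck feeding organism-level selection
        keeps heteroplasmy lower than a wide one, all else equal."""
        wins = ties = 0
        for s in range(30):
            out = {}
            for nb in (4, 64):
                cfg = MechanismConfig(
                    replication_advantage=0.3,
                    bottleneck_size=nb,
                    organism_fecundity=linear_fecundity(4.0),
                )
                res = run_multilevel(cfg, 5, seed=s, initial_h=0.3)
                h = res.history.mean_h.dropna()
                out[nb] = h.iloc[-1] if len(h) else np.nan
            if np.isnan(out[4]) or np.isnan(out[64]):
                continue
            wins += out[4] < out[64]
            ties += out[4] == out[64]
        assert wins > (30 - ties) / 2

    def test_price_identity_holds_at_organism_level(self):
        cfg = MechanismConfig(replication_advantage=0.2,
                              organism_fecundity=linear_fecundity(3.0))
        res = run_multilevel(cfg, 5, seed=9, initial_h=0.4)
        residuals = res.history.price_residual.dropna()
        assert len(residuals) > 0
        assert (residuals.abs() < 1e-9).all()

    def test_deterministic_given_seed(self):
        cfg = MechanismConfig(replication_advantage=0.2, mitophagy_rate=0.1,
                              mitophagy_selectivity=0.5)
        a = run_multilevel(cfg, 3, seed=77)
        b = run_multilevel(cfg, 3, seed=77)
        assert a.history.equals(b.history)

    def test_annotations_reported(self):
        res = run_multilevel(MechanismConfig(), 1, seed=0)
        assert res.annotations["mitophagy_selectivity"] == ("cell↔mitochondria", "PC")
        assert res.annotations["apoptosis_rule"] == ("cell↔mtDNA", "PFF")
        assert res.annotations["organism_fecundity"][1] == "PFF"


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(replication_advantage=-0.1),
            dict(import_selectivity=1.5),
            dict(mitophagy_rate=1.0),
            dict(bottleneck_size=0),
            dict(bottleneck_sampling="poisson"),
        ],
    )
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(ValueError):
            MechanismConfig(**kw)

    def test_empty_pool_has_no_heteroplasmy(self):
        with pytest.raises(ValueError):
            MtPool(0, 0).heteroplasmy
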