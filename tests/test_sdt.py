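"""Signal detection measures, pooling rules, rmANOVA, paired t, FDR."""

from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest

from speechtrace import sdt, synth

inv = NormalDist().inv_cdf  # independent inverse-normal oracle


def toy_table():
    """4 HS trials (3 answered human), 2 NF + 2 FT trials (1 'AI' each)."""
    rows = []
    for resp in ["human", "human", "human", "AI"]:
        rows.append(dict(subject=1, session="S1", condition="HS",
                         response=resp))
    for cond in ["AI-NF", "AI-FT"]:
        rows.append(dict(subject=1, session="S1", condition=cond,
                         response="AI"))
        rows.append(dict(subject=1, session="S1", condition=cond,
                         response="human"))
    return pd.DataFrame(rows)


class TestConfusion:
    def test_hs_target_pools_both_ai_conditions(self):
        cc = sdt.build_confusion(toy_table(), "HS")
        assert (cc.hits, cc.misses) == (3, 1)
        # 4 pooled AI trials; 2 answered "AI" = correct rejections
        assert (cc.correct_rejections, cc.false_alarms) == (2, 2)

    def test_ai_target_discards_other_ai_condition(self):
        cc = sdt.build_confusion(toy_table(), "AI-FT")
        assert cc.n_target == 2           # only AI-FT trials
        assert cc.n_noise == 4            # only HS trials, AI-NF dropped
        assert cc.hits == 1               # one AI-FT trial answered "AI"
        assert cc.false_alarms == 1       # one HS trial answered "AI"

    def test_uniform_human_responses_extreme_rates(self):
        t = toy_table()
        t["response"] = "human"
        cc = sdt.build_confusion(t, "HS")
        assert cc.hit_rate == 1.0 and cc.fa_rate == 1.0

    def test_missing_target_trials_raise(self):
        t = toy_table()
        with pytest.raises(ValueError):
            sdt.build_confusion(t[t.condition != "HS"], "HS")


class TestDprimeCriterion:
    def test_equal_rates_give_zero(self):
        assert sdt.dprime(0.5, 0.5, 100, 100) == pytest.approx(0.0)
        assert sdt.criterion(0.5, 0.5, 100, 100) == pytest.approx(0.0)

    def test_textbook_values(self):
        assert sdt.dprime(0.84, 0.50, 1000, 1000) == pytest.approx(
            inv(0.84), abs=1e-9)
        assert sdt.criterion(0.84, 0.50, 1000, 1000) == pytest.approx(
            -0.5 * inv(0.84), abs=1e-9)
        assert sdt.criterion(0.16, 0.16, 1000, 1000) == pytest.approx(
            -inv(0.16), abs=1e-9)

    def test_extreme_rate_clipping_uses_cell_count(self):
        # H=1 with 20 target trials is clipped to 1 - 1/40 = 0.975
        val = sdt.dprime(1.0, 0.5, 20, 20)
        assert val == pytest.approx(inv(0.975), abs=1e-9)
        assert val == pytest.approx(1.96, abs=0.005)

    def test_inverse_normal_oracle_grid(self):
        """d'/c reproduce the closed forms on a grid of (H, F) pairs."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            h, f = rng.uniform(0.05, 0.95, 2)
            assert sdt.dprime(h, f, 10**6, 10**6) == pytest.approx(
                inv(h) - inv(f), abs=1e-6)
            assert sdt.criterion(h, f, 10**6, 10**6) == pytest.approx(
                -0.5 * (inv(h) + inv(f)), abs=1e-6)

    def test_swapping_signal_and_noise_negates_dprime(self):
        """Exchanging which class is 'signal' flips d' consistently."""
        rng = np.random.default_rng(9)
        for h, f in rng.uniform(0.1, 0.9, size=(8, 2)):
            assert sdt.dprime(f, h, 500, 500) == pytest.approx(
                -sdt.dprime(h, f, 500, 500))

    def test_rate_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            sdt.dprime(1.2, 0.5, 10, 10)

    def test_zero_trials_raise(self):
        with pytest.raises(ValueError):
            sdt.dprime(0.5, 0.5, 0, 10)


class TestRmAnova:
    def test_constant_cells_give_zero_F(self):
        y = np.tile(np.arange(4)[:, None, None], (1, 3, 2)).astype(float)
        res = sdt.rm_anova_2way(y)
        for eff in ("A", "B", "AxB"):
            assert res[eff]["F"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_sums_of_squares_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(5, 3, 2))
        res = sdt.rm_anova_2way(y)
        # oracle: pingouin's repeated-measures ANOVA
        import pingouin as pg

        n, a, b = y.shape
        df = pd.DataFrame({
            "y": y.ravel(),
            "subj": np.repeat(np.arange(n), a * b),
            "A": np.tile(np.repeat(np.arange(a), b), n),
            "B": np.tile(np.arange(b), n * a),
        })
        pr = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj",
                         detailed=True)
        for eff, label in (("A", "A"), ("B", "B"), ("AxB", "A * B")):
            row = pr[pr["Source"] == label].iloc[0]
            assert res[eff]["F"] == pytest.approx(row["F"], rel=1e-6)
            assert res[eff]["p"] == pytest.approx(row["p_unc"], rel=1e-6)
            assert res[eff]["df"] == (row["ddof1"], row["ddof2"])

    def test_degrees_of_freedom_convention(self):
        y = np.random.default_rng(0).normal(size=(30, 3, 2))
        res = sdt.rm_anova_2way(y)
        assert res["A"]["df"] == (2, 58)
        assert res["B"]["df"] == (1, 29)
        assert res["AxB"]["df"] == (2, 58)

    def test_too_few_subjects_raise(self):
        with pytest.raises(ValueError):
            sdt.rm_anova_2way(np.zeros((1, 3, 2)))


class TestPairedT:
    def test_identical_samples_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            sdt.paired_t([1, 2, 3], [1, 2, 3])

    def test_hand_computed_example(self):
        res = sdt.paired_t([1, 2, 3], [2, 3, 5])
        assert res["t"] == pytest.approx(-4.0, abs=1e-9)
        assert res["df"] == 2
        assert res["cohens_d"] == pytest.approx((-4 / 3) / np.std(
            [-1, -1, -2], ddof=1), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 10))
        a, b = sdt.paired_t(x, y), sdt.paired_t(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["p"] == pytest.approx(b["p"])


class TestFdr:
    def test_bh_hand_computation(self):
        adj = sdt.fdr_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert sdt.fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert np.allclose(sdt.fdr_adjust([0.07] * 5), 0.07)

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        adj = sdt.fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            sdt.fdr_adjust([0.5, 1.5])


class TestObserverRecovery:
    def test_closed_form_dprime_recovery(self):
        """The generative observer's d' is recovered by the SDT pipeline."""
        obs = synth.ObserverParams(
            mu={"S1": {"HS": 0.0, "AI-NF": 1.0, "AI-FT": 1.0},
                "S2": {"HS": 0.0, "AI-NF": 1.0, "AI-FT": 1.0}},
            lam={"S1": 0.5, "S2": 0.5},
            subject_sd_mu=0.0, subject_sd_lam=0.0)
        cfg = synth.SynthConfig(n_subjects=1, n_sentences_per_cell=33334,
                                speakers=3, sessions=("S1",),
                                observer_params=obs, seed=11)
        tab = sdt.sdt_table(synth.gen_behavior(cfg))
        d_nf = tab[tab.condition == "AI-NF"].d_prime.iloc[0]
        d_ft = tab[tab.condition == "AI-FT"].d_prime.iloc[0]
        assert d_nf == pytest.approx(1.0, abs=0.02)
        assert d_ft == pytest.approx(1.0, abs=0.02)

    def test_threshold_shift_moves_criterion_not_dprime(self):
        base = {"S1": {"HS": 0.0, "AI-NF": 1.0, "AI-FT": 1.0}}
        res = {}
        for lam in (0.0, 0.5):
            obs = synth.ObserverParams(mu=base, lam={"S1": lam},
                                       subject_sd_mu=0.0, subject_sd_lam=0.0)
            cfg = synth.SynthConfig(n_subjects=1, n_sentences_per_cell=33334,
                                    speakers=3, sessions=("S1",),
                                    observer_params=obs, seed=13)
            tab = sdt.sdt_table(synth.gen_behavior(cfg))
            row = tab[tab.condition == "AI-NF"].iloc[0]
            res[lam] = (row.d_prime, row.criterion)
        assert res[0.5][0] == pytest.approx(res[0.0][0], abs=0.02)
        assert res[0.5][1] - res[0.0][1] == pytest.approx(0.5, abs=0.02)
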