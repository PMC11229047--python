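"""Group x time mixed ANCOVA, Holm correction, post-hoc battery."""

import numpy as np
import pandas as pd
import pytest

from gazesweep import (
    StudyDesign,
    analyze_study,
    generate_study,
    holm_adjust,
    mixed_anova_2x3,
    posthoc_battery,
    report,
)


def make_dataset(seed=0, n=(10, 10, 10), time_shift=0.0, interaction=None,
                 pool_shift=0.0):
    """Gaussian pre/post dataset with optional injected effects."""
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for g, ng in zip(("Control", "FBEMT", "FFEMT"), n):
        for _ in range(ng):
            pid += 1
            b = rng.normal(0, 1)
            pool = "RM" if rng.random() < 0.5 else "Army"
            for ph in ("pre", "post"):
                y = b + rng.normal(0, 1)
                if ph == "post":
                    y += time_shift
                    if interaction:
                        y += interaction.get(g, 0.0)
                if pool == "RM":
                    y += pool_shift
                rows.append({"participant": f"P{pid}", "group": g, "pool": pool,
                             "phase": ph, "y": y})
    return pd.DataFrame(rows)


def oracle_split_plot(df, dv="y"):
    """Textbook balanced split-plot ANOVA from cell means and sums of squares."""
    wide = df.pivot_table(index=["participant", "group"], columns="phase",
                          values=dv).reset_index()
    y = wide[["pre", "post"]].to_numpy()
    groups = wide["group"].to_numpy()
    levels = sorted(set(groups))
    a, b = len(levels), 2
    n = len(wide) // a
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_group = sum(b * n * (y[groups == g].mean() - grand) ** 2 for g in levels)
    ss_subj = b * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_time = a * n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_cells = sum(n * (y[groups == g][:, j].mean() - grand) ** 2
                   for g in levels for j in range(b))
    ss_int = ss_cells - ss_group - ss_time
    ss_err_b = ss_subj - ss_group
    ss_err_w = ss_total - ss_subj - ss_time - ss_int
    return {
        "group": (ss_group / (a - 1)) / (ss_err_b / (a * n - a)),
        "time": ss_time / (ss_err_w / (a * n - a)),
        "group x time": (ss_int / (a - 1)) / (ss_err_w / (a * n - a)),
    }


class TestMixedAnova:
    def test_balanced_fit_equals_cell_means_oracle(self):
        df = make_dataset(seed=3, time_shift=0.4)
        res = mixed_anova_2x3(df, "y")
        oracle = oracle_split_plot(df)
        for effect, f_expected in oracle.items():
            assert res.effects[effect].F == pytest.approx(f_expected, abs=1e-8)

    def test_matches_independent_mixed_anova_implementation(self):
        pg = pytest.importorskip("pingouin")
        df = make_dataset(seed=11, time_shift=0.3, interaction={"FBEMT": 0.5})
        res = mixed_anova_2x3(df, "y")
        aov = pg.mixed_anova(data=df, dv="y", within="phase",
                             subject="participant", between="group").set_index("Source")
        assert res.effects["group"].F == pytest.approx(aov.loc["group", "F"])
        assert res.effects["time"].F == pytest.approx(aov.loc["phase", "F"])
        assert res.effects["group x time"].F == pytest.approx(aov.loc["Interaction", "F"])
        assert res.effects["group"].eta_sq == pytest.approx(aov.loc["group", "np2"])

    def test_pure_time_shift_loads_on_time_not_interaction(self):
        df = make_dataset(seed=5, time_shift=2.0)
        res = mixed_anova_2x3(df, "y")
        assert res.effects["time"].p < 1e-6
        assert res.effects["group x time"].p > 0.01

    def test_covariate_retention_follows_significance_rule(self):
        strong = mixed_anova_2x3(make_dataset(seed=2, pool_shift=3.0), "y",
                                 covariate="pool")
        assert strong.covariate_retained
        assert "covariate" in strong.effects
        null = mixed_anova_2x3(make_dataset(seed=2, pool_shift=0.0), "y",
                               covariate="pool")
        assert not null.covariate_retained
        assert "covariate" not in null.effects

    def test_dropped_covariate_refit_equals_plain_anova(self):
        df = make_dataset(seed=8)
        with_cov = mixed_anova_2x3(df, "y", covariate="pool")
        plain = mixed_anova_2x3(df, "y")
        assert not with_cov.covariate_retained
        for effect in ("group", "time", "group x time"):
            assert with_cov.effects[effect].F == pytest.approx(plain.effects[effect].F)

    def test_retained_covariate_costs_a_denominator_df(self):
        df = make_dataset(seed=2, n=(13, 13, 12), pool_shift=3.0)
        res = mixed_anova_2x3(df, "y", covariate="pool")
        assert res.covariate_retained
        assert res.effects["time"].df_den == 38 - 3 - 1
        assert res.effects["group"].df_den == 38 - 3 - 1

    def test_incomplete_participants_deleted_listwise(self):
        df = make_dataset(seed=4)
        df = df.drop(df[(df.participant == "P1") & (df.phase == "post")].index)
        res = mixed_anova_2x3(df, "y")
        assert res.n == 29

    def test_insufficient_and_degenerate_data_rejected(self):
        df = make_dataset(seed=0, n=(1, 10, 10))
        with pytest.raises(ValueError, match="insufficient"):
            mixed_anova_2x3(df, "y")
        flat = make_dataset(seed=0)
        flat["y"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            mixed_anova_2x3(flat, "y")

    def test_null_interaction_rejection_rate_near_alpha(self):
        rej = 0
        nsim = 400
        rng = np.random.default_rng(10)
        for _ in range(nsim):
            df = make_dataset(seed=int(rng.integers(2 ** 31)), n=(13, 13, 12))
            rej += mixed_anova_2x3(df, "y").effects["group x time"].p < 0.05
        assert abs(rej / nsim - 0.05) < 0.025  # 400-sim check; full run in acceptance

    def test_power_rises_with_interaction_size(self):
        rng = np.random.default_rng(21)
        power = []
        for delta in (0.0, 0.8, 1.6):
            hits = 0
            for _ in range(150):
                df = make_dataset(seed=int(rng.integers(2 ** 31)),
                                  interaction={"FBEMT": delta})
                hits += mixed_anova_2x3(df, "y").effects["group x time"].p < 0.05
            power.append(hits / 150)
        assert power[0] < power[1] < power[2]


class TestHolm:
    def test_hand_computed_step_down(self):
        assert holm_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged_and_cap_at_one(self):
        assert holm_adjust([0.7]) == pytest.approx([0.7])
        assert holm_adjust([0.5, 0.5]) == pytest.approx([1.0, 1.0])

    def test_adjusted_never_below_raw_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all((p[:, None] <= p[None, :]) <= (adj[:, None] <= adj[None, :] + 1e-15))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPosthocBattery:
    def test_family_structure_matches_three_groups(self):
        comps = posthoc_battery(make_dataset(seed=1), "y", True)
        fams = {}
        for c in comps:
            fams.setdefault(c["family"], []).append(c)
        assert len(fams["between_pre"]) == 3
        assert len(fams["between_post"]) == 3
        assert len(fams["pre_post_change"]) == 3
        assert all(c["p_holm"] >= c["p_raw"] - 1e-15 for c in comps)

    def test_suppressed_when_interaction_not_significant(self):
        assert posthoc_battery(make_dataset(seed=1), "y", False) == []

    def test_injected_shift_wins_the_paired_family(self):
        """An FBEMT-only post shift makes the FBEMT pre-post comparison
        the strongest of the paired family across 200 simulations."""
        rng = np.random.default_rng(3)
        wins = 0
        mean_p = {"FBEMT": [], "FFEMT": [], "Control": []}
        n = 200
        for _ in range(n):
            df = make_dataset(seed=int(rng.integers(2 ** 31)),
                              interaction={"FBEMT": 1.2})
            fam = [c for c in posthoc_battery(df, "y", True)
                   if c["family"] == "pre_post_change"]
            best = min(fam, key=lambda c: (c["p_holm"], c["p_raw"]))
            wins += best["label"].startswith("FBEMT")
            for c in fam:
                mean_p[c["label"].split()[0]].append(c["p_holm"])
        assert wins / n > 0.5  # clear plurality over the two null groups
        assert np.mean(mean_p["FBEMT"]) < np.mean(mean_p["FFEMT"])
        assert np.mean(mean_p["FBEMT"]) < np.mean(mean_p["Control"])


class TestReport:
    def test_reports_are_deterministic_and_ordered(self):
        design = StudyDesign(n_per_group=5, trials_per_phase=3, seed=2)
        df = generate_study(design, method="parametric")
        results = analyze_study(df, metrics=["entropy", "search_rate"])
        t1, p1 = report(results)
        t2, p2 = report(analyze_study(df, metrics=["entropy", "search_rate"]))
        assert t1 == t2 and p1 == p2
        assert t1.index("== entropy") < t1.index("== search_rate")

    def test_non_significant_interaction_noted(self):
        df = make_dataset(seed=6)
        results = analyze_study(df, metrics=["y"], covariate="pool")
        text, payload = report(results)
        if not results["y"].posthoc:
            assert "interaction not significant" in text
        assert "y" in payload and "effects" in payload["y"]
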