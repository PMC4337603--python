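"""Mixed ANOVA, post hocs, and within-subject normalization."""

import numpy as np
import pandas as pd
import pytest

from avcoherence.scheduler import CONDITIONS
from avcoherence.stats import (
    mixed_anova,
    normalize_within_subject,
    posthoc_pairwise,
    run_full_analysis,
)


def balanced_table(rng, n_per_group=16, effects=(0.3, 0.0, 0.15), group_gap=0.6):
    rows = []
    for s in range(2 * n_per_group):
        g = "pitch" if s < n_per_group else "timbre"
        base = rng.normal(2.0 if g == "pitch" else 2.0 - group_gap, 0.4)
        for c, eff in zip(CONDITIONS, effects):
            rows.append(
                dict(subject=s, group=g, condition=c, value=base + eff + rng.normal(0, 0.3))
            )
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Projection-based decomposition: sequential OLS on dummy designs.

    Model: y = mu + group + subject(group) + condition + group:condition + eps.
    Each SS is the drop in residual SS when the effect's columns join the
    design; F ratios use the split-plot error strata.
    """
    subs = pd.Categorical(df["subject"]).codes
    grps = pd.Categorical(df["group"]).codes
    conds = pd.Categorical(df["condition"]).codes
    y = df["value"].to_numpy(float)
    n = len(y)

    def dummies(codes):
        k = codes.max() + 1
        m = np.zeros((n, k))
        m[np.arange(n), codes] = 1.0
        return m

    one = np.ones((n, 1))
    G = dummies(grps)
    S = dummies(subs)
    C = dummies(conds)
    GC = dummies(grps * (conds.max() + 1) + conds)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_1 = rss(one)
    rss_g = rss(np.hstack([one, G]))
    rss_gs = rss(np.hstack([one, G, S]))
    rss_gsc = rss(np.hstack([one, G, S, C]))
    rss_full = rss(np.hstack([one, G, S, C, GC]))

    n_sub = subs.max() + 1
    a = grps.max() + 1
    b = conds.max() + 1
    ss_group, ss_subj = rss_1 - rss_g, rss_g - rss_gs
    ss_cond, ss_inter, ss_err = rss_gs - rss_gsc, rss_gsc - rss_full, rss_full
    ss_intercept = n * y.mean() ** 2
    df_subj = n_sub - a
    df_err = (b - 1) * (n_sub - a)
    ms_subj, ms_err = ss_subj / df_subj, ss_err / df_err
    return {
        "intercept": ss_intercept / ms_subj,
        "group": (ss_group / (a - 1)) / ms_subj,
        "condition": (ss_cond / (b - 1)) / ms_err,
        "interaction": (ss_inter / ((a - 1) * (b - 1))) / ms_err,
    }


class TestMixedAnova:
    def test_df_structure_matches_design(self, rng):
        tab = mixed_anova(balanced_table(rng))
        assert tuple(tab.row("group")[["df1", "df2"]]) == (1, 30)
        assert tuple(tab.row("condition")[["df1", "df2"]]) == (2, 60)
        assert tuple(tab.row("interaction")[["df1", "df2"]]) == (2, 60)
        assert tuple(tab.row("intercept")[["df1", "df2"]]) == (1, 30)

    def test_location_invariance_of_non_intercept_effects(self, rng):
        df = balanced_table(rng)
        shifted = df.assign(value=df["value"] + 100.0)
        t1, t2 = mixed_anova(df), mixed_anova(shifted)
        for eff in ("group", "condition", "interaction"):
            assert t1.F(eff) == pytest.approx(t2.F(eff), rel=1e-9)

    def test_agrees_with_projection_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for i in range(50):
            n_per = int(rng.integers(3, 10))
            df = balanced_table(
                rng, n_per_group=n_per,
                effects=tuple(rng.normal(0, 0.5, 3)), group_gap=rng.normal(0, 1),
            )
            tab = mixed_anova(df)
            oracle = anova_oracle(df)
            for eff, F in oracle.items():
                assert tab.F(eff) == pytest.approx(F, abs=1e-8, rel=1e-8)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = balanced_table(rng)
        tab = mixed_anova(df)
        ref = pg.mixed_anova(
            df, dv="value", within="condition", between="group", subject="subject"
        ).set_index("Source")
        assert tab.F("group") == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert tab.F("condition") == pytest.approx(ref.loc["condition", "F"], rel=1e-9)
        assert tab.F("interaction") == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_missing_cell_rejected(self, rng):
        df = balanced_table(rng).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(df)

    def test_single_subject_group_rejected(self, rng):
        df = balanced_table(rng, n_per_group=1)
        with pytest.raises(ValueError):
            mixed_anova(df)


class TestPosthoc:
    def test_identical_columns_null_result(self, rng):
        df = balanced_table(rng, effects=(0.0, 0.0, 0.0))
        wide = df.pivot(index="subject", columns="condition", values="value")
        dup = wide.copy()
        dup[CONDITIONS[1]] = dup[CONDITIONS[0]]
        long = dup.reset_index().melt(id_vars="subject", var_name="condition")
        res = posthoc_pairwise(long, pairs=[(CONDITIONS[0], CONDITIONS[1])])
        assert res[0].t == 0.0 and res[0].p == 1.0 and not res[0].significant

    def test_matches_hand_computed_paired_t(self, rng):
        df = balanced_table(rng)
        wide = df.pivot(index="subject", columns="condition", values="value")
        a, b = CONDITIONS[0], CONDITIONS[1]
        d = (wide[a] - wide[b]).to_numpy()
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = posthoc_pairwise(df, pairs=[(a, b)])
        assert res[0].t == pytest.approx(t_hand, abs=1e-10)
        assert res[0].mean_difference == pytest.approx(d.mean())

    def test_bonferroni_alpha_value(self, rng):
        res = posthoc_pairwise(balanced_table(rng))
        assert len(res) == 3
        for r in res:
            assert r.corrected_alpha == pytest.approx(0.05 / 3, abs=5e-4)

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame(
            dict(subject=[0, 0, 0], condition=list(CONDITIONS), value=[1.0, 2.0, 3.0])
        )
        with pytest.raises(ValueError):
            posthoc_pairwise(df)


class TestNormalization:
    def test_simple_pattern(self):
        df = pd.DataFrame(
            dict(subject=[0, 0, 0], condition=list(CONDITIONS), value=[1.0, 2.0, 3.0])
        )
        out = normalize_within_subject(df)
        assert list(out["value"]) == [-1.0, 0.0, 1.0]

    def test_per_subject_means_zero(self, rng):
        out = normalize_within_subject(balanced_table(rng))
        means = out.groupby("subject")["value"].mean()
        assert np.allclose(means, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        df = balanced_table(rng)
        once = normalize_within_subject(df)
        twice = normalize_within_subject(once)
        assert np.allclose(once["value"], twice["value"])

    def test_condition_means_shift_by_grand_pattern(self, rng):
        df = balanced_table(rng)
        out = normalize_within_subject(df)
        raw = df.groupby("condition")["value"].mean()
        # balanced: subtracting each subject's mean shifts every condition
        # mean by the grand mean
        norm = out.groupby("condition")["value"].mean()
        assert np.allclose(norm, raw - df["value"].mean(), atol=1e-12)


class TestFullAnalysis:
    def frame(self, rng):
        rows = []
        for s in range(8):
            g = "pitch" if s < 4 else "timbre"
            base = rng.normal(2.0, 0.3)
            for c, eff in zip(CONDITIONS, (0.8, 0.0, 0.4)):
                rows.append(
                    dict(
                        subject=s, task=g, condition=c,
                        d_prime=base + eff + rng.normal(0, 0.1),
                        ln_beta=rng.normal(0.5, 0.2),
                        hit_rate=rng.uniform(0.5, 0.9),
                        fa_rate=rng.uniform(0.05, 0.2),
                        visual_hit_rate=rng.uniform(0.8, 0.95),
                    )
                )
        return pd.DataFrame(rows)

    def test_five_measures_analyzed_and_posthocs_gated(self, rng):
        report = run_full_analysis(self.frame(rng))
        assert set(report.anovas) == {
            "d_prime", "ln_beta", "hit_rate", "fa_rate", "visual_hit_rate"
        }
        # the strong built-in effect must reach significance and get post hocs
        assert report.anovas["d_prime"].p("condition") < 0.05
        assert "d_prime" in report.posthocs
        for m in report.posthocs:
            assert report.anovas[m].p("condition") < 0.05

    def test_report_serialization(self, rng):
        report = run_full_analysis(self.frame(rng))
        frame = report.to_frame()
        assert set(frame["measure"]) == set(report.anovas)
        d = report.to_dict()
        assert d["alpha"] == 0.05
        assert set(d["anovas"]) == set(report.anovas)
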