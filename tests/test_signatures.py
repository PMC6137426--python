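import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motmem import classify_model, rm_anova, signature_battery
from motmem.signatures import SegmentSignatures, SignatureMatrix


def _long(y, subjects, levels_a, levels_b=None):
    """Arrange an array y[s, a(, b)] as a long table."""
    rows = []
    for si, s in enumerate(subjects):
        for ai, a in enumerate(levels_a):
            if levels_b is None:
                rows.append(dict(subject=s, a=a, y=y[si, ai]))
            else:
                for bi, b in enumerate(levels_b):
                    rows.append(dict(subject=s, a=a, b=b, y=y[si, ai, bi]))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(6, 2)) + [0.0, 0.4]
        data = _long(y, list("abcdef"), ["x", "z"])
        res = rm_anova(data, "y", "a", "subject")[0]
        t = stats.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)
        assert res.df_num == 1
        assert res.corrected is False and res.gg_epsilon is None

    def test_two_way_matches_hand_computed_sums_of_squares(self):
        """Full within-subject decomposition on a 4x2x3 fixture,
        computed from scratch with cell-mean arithmetic."""
        rng = np.random.default_rng(1)
        S, A, B = 4, 2, 3
        y = (
            rng.normal(size=(S, A, B))
            + np.array([0, 0.5])[None, :, None]
            + np.linspace(0, 0.6, B)[None, None, :]
        )
        data = _long(y, [f"s{i}" for i in range(S)], ["a0", "a1"], ["b0", "b1", "b2"])
        results = {r.effect: r for r in rm_anova(data, "y", ["a", "b"], "subject")}

        m = y.mean()
        m_s = y.mean(axis=(1, 2))
        m_a = y.mean(axis=(0, 2))
        m_b = y.mean(axis=(0, 1))
        m_sa = y.mean(axis=2)
        m_sb = y.mean(axis=1)
        m_ab = y.mean(axis=0)

        ss_a = B * S * np.sum((m_a - m) ** 2)
        ss_as = B * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
        ss_b = A * S * np.sum((m_b - m) ** 2)
        ss_bs = A * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
        ss_ab = S * np.sum(
            (m_ab - m_a[:, None] - m_b[None, :] + m) ** 2
        )
        resid = (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - m
        )
        ss_abs = np.sum(resid**2)

        expect = {
            "a": (ss_a / (A - 1)) / (ss_as / ((A - 1) * (S - 1))),
            "b": (ss_b / (B - 1)) / (ss_bs / ((B - 1) * (S - 1))),
            "a * b": (ss_ab / ((A - 1) * (B - 1)))
            / (ss_abs / ((A - 1) * (B - 1) * (S - 1))),
        }
        eta = {
            "a": ss_a / (ss_a + ss_as),
            "b": ss_b / (ss_b + ss_bs),
            "a * b": ss_ab / (ss_ab + ss_abs),
        }
        dfs = {"a": (A - 1, (A - 1) * (S - 1)), "b": (B - 1, (B - 1) * (S - 1)),
               "a * b": ((A - 1) * (B - 1), (A - 1) * (B - 1) * (S - 1))}
        for effect, f_expected in expect.items():
            r = results[effect]
            assert r.F == pytest.approx(f_expected, rel=1e-6), effect
            assert r.partial_eta_sq == pytest.approx(eta[effect], rel=1e-6)
            if not r.corrected:
                assert (r.df_num, r.df_den) == dfs[effect]

    def test_null_type_one_error_rate(self):
        """On iid noise (4 subjects x 4 levels) the delay factor is
        declared significant in about 5% of replicates."""
        rng = np.random.default_rng(2)
        n_rep, hits = 400, 0
        for _ in range(n_rep):
            y = rng.normal(size=(4, 4))
            data = _long(y, list("wxyz"), ["l1", "l2", "l3", "l4"])
            hits += rm_anova(data, "y", "a", "subject")[0].p < 0.05
        rate = hits / n_rep
        assert 0.02 <= rate <= 0.085

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 4))
        data = _long(y, list("abcdef"), ["l1", "l2", "l3", "l4"])
        res = rm_anova(data, "y", "a", "subject")[0]
        if res.gg_epsilon is not None:
            assert 0 < res.gg_epsilon <= 1

    def test_unbalanced_design_names_cell(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(4, 3))
        data = _long(y, list("wxyz"), ["l1", "l2", "l3"]).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            rm_anova(data, "y", "a", "subject")

    def test_needs_two_subjects(self):
        data = _long(np.zeros((1, 2)), ["s"], ["l1", "l2"])
        with pytest.raises(ValueError, match="subjects"):
            rm_anova(data, "y", "a", "subject")


class TestSignatureBattery:
    def test_exclusive_cohort_shows_post_only_signatures(self, exclusive_log):
        matrix = signature_battery(exclusive_log)
        assert matrix["post_deviation"].as_tuple() == (True, True, True)
        pre = matrix["pre_deviation"]
        assert pre.decay_with_delay is False
        assert pre.sr_gt_fr is False
        assert pre.sr_eq_fr1 is False  # SR is reliably below FR1
        assert classify_model(matrix).verdict == "exclusive"

    def test_shared_cohort_shows_signatures_in_both_segments(self, shared_log):
        matrix = signature_battery(shared_log)
        assert matrix["post_deviation"].as_tuple() == (True, True, True)
        pre = matrix["pre_deviation"]
        assert pre.decay_with_delay and pre.sr_gt_fr
        assert classify_model(matrix).verdict == "shared"

    def test_guessing_cohort_triggers_nothing(self, guessing_log):
        matrix = signature_battery(guessing_log)
        for segment in ("pre_deviation", "post_deviation"):
            assert matrix[segment].as_tuple() == (False, False, False)
        # performance sits at chance, so SR-above-chance never holds
        chance = matrix.tests[matrix.tests.comparison == "sr_above_chance"]
        assert not chance.significant.any()
        assert classify_model(matrix).verdict == "indeterminate"

    def test_missing_scope_is_an_error(self, exclusive_log):
        broken = exclusive_log[exclusive_log.scope == "single_report"]
        with pytest.raises(ValueError, match="full_report"):
            signature_battery(broken)

    def test_table_style_output(self, exclusive_log):
        tests = signature_battery(exclusive_log).tests
        assert {"comparison", "segment", "statistic", "p", "significant"} <= set(tests.columns)
        assert (tests.p.between(0, 1)).all()


class TestClassifyModel:
    @staticmethod
    def _matrix(pre, post):
        return SignatureMatrix(
            segments={
                "pre_deviation": SegmentSignatures(*pre),
                "post_deviation": SegmentSignatures(*post),
            },
            alpha=0.05,
            tests=pd.DataFrame(),
        )

    @pytest.mark.parametrize(
        "pre,post,verdict",
        [
            ((False, False, False), (True, True, True), "exclusive"),
            ((True, True, True), (True, True, True), "shared"),
            ((False, False, False), (False, False, False), "indeterminate"),
            ((True, True, False), (True, True, True), "shared"),
            ((False, False, True), (True, True, False), "exclusive"),
            ((True, False, False), (False, True, False), "indeterminate"),
        ],
    )
    def test_verdicts(self, pre, post, verdict):
        assert classify_model(self._matrix(pre, post)).verdict == verdict

    def test_agreement_table_mirrors_templates(self):
        v = classify_model(self._matrix((False, False, False), (True, True, True)))
        assert v.agreement.agrees_exclusive.all()
        pre_rows = v.agreement[v.agreement.segment == "pre_deviation"]
        assert not pre_rows.agrees_shared.any()
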