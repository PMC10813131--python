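"""Statistics: rank-sum, BH-FDR, signed contrasts, correlations, behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from plvnet.connectivity import ConnectivityMatrix
from plvnet.stats import (
    BehaviorRecord,
    MalformedLogError,
    behavior_contrast,
    behavior_from_events,
    edgewise_contrast,
    fdr_bh,
    group_stage_means,
    nodewise_contrast,
    ranksum_test,
    spearman_region_cesd,
    stage_durations,
)

from .oracles import bh_stepup, exact_ranksum_p, spearman_via_ranks


class TestRanksum:
    def test_frozen_exact_p_123_vs_456(self):
        """[1,2,3] vs [4,5,6]: the most extreme split, p = 2/C(6,3) = 0.1."""
        w, p = ranksum_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_oracle_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=4).astype(float)
            y = rng.integers(0, 5, size=5).astype(float)
            _, p = ranksum_test(x, y, mode="exact")
            assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_exact_limit(self, rng):
        with pytest.raises(ValueError):
            ranksum_test(np.arange(13), np.arange(13), mode="exact")

    def test_normal_approx_close_to_exact(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(loc=1.0, size=10)
        _, p_exact = ranksum_test(x, y, mode="exact")
        _, p_norm = ranksum_test(x, y, mode="normal_approx")
        assert abs(p_exact - p_norm) < 0.02

    def test_all_tied_returns_one(self):
        _, p = ranksum_test([2.0, 2.0, 2.0], [2.0, 2.0], mode="normal_approx")
        assert p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            ranksum_test([1.0, 2.0], [3.0, 4.0], mode="bogus")


class TestFdr:
    def test_matches_literal_stepup_over_many_vectors(self, rng):
        """statsmodels q-values equal the textbook step-up on 1000 vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m)
            if rng.uniform() < 0.3:
                p[: m // 2] *= 0.01  # inject some small p-values
            q, rej = fdr_bh(p, alpha=0.05)
            q_ref, rej_ref = bh_stepup(p, alpha=0.05)
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_ref)

    def test_monotone_in_pvalues(self, rng):
        p = np.sort(rng.uniform(size=20))
        q, _ = fdr_bh(p)
        assert np.all(np.diff(q) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_bh([0.5], alpha=1.5)

    def test_empty(self):
        q, rej = fdr_bh([])
        assert q.size == 0 and rej.size == 0


class TestSpearman:
    def test_equals_pearson_of_ranks(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            a = rng.normal(size=n)
            b = rng.integers(0, 6, size=n).astype(float)  # ties
            rho = float(spstats.spearmanr(a, b).statistic)
            assert rho == pytest.approx(spearman_via_ranks(a, b), abs=1e-12)

    def test_region_table(self, rng):
        cc = rng.normal(size=(12, 3))
        cesd = rng.integers(5, 30, size=12).astype(float)
        df = spearman_region_cesd(cc, cesd, ["LF", "RF", "LC"])
        assert list(df["region"]) == ["LF", "RF", "LC"]
        for k in range(3):
            assert df["rho"].iloc[k] == pytest.approx(
                spearman_via_ranks(cc[:, k], cesd), abs=1e-12
            )

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            spearman_region_cesd(rng.normal(size=(2, 3)), np.array([1.0, 2.0]))


def _matrices(rng, n_subj, n_ch, shift=0.0, band="alpha", stage="RS"):
    chans = [f"c{i}" for i in range(n_ch)]
    out = []
    for s in range(n_subj):
        v = rng.uniform(0.2, 0.6, size=(n_ch, n_ch))
        v = (np.triu(v, 1) + np.triu(v, 1).T) + shift
        np.fill_diagonal(v, 1.0)
        v = np.clip(v, 0.0, 1.0)
        out.append(ConnectivityMatrix(v, chans, band, stage, subject_id=f"s{s}"))
    return out


class TestEdgewiseContrast:
    def test_planted_shift_detected_with_sign(self, rng):
        de = _matrices(rng, 12, 6, shift=0.3)
        hc = _matrices(rng, 12, 6, shift=0.0)
        res = edgewise_contrast(de, hc, alpha=0.05)
        iu = np.triu_indices(6, k=1)
        assert res.metadata["n_tests"] == 15
        # a +0.3 global shift should light up essentially every edge as DE > HC
        assert np.mean(res.signed[iu] == 1) > 0.9
        assert res.n_significant == int(np.count_nonzero(res.signed[iu]))

    def test_null_controls_fdr(self, rng):
        de = _matrices(rng, 10, 8)
        hc = _matrices(rng, 10, 8)
        res = edgewise_contrast(de, hc, alpha=0.05)
        iu = np.triu_indices(8, k=1)
        assert np.mean(res.signed[iu] != 0) <= 0.1

    def test_qvalues_match_oracle(self, rng):
        de = _matrices(rng, 8, 5, shift=0.1)
        hc = _matrices(rng, 8, 5)
        res = edgewise_contrast(de, hc)
        iu = np.triu_indices(5, k=1)
        q_ref, _ = bh_stepup(res.pvalues[iu], alpha=0.05)
        np.testing.assert_allclose(res.qvalues[iu], q_ref, atol=1e-12)

    def test_output_matrices_symmetric_zero_diag(self, rng):
        res = edgewise_contrast(_matrices(rng, 5, 4), _matrices(rng, 5, 4))
        for mat in (res.statistic, res.pvalues, res.qvalues, res.signed):
            np.testing.assert_allclose(mat, mat.T)
            np.testing.assert_allclose(np.diag(mat), 0.0)

    def test_edge_table_shape(self, rng):
        res = edgewise_contrast(_matrices(rng, 5, 4), _matrices(rng, 5, 4))
        df = res.edge_table()
        assert len(df) == 6
        assert set(df.columns) == {"ch_i", "ch_j", "stat", "p", "q", "sign"}

    def test_mismatched_inputs_rejected(self, rng):
        de = _matrices(rng, 3, 4)
        hc = _matrices(rng, 3, 4, band="beta")
        with pytest.raises(ValueError):
            edgewise_contrast(de, hc)
        with pytest.raises(ValueError):
            edgewise_contrast(de[:1], de[1:])


class TestNodewiseContrast:
    def test_shifted_nodes_found(self, rng):
        de = rng.normal(loc=1.5, size=(12, 5))
        hc = rng.normal(loc=0.0, size=(12, 5))
        res = nodewise_contrast(de, hc, [f"c{i}" for i in range(5)], "alpha", "RS")
        assert np.all(res.signed == 1)
        assert res.n_significant == 5

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError):
            nodewise_contrast(
                rng.normal(size=(4, 3)), rng.normal(size=(4, 5)),
                [f"c{i}" for i in range(5)], "alpha", "RS",
            )


class TestBehavior:
    def _events(self, subject_id="s1", trials=2, durs=(2.0, 3.0, 4.0, 5.0)):
        rows = []
        for t in range(1, trials + 1):
            times = np.concatenate([[1.0], 1.0 + np.cumsum(durs)])
            for ev, tt in zip(
                ("start", "arm_move", "fine_adjust", "arm_move_again", "dock_complete"),
                times,
            ):
                rows.append(
                    {"subject_id": subject_id, "trial": t, "event": ev, "time_s": tt}
                )
        return pd.DataFrame(rows)

    def test_stage_durations_from_log(self):
        df = self._events(trials=1)
        d = stage_durations(df)
        assert d == {"O": 2.0, "LM": 3.0, "FO": 4.0, "D": 5.0}

    def test_malformed_order_rejected(self):
        df = self._events(trials=1)
        df.loc[2, "time_s"] = 0.5  # fine_adjust before arm_move
        df = df.sort_values("time_s").reset_index(drop=True)
        with pytest.raises(MalformedLogError):
            stage_durations(df)

    def test_missing_event_rejected(self):
        df = self._events(trials=1).iloc[:-1]
        with pytest.raises(MalformedLogError):
            stage_durations(df)

    def test_behavior_from_events_averages_trials(self):
        df = pd.concat(
            [self._events("s1", 1, (2, 3, 4, 5)), self._events("s1", 1, (4, 5, 6, 7))]
        ).reset_index(drop=True)
        df.loc[5:, "trial"] = 2
        recs = behavior_from_events(df)
        assert len(recs) == 1
        assert recs[0].stage_times == {"O": 3.0, "LM": 4.0, "FO": 5.0, "D": 6.0}
        assert recs[0].total == pytest.approx(18.0)

    def test_group_means_include_total(self):
        recs = [
            BehaviorRecord("a", {"O": 2, "LM": 3, "FO": 4, "D": 5}),
            BehaviorRecord("b", {"O": 4, "LM": 5, "FO": 6, "D": 7}),
        ]
        m = group_stage_means(recs)
        assert m == {"O": 3.0, "LM": 4.0, "FO": 5.0, "D": 6.0, "total": 18.0}

    def test_behavior_contrast_layout_and_flags(self, rng):
        de = [
            BehaviorRecord(f"d{i}", {"O": 10 + x, "LM": 26 + x, "FO": 26 + x, "D": 25 + x})
            for i, x in enumerate(rng.normal(size=10))
        ]
        hc = [
            BehaviorRecord(f"h{i}", {"O": 10 + x, "LM": 20 + x, "FO": 19 + x, "D": 24 + x})
            for i, x in enumerate(rng.normal(size=10))
        ]
        df = behavior_contrast(de, hc)
        assert list(df["measure"]) == ["O", "LM", "FO", "D", "total"]
        assert (~df["corrected"]).all()
        by = df.set_index("measure")
        assert by.loc["LM", "significant"] and by.loc["FO", "significant"]
        assert by.loc["total", "significant"]

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            BehaviorRecord("a", {"O": 0.0, "LM": 3, "FO": 4, "D": 5})
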