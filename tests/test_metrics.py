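"""Confusion counts, the nine scores, their identities, and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmseg.metrics import ConfusionCounts, aggregate, confusion, pivot_table, score


class TestConfusion:
    def test_perfect_and_inverted(self, rng):
        truth = rng.uniform(size=(8, 8)) > 0.5
        c = confusion(truth, truth)
        assert c.fp == c.fn == 0
        c_inv = confusion(~truth, truth)
        assert c_inv.tp == c_inv.tn == 0

    def test_four_pixel_enumeration(self):
        pred = np.array([1, 1, 0, 0], dtype=bool)
        truth = np.array([1, 0, 1, 0], dtype=bool)
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestScore:
    def test_balanced_toy_table(self):
        rep = score(ConfusionCounts(tp=1, fp=1, fn=1, tn=1))
        assert rep.precision == pytest.approx(0.5, abs=1e-9)
        assert rep.recall == pytest.approx(0.5, abs=1e-9)
        assert rep.f_measure == pytest.approx(0.5, abs=1e-9)
        assert rep.accuracy_pct == pytest.approx(50.0, abs=1e-9)
        assert rep.error_pct == pytest.approx(50.0, abs=1e-9)
        assert rep.mcc == pytest.approx(0.0, abs=1e-9)
        assert rep.dice == pytest.approx(0.5, abs=1e-9)
        assert rep.jaccard == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_perfect_prediction(self):
        rep = score(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        for name in ("precision", "recall", "f_measure", "mcc", "dice", "jaccard"):
            assert getattr(rep, name) == 1.0
        assert rep.accuracy_pct == 100.0

    def test_empty_overlap(self):
        rep = score(ConfusionCounts(tp=0, fp=3, fn=2, tn=5))
        assert rep.dice == 0.0 and rep.jaccard == 0.0 and rep.precision == 0.0

    def test_all_zero_ratios_default_to_zero(self):
        rep = score(ConfusionCounts(tp=0, fp=0, fn=0, tn=4))
        assert rep.precision == rep.recall == rep.dice == rep.mcc == 0.0

    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        fn=st.integers(0, 500), tn=st.integers(0, 500),
    )
    @settings(max_examples=200, deadline=None)
    def test_identities_hold_for_any_table(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = score(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        assert rep.accuracy_pct + rep.error_pct == pytest.approx(100.0, abs=1e-9)
        if rep.jaccard > 0:
            assert rep.dice == pytest.approx(
                2 * rep.jaccard / (1 + rep.jaccard), abs=1e-9
            )
        assert -1.0 <= rep.mcc <= 1.0

    def test_agrees_with_per_pixel_recount(self, rng):
        for _ in range(20):
            pred = rng.uniform(size=(16, 16)) > rng.uniform()
            truth = rng.uniform(size=(16, 16)) > rng.uniform()
            c = confusion(pred, truth)
            # brute-force oracle: walk every pixel
            tp = sum(bool(p) and bool(t) for p, t in zip(pred.ravel(), truth.ravel()))
            fp = sum(bool(p) and not t for p, t in zip(pred.ravel(), truth.ravel()))
            fn = sum(not p and bool(t) for p, t in zip(pred.ravel(), truth.ravel()))
            tn = sum(not p and not t for p, t in zip(pred.ravel(), truth.ravel()))
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert score(c).accuracy_pct == pytest.approx(
                100.0 * (tp + tn) / 256, abs=1e-9
            )

    def test_swap_symmetries(self, rng):
        pred = rng.uniform(size=(12, 12)) > 0.4
        truth = rng.uniform(size=(12, 12)) > 0.6
        a = score(confusion(pred, truth))
        b = score(confusion(truth, pred))
        assert a.accuracy_pct == b.accuracy_pct
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.dice == b.dice and a.jaccard == b.jaccard
        assert a.precision == b.recall and a.recall == b.precision


class TestAggregate:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_single_report_is_its_own_mean(self):
        rep = score(ConfusionCounts(tp=5, fp=1, fn=2, tn=10))
        df = self._frame([{"method": "fcm", **rep.as_dict()}])
        out = aggregate(df, group_keys=("method",))
        assert out.loc[0, "dice"] == rep.dice

    def test_mean_of_two_accuracies(self):
        df = self._frame(
            [
                {"method": "fcm", "accuracy_pct": 80.0},
                {"method": "fcm", "accuracy_pct": 100.0},
            ]
        )
        out = aggregate(df, group_keys=("method",))
        assert out.loc[0, "accuracy_pct"] == 90.0

    def test_six_by_five_sweep_shape(self, rng):
        rows = [
            {"method": m, "set_size": s, "dice": rng.uniform(),
             "accuracy_pct": rng.uniform(0, 100)}
            for m in ["a", "b", "c", "d", "e", "f"]
            for s in [50, 100, 500, 1000, 2000]
            for _ in range(2)
        ]
        out = aggregate(self._frame(rows), group_keys=("method", "set_size"))
        assert len(out) == 30
        wide = pivot_table(out, value="dice")
        assert wide.shape == (5, 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame())
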