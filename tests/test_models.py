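"""Model contracts: training determinism, softmax properties, refinement.

Model-quality checks here use deliberately tiny configurations; the
full-scale learnability property lives in the acceptance suite.
"""

import numpy as np
import pytest

from primood.models import (
    ModelConfig, TrainedModel, predict, predict_batch, refine_with_boundaries,
    train_model, input_gradient,
)
from primood.schema import PrimitiveClass as P
from primood.windows import make_windows
from .conftest import make_recording

TINY = dict(hidden_size=12, epochs=4, batch_size=16, embed_dim=6,
            n_conv_layers=3, learning_rate=1e-2)


def _idle_windows(n=6, seed=0):
    wins = []
    for i in range(n):
        rec = make_recording([(P.IDLE, 700)], subject=f"s{i}", seed=seed + i)
        rec.data *= 0.05          # quiet, idle-like
        wins += make_windows(rec)
    return wins


@pytest.fixture(scope="module", params=["seq2seq", "asrf"])
def idle_model(request):
    """Degenerate task: every window is idle; trains in seconds."""
    cfg = ModelConfig(arch=request.param, seed=3, label_smoothing=0.0,
                      **{**TINY, "epochs": 8})
    wins = _idle_windows()
    return cfg, train_model(cfg, wins[:-1], wins[-1:]), wins


class TestTrainModel:
    def test_degenerate_idle_task(self, idle_model):
        _, model, wins = idle_model
        held_out = _idle_windows(n=1, seed=99)[0]
        pred = predict(model, held_out)
        assert [t.label for t in pred.tokens] == [P.IDLE]
        assert pred.tokens[0].winning_probability > 0.9

    def test_training_is_deterministic(self):
        cfg = ModelConfig(arch="asrf", seed=7, **TINY)
        wins = _idle_windows()
        m1 = train_model(cfg, wins[:-1], wins[-1:])
        m2 = train_model(cfg, wins[:-1], wins[-1:])
        assert m1.val_losses == m2.val_losses
        for p1, p2 in zip(m1.net.params, m2.net.params):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_model(ModelConfig(**TINY), [], [])

    def test_wrong_n_classes_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_classes=4)

    def test_window_shape_mismatch_rejected(self, idle_model):
        _, model, wins = idle_model
        bad = _idle_windows(n=1, seed=5)[0]
        bad.input = bad.input[:, :75]
        with pytest.raises(ValueError):
            predict(model, bad)


class TestPredictContract:
    def test_softmax_properties(self, idle_model, tiny_windows):
        """Every token's winning probability is the max of a 5-class softmax."""
        _, model, _ = idle_model
        for w in tiny_windows["H02"][:5]:
            for tok in predict(model, w).tokens:
                assert 0.2 <= tok.winning_probability <= 1.0

    def test_batch_matches_single(self, idle_model, tiny_windows):
        _, model, _ = idle_model
        wins = tiny_windows["H01"][:4]
        batch = predict_batch(model, wins)
        for w, bp in zip(wins, batch):
            sp = predict(model, w)
            assert [t.label for t in sp.tokens] == [t.label for t in bp.tokens]
            np.testing.assert_allclose(
                [t.winning_probability for t in sp.tokens],
                [t.winning_probability for t in bp.tokens], rtol=1e-12)

    def test_asrf_spans_tile_middle(self, tiny_windows):
        cfg = ModelConfig(arch="asrf", seed=3, **TINY)
        wins = tiny_windows["H01"]
        model = train_model(cfg, wins[:20], wins[20:24])
        for pred in predict_batch(model, wins[:3]):
            spans = [t.frame_span for t in pred.tokens]
            assert spans[0][0] == 100 and spans[-1][1] == 500
            for (_, e), (s, _) in zip(spans, spans[1:]):
                assert e == s


class TestRefineWithBoundaries:
    def test_majority_vote(self):
        probs = np.zeros((4, 5))
        probs[:3, 0] = 0.9          # reach wins 3 frames
        probs[3, 1] = 0.9           # transport wins 1
        probs[:3, 1] = 0.05
        probs[3, 0] = 0.05
        out = refine_with_boundaries(probs, np.zeros(4, dtype=bool))
        assert (out == 0).all()

    def test_no_boundaries_single_label(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(5), size=50)
        out = refine_with_boundaries(probs, np.zeros(50, dtype=bool))
        assert len(np.unique(out)) == 1

    def test_tie_broken_by_mean_probability(self):
        probs = np.zeros((4, 5))
        # 2-2 argmax tie between classes 0 and 1; class 0 has higher mean prob
        probs[0, 0], probs[1, 0] = 0.6, 0.6
        probs[2, 1], probs[3, 1] = 0.5, 0.5
        out = refine_with_boundaries(probs, np.zeros(4, dtype=bool))
        assert (out == 0).all()

    def test_interior_boundary_gives_two_spans(self):
        probs = np.zeros((10, 5))
        probs[:5, 0] = 1.0
        probs[5:, 2] = 1.0
        flags = np.zeros(10, dtype=bool)
        flags[5] = True
        out = refine_with_boundaries(probs, flags)
        assert (out[:5] == 0).all() and (out[5:] == 2).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            refine_with_boundaries(np.zeros((5, 5)), np.zeros(4, dtype=bool))


class TestCheckpointRoundTrip:
    def test_save_load_identical_predictions(self, idle_model, tmp_path):
        cfg, model, wins = idle_model
        model.save(tmp_path / "ck")
        back = TrainedModel.load(tmp_path / "ck")
        a = predict(model, wins[0])
        b = predict(back, wins[0])
        assert [t.label for t in a.tokens] == [t.label for t in b.tokens]
        np.testing.assert_allclose([t.winning_probability for t in a.tokens],
                                   [t.winning_probability for t in b.tokens])


class TestInputGradient:
    @pytest.mark.parametrize("arch", ["seq2seq", "asrf"])
    def test_matches_finite_differences(self, arch, tiny_windows):
        """Reverse-mode input gradient vs central differences (numeric oracle)."""
        cfg = ModelConfig(arch=arch, seed=1, **TINY)
        wins = tiny_windows["H01"]
        model = train_model(cfg, wins[:16], wins[16:18])
        w = wins[20]
        pred = predict(model, w)
        g = input_gradient(model, w, pred, 0)
        assert g.shape == (600, 76)
        tok = pred.tokens[0]

        def scalar(std_window):
            # recompute the token probability from a standardized window
            from primood._autodiff import no_grad, Tensor
            with no_grad():
                ds = cfg.downsample
                x = Tensor(std_window[None])
                pooled = x.reshape(1, 600 // ds, ds, 76).mean(axis=2)
                if arch == "seq2seq":
                    logits, _ = model.net.decode(model.net.encode(pooled), 1)
                    return logits[:, 0, :].softmax(axis=-1).data[0, tok.label.index]
                cls_logits, _ = model.net.forward(pooled)
                lo = 100 // ds
                s, e = tok.frame_span
                ds_s = (s - 100) // ds + lo
                ds_e = max((e - 100 + ds - 1) // ds + lo, ds_s + 1)
                probs = cls_logits.softmax(axis=-1).data[0, ds_s:ds_e, tok.label.index]
                return probs.mean()

        std_w = model.standardizer.apply(w.input)
        rng = np.random.default_rng(0)
        h = 1e-3
        checked = 0
        for _ in range(20):
            i, j = rng.integers(0, 600), rng.integers(0, 76)
            xp, xm = std_w.copy(), std_w.copy()
            xp[i, j] += h
            xm[i, j] -= h
            fd = (scalar(xp) - scalar(xm)) / (2 * h)
            if abs(fd) < 1e-7:
                continue
            assert abs(abs(fd) - g[i, j]) / abs(fd) < 1e-3
            checked += 1
        assert checked >= 5
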