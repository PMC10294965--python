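"""The two primitive classifiers and their shared prediction contract.

Both models consume a raw 600 x 76 window, standardize it with statistics
fit on their training split, average-pool the time axis (factor 10, so the
recurrences/convolutions run over 60 steps), and expose winner-take-all
softmax probabilities over the five primitive classes:

* ``seq2seq`` — three-layer bidirectional GRU encoder into a single-layer
  GRU decoder that emits an ordered token sequence.  End-of-sequence is a
  separate sigmoid stop head, so each emitted token's confidence is the
  maximum of a genuine 5-class softmax (hence always >= 0.2).
* ``asrf`` — a dilated temporal-convolution segmentation head plus a
  boundary-detection head; framewise labels are refined by majority vote
  between detected boundaries, and runs collapse to tokens whose
  confidence is the mean winning framewise probability over the run.

Standardization and pooling live inside the differentiable graph, so
gradients of a token's confidence with respect to the raw 600 x 76 input
are available for attribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from ._autodiff import Tensor, concat, no_grad
from .schema import PrimitiveClass
from .windows import (
    Standardizer, WindowExample, WINDOW_FRAMES, TARGET_LO, TARGET_HI,
    filter_min_run, MIN_RUN_FRAMES,
)

__all__ = [
    "ModelConfig", "PredictedPrimitive", "WindowPrediction", "TrainedModel",
    "train_model", "predict", "predict_batch", "refine_with_boundaries",
]

N_CLASSES = 5
START_TOKEN = 5
BOUNDARY_NMS_RADIUS = 25      # frames (0.25 s) for boundary non-max suppression
BOUNDARY_THRESHOLD = 0.5


@dataclass
class ModelConfig:
    arch: str = "seq2seq"                 # seq2seq | asrf
    hidden_size: int = 64
    n_encoder_layers: int = 3             # bidirectional
    n_decoder_layers: int = 1
    n_conv_layers: int = 4                # dilations 1, 2, 4, ... for asrf
    kernel_size: int = 3
    n_classes: int = N_CLASSES
    max_output_tokens: int = 12
    epochs: int = 18
    learning_rate: float = 5e-3
    batch_size: int = 32
    seed: int = 0
    downsample: int = 10
    class_weighting: bool = True
    label_smoothing: float = 0.1
    weight_decay: float = 1e-3
    augment_noise_sd: float = 0.0     # Gaussian jitter on standardized inputs
    embed_dim: int = 16

    def __post_init__(self):
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")
        if self.arch not in ("seq2seq", "asrf"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.arch == "seq2seq" and self.n_decoder_layers != 1:
            raise ValueError("seq2seq uses a single-layer decoder")
        if WINDOW_FRAMES % self.downsample != 0:
            raise ValueError("downsample must divide the window length")


@dataclass(frozen=True)
class PredictedPrimitive:
    label: PrimitiveClass
    winning_probability: float
    subject_id: str
    trial_id: str
    start_frame: int
    token_index: int
    frame_span: tuple[int, int] | None = None   # asrf only, within [100, 500)


@dataclass
class WindowPrediction:
    tokens: list[PredictedPrimitive]


# --------------------------------------------------------------------- nets

class _Seq2SeqNet:
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        H, E = cfg.hidden_size, cfg.embed_dim
        self.cfg = cfg
        self.enc: list[tuple[nn.GRULayer, nn.GRULayer]] = []
        d_in = 76
        for _ in range(cfg.n_encoder_layers):
            self.enc.append((nn.GRULayer(d_in, H, rng), nn.GRULayer(d_in, H, rng)))
            d_in = 2 * H
        self.bridge = nn.Linear(2 * H, H, rng)
        # the decoder is driven by learned *positional* inputs, so every
        # bit of class evidence must flow through the encoder state; the
        # token sequence cannot be rote-completed from its own prefix
        self.embed = Tensor(rng.normal(0, 0.1, size=(cfg.max_output_tokens + 1,
                                                     cfg.embed_dim)),
                            requires_grad=True)
        self.dec = nn.GRULayer(E, H, rng)
        self.cls = nn.Linear(H, N_CLASSES, rng)
        self.stop = nn.Linear(H, 1, rng)

    @property
    def params(self):
        ps = []
        for f, b in self.enc:
            ps += f.params + b.params
        ps += self.bridge.params + [self.embed] + self.dec.params
        ps += self.cls.params + self.stop.params
        return ps

    def encode(self, x: Tensor) -> Tensor:
        """x: (B, T, 76) pooled+standardized -> decoder initial state (B, H)."""
        h = x
        for f, b in self.enc:
            h = concat([nn.gru(h, f), nn.gru(h, b, reverse=True)], axis=-1)
        last_f = h[:, -1, : self.cfg.hidden_size]
        first_b = h[:, 0, self.cfg.hidden_size:]
        return self.bridge(concat([last_f, first_b], axis=-1)).tanh()

    def decode(self, h0: Tensor, n_steps: int) -> tuple[Tensor, Tensor]:
        """Unroll the decoder for n_steps; returns (class logits, stop logits)."""
        B = h0.shape[0]
        pos = np.broadcast_to(np.arange(n_steps), (B, n_steps))
        emb = self.embed[pos.ravel()].reshape(B, n_steps, self.cfg.embed_dim)
        out = nn.gru(emb, self.dec, h0=h0)
        return self.cls(out), self.stop(out)


class _ASRFNet:
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        H = cfg.hidden_size
        self.cfg = cfg
        self.proj = nn.Linear(76, H, rng)
        self.blocks = [nn.Conv1d(H, H, cfg.kernel_size, 2 ** i, rng)
                       for i in range(cfg.n_conv_layers)]
        self.cls = nn.Linear(H, N_CLASSES, rng)
        self.bnd = nn.Linear(H, 1, rng)

    @property
    def params(self):
        ps = self.proj.params
        for blk in self.blocks:
            ps += blk.params
        return ps + self.cls.params + self.bnd.params

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.proj(x)
        for blk in self.blocks:
            h = h + blk(h).relu()
        return self.cls(h), self.bnd(h)


# ----------------------------------------------------------------- container

@dataclass
class TrainedModel:
    config: ModelConfig
    net: object
    standardizer: Standardizer
    schema_hash: str
    val_losses: list[float] = field(default_factory=list)

    def _graph_input(self, raw: np.ndarray, requires_grad: bool = False):
        """Raw (B, 600, 76) -> standardized leaf and pooled model input.

        The differentiable leaf is the *standardized* window, so input
        gradients are expressed in standardized units: channels are
        compared on a common scale instead of being dominated by the
        1/sd factor of quiet channels.
        """
        x = Tensor(self.standardizer.apply(raw), requires_grad=requires_grad)
        ds = self.config.downsample
        B, T = raw.shape[0], raw.shape[1]
        pooled = x.reshape(B, T // ds, ds, 76).mean(axis=2)
        return x, pooled

    # persistence --------------------------------------------------------
    def save(self, path):
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.net.params)}
        arrays["mean"] = self.standardizer.mean
        arrays["sd"] = self.standardizer.sd
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = dict(config=asdict(self.config), schema_hash=self.schema_hash,
                    val_losses=self.val_losses)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**meta["config"])
        rng = np.random.default_rng(0)
        net = _Seq2SeqNet(cfg, rng) if cfg.arch == "seq2seq" else _ASRFNet(cfg, rng)
        with np.load(path.with_suffix(".npz")) as z:
            for i, p in enumerate(net.params):
                p.data = z[f"p{i}"]
            std = Standardizer(z["mean"], z["sd"])
        return cls(cfg, net, std, meta["schema_hash"], meta["val_losses"])


def schema_fingerprint(names: list[str]) -> str:
    import hashlib
    return hashlib.sha1("|".join(names).encode()).hexdigest()[:12]


# ------------------------------------------------------------------ training

def _token_arrays(windows: list[WindowExample]):
    seqs = [[p.index for p in w.target_sequence] for w in windows]
    return seqs


def _class_weights_tokens(seqs) -> np.ndarray:
    counts = np.bincount([t for s in seqs for t in s], minlength=N_CLASSES).astype(float)
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (N_CLASSES * counts)
    return w


def _seq2seq_batch_loss(net: _Seq2SeqNet, model: TrainedModel, raw, seqs, weights):
    B = raw.shape[0]
    seqs = [s[: net.cfg.max_output_tokens] for s in seqs]
    L = max(len(s) for s in seqs)
    lens = np.array([len(s) for s in seqs])
    _, pooled = model._graph_input(raw)
    h0 = net.encode(pooled)
    cls_logits, stop_logits = net.decode(h0, L + 1)
    flat_cls = cls_logits.reshape(B * (L + 1), N_CLASSES)
    rows, tgt = [], []
    for i, s in enumerate(seqs):
        for t, tok in enumerate(s):
            rows.append(i * (L + 1) + t)
            tgt.append(tok)
    sel = flat_cls[np.asarray(rows)]
    loss = nn.cross_entropy(sel, np.asarray(tgt), weights,
                            smoothing=model.config.label_smoothing)
    # stop head: 0 before the end of the sequence, 1 at it
    srows, sy = [], []
    for i, n in enumerate(lens):
        for t in range(n + 1):
            srows.append(i * (L + 1) + t)
            sy.append(1.0 if t == n else 0.0)
    z = stop_logits.reshape(B * (L + 1), 1)[np.asarray(srows)].reshape(-1)
    y = np.asarray(sy)
    bce = (z.relu() - z * y + (1.0 + (-z.abs()).exp()).log()).mean()
    return loss + 0.5 * bce


def _downsample_targets(target_frames: np.ndarray, ds: int) -> np.ndarray:
    """Majority label per pooled chunk of the middle 400 frames."""
    chunks = target_frames.reshape(-1, ds)
    out = np.empty(chunks.shape[0], dtype=np.int64)
    for i, c in enumerate(chunks):
        out[i] = np.bincount(c, minlength=N_CLASSES).argmax()
    return out


def _asrf_batch_loss(net: _ASRFNet, model: TrainedModel, raw, tgt_ds, weights):
    B = raw.shape[0]
    ds = model.config.downsample
    lo, hi = TARGET_LO // ds, TARGET_HI // ds
    _, pooled = model._graph_input(raw)
    cls_logits, bnd_logits = net.forward(pooled)
    mid = cls_logits[:, lo:hi, :]
    n_mid = hi - lo
    flat = mid.reshape(B * n_mid, N_CLASSES)
    loss = nn.cross_entropy(flat, tgt_ds.reshape(-1), weights,
                            smoothing=model.config.label_smoothing)
    # boundary targets: label changes on the pooled grid
    yb = np.zeros((B, n_mid))
    yb[:, 1:] = (np.diff(tgt_ds, axis=1) != 0).astype(float)
    z = bnd_logits[:, lo:hi, :].reshape(B * n_mid)
    y = yb.reshape(-1)
    pos_w = max(1.0, (y.size - y.sum()) / max(y.sum(), 1.0))
    w = np.where(y > 0, pos_w, 1.0)
    bce_el = z.relu() - z * y + (1.0 + (-z.abs()).exp()).log()
    bce = (bce_el * w).sum() / w.sum()
    return loss + bce


def train_model(config: ModelConfig, train: list[WindowExample],
                val: list[WindowExample], schema_hash: str = "") -> TrainedModel:
    """Train one model version; deterministic in (config.seed, data order)."""
    if not train:
        raise ValueError("empty training set")
    for w in train + val:
        if w.input.shape != (WINDOW_FRAMES, 76):
            raise ValueError(f"window shape {w.input.shape} does not match schema")
    rng = np.random.default_rng(config.seed)
    net = _Seq2SeqNet(config, rng) if config.arch == "seq2seq" else _ASRFNet(config, rng)
    std = Standardizer.fit(train)
    model = TrainedModel(config, net, std, schema_hash)
    opt = nn.Adam(net.params, lr=config.learning_rate,
                  weight_decay=config.weight_decay)

    raw_train = np.stack([w.input for w in train])
    if config.arch == "seq2seq":
        seqs = _token_arrays(train)
        weights = _class_weights_tokens(seqs) if config.class_weighting else None
        val_seqs = _token_arrays(val) if val else None
    else:
        ds = config.downsample
        tgt_ds = np.stack([_downsample_targets(w.target_frames, ds) for w in train])
        counts = np.bincount(tgt_ds.ravel(), minlength=N_CLASSES).astype(float)
        counts = np.maximum(counts, 1.0)
        weights = counts.sum() / (N_CLASSES * counts) if config.class_weighting else None
        val_tgt = (np.stack([_downsample_targets(w.target_frames, ds) for w in val])
                   if val else None)
    raw_val = np.stack([w.input for w in val]) if val else None

    n = len(train)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            opt.zero_grad()
            batch = raw_train[idx]
            if config.augment_noise_sd > 0:
                # jitter in standardized units: weights on uninformative
                # channels then actively cost loss variance
                batch = batch + rng.normal(0.0, config.augment_noise_sd,
                                           size=batch.shape) * std.sd
            if config.arch == "seq2seq":
                loss = _seq2seq_batch_loss(net, model, batch,
                                           [seqs[i] for i in idx], weights)
            else:
                loss = _asrf_batch_loss(net, model, batch, tgt_ds[idx], weights)
            loss.backward()
            opt.step()
        if val:
            with no_grad():
                if config.arch == "seq2seq":
                    vl = _seq2seq_batch_loss(net, model, raw_val, val_seqs, weights)
                else:
                    vl = _asrf_batch_loss(net, model, raw_val, val_tgt, weights)
            model.val_losses.append(float(vl.data))
    return model


# ----------------------------------------------------------------- inference

def refine_with_boundaries(framewise_probs: np.ndarray,
                           boundary_flags: np.ndarray) -> np.ndarray:
    """Relabel frames to the majority argmax class between boundaries.

    Ties are broken by higher mean softmax probability of the tied classes
    over the span, then by fixed class order.
    """
    T = framewise_probs.shape[0]
    if boundary_flags.shape[0] != T:
        raise ValueError("shape mismatch")
    argmax = framewise_probs.argmax(axis=1)
    cuts = [0] + [t for t in range(1, T) if boundary_flags[t]] + [T]
    out = np.empty(T, dtype=np.int64)
    for s, e in zip(cuts[:-1], cuts[1:]):
        if s == e:
            continue
        votes = np.bincount(argmax[s:e], minlength=framewise_probs.shape[1])
        best = votes.max()
        tied = np.flatnonzero(votes == best)
        if tied.size > 1:
            mean_p = framewise_probs[s:e, tied].mean(axis=0)
            tied = tied[np.flatnonzero(mean_p == mean_p.max())]
        out[s:e] = tied[0]
    return out


def _detect_boundaries(bprob: np.ndarray) -> np.ndarray:
    """Threshold at 0.5 + non-maximum suppression over a 25-frame radius."""
    flags = np.zeros(bprob.shape[0], dtype=bool)
    cand = np.flatnonzero(bprob > BOUNDARY_THRESHOLD)
    order = cand[np.lexsort((cand, -bprob[cand]))]   # prob desc, index asc
    taken: list[int] = []
    for t in order:
        if all(abs(t - u) > BOUNDARY_NMS_RADIUS for u in taken):
            taken.append(int(t))
    flags[taken] = True
    return flags


def _asrf_window_probs(model: TrainedModel, raw: np.ndarray):
    """(B, 600, 76) -> middle-frame softmax (B, 400, 5) and boundary prob (B, 400)."""
    ds = model.config.downsample
    lo, hi = TARGET_LO // ds, TARGET_HI // ds
    _, pooled = model._graph_input(raw)
    cls_logits, bnd_logits = model.net.forward(pooled)
    probs = cls_logits.softmax(axis=-1).data[:, lo:hi, :]
    bprob = 1.0 / (1.0 + np.exp(-bnd_logits.data[:, lo:hi, 0]))
    return np.repeat(probs, ds, axis=1), np.repeat(bprob, ds, axis=1)


def predict_batch(model: TrainedModel, windows: list[WindowExample]) -> list[WindowPrediction]:
    """Predict many windows at once (winner-take-all on the 5-class softmax)."""
    if not windows:
        return []
    for w in windows:
        if w.input.shape != (WINDOW_FRAMES, 76):
            raise ValueError("window shape mismatch")
    raw = np.stack([w.input for w in windows])
    cfg = model.config
    out: list[WindowPrediction] = []
    with no_grad():
        if cfg.arch == "seq2seq":
            net: _Seq2SeqNet = model.net
            _, pooled = model._graph_input(raw)
            h0 = net.encode(pooled)
            B = raw.shape[0]
            cls_logits, stop_logits = net.decode(h0, cfg.max_output_tokens)
            probs_all = cls_logits.softmax(axis=-1).data
            stop_all = 1.0 / (1.0 + np.exp(-stop_logits.data[..., 0]))
            toks: list[list[tuple[int, float]]] = [[] for _ in range(B)]
            for i in range(B):
                for step in range(cfg.max_output_tokens):
                    if stop_all[i, step] > 0.5 and step > 0:
                        break
                    lab = int(probs_all[i, step].argmax())
                    toks[i].append((lab, float(probs_all[i, step, lab])))
            for w, tk in zip(windows, toks):
                out.append(WindowPrediction([
                    PredictedPrimitive(PrimitiveClass.from_index(lb), p,
                                       w.subject_id, w.trial_id, w.start_frame, j)
                    for j, (lb, p) in enumerate(tk)]))
        else:
            probs_all, bprob_all = _asrf_window_probs(model, raw)
            for w, probs, bprob in zip(windows, probs_all, bprob_all):
                flags = _detect_boundaries(bprob)
                labels = refine_with_boundaries(probs, flags)
                labels = filter_min_run(labels, MIN_RUN_FRAMES)
                tokens = []
                s = 0
                j = 0
                for t in range(1, labels.size + 1):
                    if t == labels.size or labels[t] != labels[s]:
                        lab = int(labels[s])
                        wp = float(probs[s:t, lab].mean())
                        tokens.append(PredictedPrimitive(
                            PrimitiveClass.from_index(lab), wp, w.subject_id,
                            w.trial_id, w.start_frame, j,
                            frame_span=(s + TARGET_LO, t + TARGET_LO)))
                        j += 1
                        s = t
                out.append(WindowPrediction(tokens))
    return out


def predict(model: TrainedModel, window: WindowExample) -> WindowPrediction:
    return predict_batch(model, [window])[0]


# --------------------------------------------------------------- attribution

def input_gradient(model: TrainedModel, window: WindowExample,
                   prediction: WindowPrediction, token_index: int) -> np.ndarray:
    """|d winning_probability / d input| for one predicted token, (600, 76).

    The gradient is taken of the post-softmax winning-class probability
    (in standardized input units); for asrf the scalar is the mean winning
    framewise probability over the token's (pre-collapse) span.
    """
    if not 0 <= token_index < len(prediction.tokens):
        raise IndexError(f"token index {token_index} out of range")
    cfg = model.config
    raw = window.input[None]
    tok = prediction.tokens[token_index]
    if cfg.arch == "seq2seq":
        net: _Seq2SeqNet = model.net
        x, pooled = model._graph_input(raw, requires_grad=True)
        h0 = net.encode(pooled)
        cls_logits, _ = net.decode(h0, token_index + 1)
        prob = cls_logits[:, token_index, :].softmax(axis=-1)[0, tok.label.index]
        prob.backward()
    else:
        ds = cfg.downsample
        lo = TARGET_LO // ds
        x, pooled = model._graph_input(raw, requires_grad=True)
        cls_logits, _ = model.net.forward(pooled)
        s, e = tok.frame_span
        ds_s, ds_e = (s - TARGET_LO) // ds + lo, max((e - TARGET_LO + ds - 1) // ds + lo,
                                                     (s - TARGET_LO) // ds + lo + 1)
        span_probs = cls_logits[:, ds_s:ds_e, :].softmax(axis=-1)[0, :, tok.label.index]
        span_probs.mean().backward()
    return np.abs(x.grad[0])
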