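"""The sequence-to-contact CNN: architecture, training and prediction.

The network maps a CSCN-encoded window (4 x window_bp) to the zigzag pole of
contact values, one per genomic distance:

* a chromatin-feature stack of five convolution layers (ReLU, max pooling,
  dropout) compresses the base-pair sequence 1000-fold,
* ten gated dilated convolution blocks (residual ``tanh * sigmoid`` gating)
  model long-range context across the window,
* a final dense head maps the flattened features to the pole — a distinct
  set of weights for every genomic distance.

Training follows the summed-haplotype scheme: windows come from SV-free
regions only, the two haplotype contigs of a window are forwarded separately
and their predicted poles are summed before the mean-squared-error loss
against the observed *raw* total counts.  Optimization is Adam
(learning rate 1e-3, epsilon 0.1) with L2 strength 1e-3 on all trainable
weights, batch size 1, at most 10 epochs, keeping the best-validation state.

Targets stay in raw count units (the Adam epsilon is calibrated for
raw-count gradient magnitudes); the head bias starts at the per-distance
mean of the training targets so the optimizer spends its budget on
sequence-dependent structure rather than on the overall decay level.  The
convolution stack can be pretrained on a cheap sequence-feature task
(:func:`pretrain_conv_stack`) and loaded through ``build_predictor``'s
``pretrained`` hook — the desk-scale analog of transferring a
chromatin-feature model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .contigs import encode_cscn
from .genome import reverse_complement
from .hic import ContactMatrix, ZigzagPole, pole_to_matrix
from .nn import F32, Adam, Conv1d, Dense, Dropout, GatedBlock, MaxPool, ReLU, Sequential


@dataclass(frozen=True)
class PredictorConfig:
    conv_units: tuple[int, ...] = (300, 600, 600, 900, 900)
    conv_kernels: tuple[int, ...] = (8, 8, 8, 4, 4)
    pool_widths: tuple[int, ...] = (4, 5, 5, 5, 2)
    dropout: float = 0.2
    dilated_units: int = 100
    dilated_kernel: int = 3
    dilation_rates: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128, 256, 1)
    window_bp: int = 1_040_000
    resolution: int = 40_000

    def __post_init__(self):
        if not (len(self.conv_units) == len(self.conv_kernels) == len(self.pool_widths)):
            raise ValueError("conv_units, conv_kernels and pool_widths must align")
        if self.window_bp % self.resolution:
            raise ValueError("window must be a whole number of bins")
        if self.window_bp % self.pool_factor:
            raise ValueError("window length must survive the pooling stack evenly")
        if self.feature_length < 1:
            raise ValueError("pooling stack collapses the window to nothing")

    @property
    def pool_factor(self) -> int:
        return int(np.prod(self.pool_widths))

    @property
    def window_bins(self) -> int:
        return self.window_bp // self.resolution

    @property
    def pole_length(self) -> int:
        """Targets per window: one contact value per distance 1..n-1."""
        return self.window_bins - 1

    @property
    def feature_length(self) -> int:
        return self.window_bp // self.pool_factor

    @classmethod
    def two_megabase(cls, **kw) -> "PredictorConfig":
        return cls(window_bp=2_000_000, resolution=40_000, **kw)

    @classmethod
    def ten_kb(cls, **kw) -> "PredictorConfig":
        return cls(window_bp=1_020_000, resolution=10_000, **kw)

    @classmethod
    def scaled_down(cls, factor: int = 10) -> "PredictorConfig":
        """Desk-scale config: window 104 kb at 4-kb resolution, units / factor.

        Dropout is disabled here: stochastic regularization sized for the
        full model prevents any fit within the small step budget this
        configuration trains for.
        """
        return cls(
            conv_units=tuple(max(1, u // factor) for u in (300, 600, 600, 900, 900)),
            dilated_units=max(1, 100 // factor),
            window_bp=104_000,
            resolution=4_000,
            dropout=0.0,
        )


@dataclass
class TrainHyper:
    learning_rate: float = 1e-3
    epsilon: float = 0.1
    l2_strength: float = 1e-3
    batch_size: int = 1
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainSample:
    """One training window: the haplotype contig sequences and the total pole.

    ``seqs``/``mus`` hold at most two contigs (the summed-haplotype training
    simplification after breakpoint removal); sequences are encoded lazily.
    """

    seqs: tuple[str, ...]
    mus: tuple[int, ...]
    target: np.ndarray

    def __post_init__(self):
        if len(self.seqs) > 2:
            raise ValueError("training windows carry at most two haplotype contigs")
        if len(self.seqs) != len(self.mus):
            raise ValueError("one copy number per contig")
        self.target = np.asarray(self.target, dtype=float)


@dataclass
class PredictorState:
    cfg: PredictorConfig
    net: Sequential
    head: Dense
    seed: int
    target_scale: float = 1.0
    history: list[dict] = field(default_factory=list)


def _build_net(cfg: PredictorConfig, rng) -> tuple[Sequential, Dense]:
    layers = []
    c_prev = 4
    for u, k, p in zip(cfg.conv_units, cfg.conv_kernels, cfg.pool_widths):
        layers += [Conv1d(c_prev, u, k, rng=rng), ReLU(), MaxPool(p), Dropout(cfg.dropout)]
        c_prev = u
    layers[0].input_grad = False  # no gradient needed w.r.t. the input encoding
    layers.append(Conv1d(c_prev, cfg.dilated_units, 1, rng=rng))  # channel projection
    for rate in cfg.dilation_rates:
        layers.append(GatedBlock(cfg.dilated_units, cfg.dilated_kernel, rate, rng))
    head = Dense(cfg.dilated_units * cfg.feature_length, cfg.pole_length, rng)
    layers.append(head)
    return Sequential(layers), head


def build_predictor(
    cfg: PredictorConfig,
    pretrained: list[np.ndarray] | None = None,
    seed: int = 0,
) -> PredictorState:
    """Assemble the network; optionally load pretrained chromatin-stack weights.

    ``pretrained`` is a flat list of arrays matching the parameters of the
    five convolution layers in order (the transfer-learning entry point);
    without it all layers get a seeded He-style initialization.
    """
    rng = np.random.default_rng(seed)
    net, head = _build_net(cfg, rng)
    if pretrained is not None:
        conv_params = _conv_stack_params(net, cfg)
        proj_params = net.layers[4 * len(cfg.conv_units)].parameters()
        if len(pretrained) == len(conv_params):
            targets = conv_params
        elif len(pretrained) == len(conv_params) + len(proj_params):
            targets = conv_params + proj_params
        else:
            raise ValueError("pretrained weight list does not match the conv stack")
        for p, w in zip(targets, pretrained):
            w = np.asarray(w, dtype=F32)
            if w.shape != p.value.shape:
                raise ValueError(f"pretrained shape {w.shape} != {p.value.shape}")
            p.value[...] = w
    return PredictorState(cfg, net, head, seed)


def _conv_stack_params(net: Sequential, cfg: PredictorConfig):
    out = []
    for lay in net.layers[: 4 * len(cfg.conv_units)]:
        out.extend(lay.parameters())
    return out


def _shared_params(net: Sequential, cfg: PredictorConfig):
    """All parameters except the distance-specific head."""
    out = []
    for lay in net.layers[:-1]:
        out.extend(lay.parameters())
    return out


def _forward_counts(state: PredictorState, x: np.ndarray) -> np.ndarray:
    # the engine is position-major: (length, channels)
    y, _ = state.net.forward(np.ascontiguousarray(x.T, dtype=F32), train=False)
    return np.maximum(y.astype(float) * state.target_scale, 0.0)


def _reverse_input(x: np.ndarray) -> np.ndarray:
    # reverse complement of a CSCN matrix: flip positions; row order A,C,G,T
    # maps to T,G,C,A, i.e. the row axis simply reverses
    return x[::-1, ::-1]


def predict_pole(
    state: PredictorState, cscn: np.ndarray, strand_average: bool = False
) -> np.ndarray:
    """Predict the contact pole for one encoded window.

    With ``strand_average`` the forward prediction and the prediction on the
    reverse-complemented input (re-indexed to the mirrored window) are
    averaged.  Counts are clamped at zero.
    """
    cscn = np.asarray(cscn)
    if cscn.shape != (4, state.cfg.window_bp):
        raise ValueError(
            f"expected a 4 x {state.cfg.window_bp} encoding, got {cscn.shape}"
        )
    fwd = _forward_counts(state, cscn)
    if not strand_average:
        return fwd
    rev = _forward_counts(state, _reverse_input(cscn))
    return 0.5 * (fwd + rev)


def predict_decode(
    state: PredictorState, onehot: np.ndarray, mu: int, strand_average: bool = False
) -> np.ndarray:
    """CSCN-decoding prediction: one-hot input, output scaled by copy number."""
    if mu < 1:
        raise ValueError("mu must be >= 1")
    if onehot.max(initial=0) > 1:
        raise ValueError("decoding mode expects a one-hot (mu=1) encoding")
    return mu * predict_pole(state, onehot, strand_average=strand_average)


def train_total(
    state: PredictorState,
    samples: list[TrainSample],
    hyper: TrainHyper,
    val_samples: list[TrainSample] = (),
    selection: str = "correlation",
    train_conv_stack: bool = True,
) -> PredictorState:
    """Fit the predictor on summed-haplotype windows with MSE on raw counts.

    Keeps the parameters of the best validation epoch (or the final epoch
    when no validation set is given).  ``selection`` picks the criterion:
    ``"correlation"`` (default) keeps the epoch with the highest mean
    per-distance correlation between predicted and observed validation
    poles — the deployment metric, robust to the Poisson noise floor that
    masks MSE differences — while ``"mse"`` keeps the lowest validation
    MSE.  Training history (per-epoch train/validation MSE and validation
    correlation) is appended to ``state.history``.
    """
    if selection not in ("correlation", "mse"):
        raise ValueError("selection must be 'correlation' or 'mse'")
    # With ``train_conv_stack=False`` the (typically pretrained) convolution
    # stack is frozen: only the projection, dilated blocks and head update,
    # and backpropagation stops at the projection layer.  This is the
    # small-data transfer-learning mode — fine-tuning the feature stack on
    # few windows trades its transferable features for memorization.
    if not samples:
        raise ValueError("no training samples")
    k = state.cfg.pole_length
    for s in samples:
        if len(s.target) != k:
            raise ValueError("target pole length does not match the config")

    all_targets = np.stack([s.target for s in samples])
    # targets stay in raw count units: Adam's epsilon (0.1) is calibrated for
    # raw-count gradient magnitudes and would dominate normalized gradients
    scale = 1.0
    state.target_scale = scale
    if not np.any(state.head.b.value):
        state.head.b.value[...] = (all_targets.mean(axis=0) / scale).astype(F32)

    n_frozen = 4 * len(state.cfg.conv_units) + 1  # conv stack + channel projection
    if train_conv_stack:
        params = state.net.parameters()
    else:
        params = []
        for lay in state.net.layers[n_frozen:]:
            params.extend(lay.parameters())
        state.net.layers[n_frozen - 1].input_grad = False  # stop backprop at the trunk
    opt = Adam(params, lr=hyper.learning_rate, eps=hyper.epsilon, l2=hyper.l2_strength)
    rng = np.random.default_rng(hyper.seed)

    def _validate() -> tuple[float, float]:
        """Validation MSE and mean per-distance correlation."""
        if not len(val_samples):
            return math.nan, math.nan
        preds, targets = [], []
        for s in val_samples:
            pred = np.zeros(k)
            for seq, mu in zip(s.seqs, s.mus):
                x = np.ascontiguousarray(encode_cscn(seq, mu).T, dtype=F32)
                y, _ = state.net.forward(x, train=False)
                pred += y.astype(float) * scale
            preds.append(pred)
            targets.append(s.target)
        P, T = np.asarray(preds), np.asarray(targets)
        mse = float(np.mean((P - T) ** 2))
        rs = []
        for d in range(k):
            if P[:, d].std() > 0 and T[:, d].std() > 0 and len(P) >= 3:
                rs.append(float(np.corrcoef(P[:, d], T[:, d])[0, 1]))
        return mse, (float(np.mean(rs)) if rs else math.nan)

    best = None
    best_score = -math.inf
    for epoch in range(hyper.max_epochs):
        order = rng.permutation(len(samples))
        running = 0.0
        for idx in order:
            s = samples[idx]
            opt.zero_grad()
            caches = []
            pred = np.zeros(k, dtype=F32)
            for seq, mu in zip(s.seqs, s.mus):
                x = np.ascontiguousarray(encode_cscn(seq, mu).T, dtype=F32)
                y, cache = state.net.forward(x, train=True, rng=rng)
                caches.append(cache)
                pred = pred + y
            err = pred - (s.target / scale).astype(F32)
            running += float(np.mean(err.astype(float) ** 2)) * scale * scale
            dy = (2.0 / k) * err
            for cache in reversed(caches):
                state.net.backward(cache, dy)
            opt.step()
        val_mse, val_r = _validate()
        state.history.append(
            {"epoch": epoch, "train_mse": running / len(samples),
             "val_mse": val_mse, "val_r": val_r}
        )
        if len(val_samples):
            score = val_r if selection == "correlation" else -val_mse
            if math.isnan(score):
                score = -math.inf
            if score > best_score:
                best_score = score
                best = [p.value.copy() for p in params]
    if best is not None:
        for p, w in zip(params, best):
            p.value[...] = w
    return state


def predict_contig_matrix(
    state: PredictorState,
    seq: str,
    mu: int = 1,
    mode: str = "encode",
    centers: list[int] | None = None,
    strand_average: bool = True,
) -> ContactMatrix:
    """Slide prediction windows along a contig and assemble the band matrix.

    ``centers`` restricts the window start bins (default: every position);
    entries outside the prediction band stay NaN.  ``mode`` selects CSCN
    encoding (copy number inside the input) or decoding (one-hot input,
    output multiplied by ``mu``).
    """
    cfg = state.cfg
    n_win = cfg.window_bins
    n_bins = len(seq) // cfg.resolution
    if n_bins < n_win:
        raise ValueError("contig shorter than one prediction window")
    if mode not in ("encode", "decode"):
        raise ValueError("mode must be 'encode' or 'decode'")
    if centers is None:
        centers = list(range(0, n_bins - n_win + 1))
    poles = []
    for w0 in centers:
        if w0 < 0 or w0 + n_win > n_bins:
            continue
        sub = seq[w0 * cfg.resolution : (w0 + n_win) * cfg.resolution]
        enc_mu = mu if mode == "encode" else 1
        x = encode_cscn(sub, enc_mu)
        vals = predict_pole(state, x, strand_average=strand_average)
        if mode == "decode":
            vals = mu * vals
        poles.append(ZigzagPole(w0, n_win, vals))
    mat = pole_to_matrix(poles, n_bins)
    return ContactMatrix(mat, cfg.resolution, space="contig")


def transfer_weights(
    state_small: PredictorState, cfg_large: PredictorConfig, seed: int = 0
) -> PredictorState:
    """Transfer shared layers to a larger-window config; re-initialize the head.

    The convolution and dilated stacks are window-length agnostic, so their
    weights copy verbatim; the distance-specific head is tied to the pole
    length and feature length and starts fresh.
    """
    small = state_small.cfg
    compatible = (
        small.conv_units == cfg_large.conv_units
        and small.conv_kernels == cfg_large.conv_kernels
        and small.pool_widths == cfg_large.pool_widths
        and small.dilated_units == cfg_large.dilated_units
        and small.dilation_rates == cfg_large.dilation_rates
    )
    if not compatible:
        raise ValueError("stack shapes incompatible; cannot transfer")
    new = build_predictor(cfg_large, seed=seed)
    for p_new, p_old in zip(
        _shared_params(new.net, cfg_large), _shared_params(state_small.net, small)
    ):
        p_new.value[...] = p_old.value
    new.target_scale = state_small.target_scale
    return new


# ---------------------------------------------------------------------------
# sequence-feature pretraining of the convolution stack


def pretrain_conv_stack(
    cfg: PredictorConfig,
    tiles: list[tuple[str, np.ndarray]],
    steps: int = 1500,
    tile_bp: int = 4_000,
    seed: int = 0,
    learning_rate: float = 1e-3,
    batch_size: int = 8,
) -> list[np.ndarray]:
    """Pretrain the five-layer convolution stack on a sequence-feature task.

    ``tiles`` are (sequence, occupancy) pairs: short genomic tiles with a
    binary label per pooled feature position marking presence of a
    chromatin-feature proxy (e.g. a boundary motif).  The stack plus a
    temporary position-shared logistic head (a 1x1 convolution) is trained
    with minibatch Adam on the per-position binary cross-entropy; the head
    is discarded and the stack weights are returned in the layout
    ``build_predictor`` accepts as ``pretrained``.  Tiles are ~1000x shorter
    than a prediction window, so this costs a small fraction of the main
    training.
    """
    if tile_bp % cfg.pool_factor:
        raise ValueError("tile length must survive the pooling stack evenly")
    rng = np.random.default_rng(seed)
    layers: list = []
    c_prev = 4
    for u, k, p in zip(cfg.conv_units, cfg.conv_kernels, cfg.pool_widths):
        layers += [Conv1d(c_prev, u, k, rng=rng), ReLU(), MaxPool(p), Dropout(cfg.dropout)]
        c_prev = u
    layers[0].input_grad = False
    # the channel projection is pretrained too, so the low-dimensional
    # features the dilated stack and head consume retain the learned signal
    layers.append(Conv1d(c_prev, cfg.dilated_units, 1, rng=rng))
    head = Conv1d(cfg.dilated_units, 1, 1, rng=rng)
    net = Sequential(layers + [head])
    opt = Adam(net.parameters(), lr=learning_rate, eps=1e-8, l2=1e-4)
    order = rng.permutation(len(tiles))
    cursor = 0
    for _step in range(steps):
        opt.zero_grad()
        for _b in range(batch_size):
            if cursor >= len(tiles):
                order = rng.permutation(len(tiles))
                cursor = 0
            seq, occ = tiles[order[cursor]]
            cursor += 1
            x = np.ascontiguousarray(encode_cscn(seq, 1).T, dtype=F32)
            z, cache = net.forward(x, train=True, rng=rng)
            z = z[:, 0]
            p = 0.5 * (1.0 + np.tanh(0.5 * np.clip(z, -30.0, 30.0)))
            dy = ((p - occ) / (len(occ) * batch_size)).astype(F32)[:, None]
            net.backward(cache, dy)
        opt.step()
    out = []
    for lay in layers:
        out.extend(p.value.copy() for p in lay.parameters())
    return out


def motif_occupancy_tiles(
    sequences: list[str],
    motif: str,
    n_tiles: int = 2000,
    tile_bp: int = 4_000,
    pool_factor: int = 1000,
    seed: int = 0,
) -> list[tuple[str, np.ndarray]]:
    """Balanced pretraining set: tiles with per-position motif occupancy.

    Tiles are drawn uniformly from ``sequences``; the label vector marks, for
    each pooled feature position (``pool_factor`` bases), whether ``motif``
    occurs there on either strand.  Tiles containing the motif are
    oversampled to a 50/50 balance so the pretext task stays well-conditioned
    even when the motif is sparse.
    """
    rng = np.random.default_rng(seed)
    pats = {motif, reverse_complement(motif)}
    n_pos_positions = tile_bp // pool_factor

    def occupancy(tile: str) -> np.ndarray:
        occ = np.zeros(n_pos_positions)
        for pat in pats:
            k = tile.find(pat)
            while k != -1:
                occ[min(k // pool_factor, n_pos_positions - 1)] = 1.0
                occ[min((k + len(pat) - 1) // pool_factor, n_pos_positions - 1)] = 1.0
                k = tile.find(pat, k + 1)
        return occ

    pos, neg = [], []
    want = n_tiles // 2
    guard = 0
    while (len(pos) < want or len(neg) < want) and guard < 200 * n_tiles:
        guard += 1
        seq = sequences[rng.integers(len(sequences))]
        if len(seq) <= tile_bp:
            continue
        a = int(rng.integers(0, len(seq) - tile_bp))
        tile = seq[a : a + tile_bp]
        occ = occupancy(tile)
        if occ.any() and len(pos) < want:
            pos.append((tile, occ))
        elif not occ.any() and len(neg) < want:
            neg.append((tile, occ))
    tiles = pos + neg
    # random orientation so the stack detects the feature on either strand
    oriented = []
    for tile, occ in tiles:
        if rng.random() < 0.5:
            oriented.append((reverse_complement(tile), occ[::-1].copy()))
        else:
            oriented.append((tile, occ))
    return [oriented[i] for i in rng.permutation(len(oriented))]


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: PredictorState, path) -> None:
    arrays = {f"p{k}": p.value for k, p in enumerate(state.net.parameters())}
    meta = {
        "config": asdict(state.cfg),
        "seed": state.seed,
        "target_scale": state.target_scale,
        "history": state.history,
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> PredictorState:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg_dict = meta["config"]
    for key in ("conv_units", "conv_kernels", "pool_widths", "dilation_rates"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = PredictorConfig(**cfg_dict)
    state = build_predictor(cfg, seed=meta["seed"])
    for k, p in enumerate(state.net.parameters()):
        p.value[...] = data[f"p{k}"]
    state.target_scale = float(meta["target_scale"])
    state.history = list(meta["history"])
    return state
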