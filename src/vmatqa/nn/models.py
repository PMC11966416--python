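"""GPR prediction models: Informer-CNN and the CNN / LSTM / Informer baselines.

All four models consume the same per-field inputs — a W x 141 daily linac
performance window L, and z-scored complexity (C, 31), radiomic (R, 107) and
dosimetric (D, 93) vectors — and emit four gamma passing rates plus
per-criterion pass probabilities at the 90% action limit.

The Informer-CNN encodes L with the ProbSparse Informer, concatenates the
decoder summary with C/R/D, reshapes the fused vector onto a convolutional
grid (by default features sit on the channel axis of a small spatial grid,
which preserves feature identity; a single-channel square-image layout is
config-selectable), and runs the 3x3 / 5x5 / 3x3 convolution stack (ReLU +
2x2 average pooling + dropout after each layer) before the two output
heads.  The Informer baseline is the same network with the convolutional
stack replaced by the identity (the fused vector goes straight to the
heads).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict

import numpy as np

from .autograd import Tensor, no_grad
from .layers import Conv2d, Dropout, Linear, LSTM, Module, avg_pool2d
from .informer import InformerDecoder, InformerEncoder


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (defaults as published)."""

    d_model: int = 256
    n_heads: int = 4
    encoder_layers: int = 2
    ffn_dim: int = 512
    attn_dropout: float = 0.2
    cnn_dropout: float = 0.2
    train_dropout: float = 0.5
    l2_coeff: float = 0.01
    lr: float = 0.001
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    lr_decay: float = 0.95
    lr_decay_every: int = 20
    batch_size: int = 32
    conv_kernels: tuple[int, int, int] = (3, 5, 3)
    conv_channels: tuple[int, int, int] = (64, 64, 64)
    pool: int = 2
    sparse_factor: float = 5.0
    window: int = 30
    n_linac: int = 141
    n_complexity: int = 31
    n_radiomic: int = 107
    n_dosimetric: int = 93
    lstm_hidden: int = 128
    lstm_layers: int = 2
    head_hidden: int = 128
    #: fused-vector conv layout: "channel_grid" reshapes features onto the
    #: channel axis of a small spatial grid (information-preserving, default);
    #: "square_grid" is the single-channel square-image alternative
    fusion: str = "channel_grid"
    fusion_spatial: int = 4
    max_epochs: int = 100
    patience: int = 25
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GPRPrediction:
    gpr: np.ndarray        # (4,) on [0, 1]: 3%/3mm, 3%/2mm, 2%/2mm, 1%/1mm
    pass_prob: np.ndarray  # (4,) in (0, 1), one per criterion

    @property
    def passes(self) -> np.ndarray:
        return self.pass_prob >= 0.5


def _as_batch(arrs: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v) for k, v in arrs.items()}


def pad_to_square(x: Tensor) -> tuple[Tensor, int]:
    """Zero-pad a (B, n) tensor to the smallest n_sq = s*s >= n; returns
    the (B, 1, s, s) grid."""
    B, n = x.shape
    s = int(np.ceil(np.sqrt(n)))
    padn = s * s - n
    if padn:
        from .autograd import cat
        x = cat([x, Tensor(np.zeros((B, padn)))], axis=1)
    return x.reshape(B, 1, s, s), s


def pad_to_channel_grid(x: Tensor, spatial: int) -> tuple[Tensor, int]:
    """Zero-pad a (B, n) tensor onto a (B, n_ch, spatial, spatial) grid with
    features along the channel axis.

    With few spatial positions and many channels the first convolution can
    form feature-specific linear combinations (channel mixing), which a
    single-channel layout cannot: shared spatial kernels there can only
    apply one filter bank to every region of an arbitrarily ordered
    feature image.
    """
    B, n = x.shape
    cells = spatial * spatial
    n_ch = int(np.ceil(n / cells))
    padn = n_ch * cells - n
    if padn:
        from .autograd import cat
        x = cat([x, Tensor(np.zeros((B, padn)))], axis=1)
    return x.reshape(B, n_ch, spatial, spatial), n_ch


class ConvStack(Module):
    """conv3x3 -> ReLU -> pool -> conv5x5 -> ReLU -> pool -> conv3x3 -> ReLU
    -> pool, dropout 0.2 after each pooling; flattens at the end."""

    def __init__(self, cfg: ModelConfig, rng, in_channels: int = 1):
        chans = (in_channels,) + tuple(cfg.conv_channels)
        self.convs = [
            Conv2d(chans[i], chans[i + 1], cfg.conv_kernels[i], rng)
            for i in range(3)
        ]
        self.drop = Dropout(cfg.cnn_dropout)
        self.pool = cfg.pool

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        for conv in self.convs:
            x = avg_pool2d(conv(x).relu(), self.pool)
            x = self.drop(x, rng, training)
        B = x.shape[0]
        return x.reshape(B, -1)

    @staticmethod
    def out_size(side: int, cfg: ModelConfig) -> int:
        for _ in range(3):
            side = max(side // cfg.pool, 1)
        return side * side * cfg.conv_channels[-1]


class Heads(Module):
    """Dual output heads: FC+ReLU -> 4 GPR values; FC -> sigmoid pass probs."""

    def __init__(self, n_in: int, cfg: ModelConfig, rng):
        self.reg1 = Linear(n_in, cfg.head_hidden, rng)
        self.reg2 = Linear(cfg.head_hidden, 4, rng)
        self.cls = Linear(n_in, 4, rng)
        self.drop = Dropout(cfg.train_dropout)

    def __call__(self, latent: Tensor, rng, training: bool):
        h = self.drop(self.reg1(latent).relu(), rng, training)
        return self.reg2(h), self.cls(latent)  # (gpr, pass_logits)


class InformerCNN(Module):
    """The fusion model; ``conv_identity=True`` yields the Informer baseline
    (fused vector passed to the heads without the convolutional stack)."""

    name = "informer_cnn"

    def __init__(self, cfg: ModelConfig, conv_identity: bool = False):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.conv_identity = conv_identity
        self.encoder = InformerEncoder(
            cfg.n_linac, cfg.d_model, cfg.n_heads, cfg.ffn_dim,
            cfg.encoder_layers, cfg.sparse_factor, cfg.attn_dropout, rng,
        )
        self.decoder = InformerDecoder(
            cfg.d_model, cfg.n_heads, cfg.ffn_dim, cfg.sparse_factor,
            cfg.attn_dropout, rng,
        )
        n_fused = cfg.d_model + cfg.n_complexity + cfg.n_radiomic + cfg.n_dosimetric
        if conv_identity:
            n_latent = n_fused
            self.conv = None
        elif cfg.fusion == "channel_grid":
            cells = cfg.fusion_spatial**2
            n_ch = int(np.ceil(n_fused / cells))
            self.conv = ConvStack(cfg, rng, in_channels=n_ch)
            n_latent = ConvStack.out_size(cfg.fusion_spatial, cfg)
        elif cfg.fusion == "square_grid":
            side = int(np.ceil(np.sqrt(n_fused)))
            self.conv = ConvStack(cfg, rng)
            n_latent = ConvStack.out_size(side, cfg)
        else:
            raise ValueError(f"unknown fusion layout {cfg.fusion!r}")
        self.heads = Heads(n_latent, cfg, rng)

    def summary_vector(self, batch, rng, training: bool) -> Tensor:
        encoded, emb = self.encoder(batch["L"], batch.get("cal"), rng, training)
        W = batch["L"].shape[1]
        start = emb[:, -(W // 2):, :]
        return self.decoder(encoded, start, rng, training)

    def latent(self, batch, rng, training: bool) -> Tensor:
        from .autograd import cat
        summary = self.summary_vector(batch, rng, training)
        fused = cat([summary, batch["C"], batch["R"], batch["D"]], axis=1)
        if self.conv_identity:
            return fused
        if self.cfg.fusion == "channel_grid":
            grid, _ = pad_to_channel_grid(fused, self.cfg.fusion_spatial)
        else:
            grid, _ = pad_to_square(fused)
        return self.conv(grid, rng, training)

    def __call__(self, batch, rng=None, training: bool = False):
        return self.heads(self.latent(batch, rng, training), rng, training)


class InformerModel(InformerCNN):
    """Informer baseline: decoder summary + C/R/D straight to the heads."""

    name = "informer"

    def __init__(self, cfg: ModelConfig):
        super().__init__(cfg, conv_identity=True)


class CNNModel(Module):
    """CNN baseline: all features flattened onto one square grid, then the
    3-layer convolution stack and the dual heads."""

    name = "cnn"

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        n_flat = (cfg.window * cfg.n_linac + cfg.n_complexity
                  + cfg.n_radiomic + cfg.n_dosimetric)
        if cfg.fusion == "channel_grid":
            n_ch = int(np.ceil(n_flat / cfg.fusion_spatial**2))
            self.conv = ConvStack(cfg, rng, in_channels=n_ch)
            n_latent = ConvStack.out_size(cfg.fusion_spatial, cfg)
        else:
            side = int(np.ceil(np.sqrt(n_flat)))
            self.conv = ConvStack(cfg, rng)
            n_latent = ConvStack.out_size(side, cfg)
        self.heads = Heads(n_latent, cfg, rng)

    def latent(self, batch, rng, training: bool) -> Tensor:
        from .autograd import cat
        B = batch["L"].shape[0]
        flat = cat([batch["L"].reshape(B, -1), batch["C"], batch["R"],
                    batch["D"]], axis=1)
        if self.cfg.fusion == "channel_grid":
            grid, _ = pad_to_channel_grid(flat, self.cfg.fusion_spatial)
        else:
            grid, _ = pad_to_square(flat)
        return self.conv(grid, rng, training)

    def __call__(self, batch, rng=None, training: bool = False):
        return self.heads(self.latent(batch, rng, training), rng, training)


class LSTMModel(Module):
    """LSTM baseline: two stacked 128-unit layers over the linac window; the
    last hidden state joins C/R/D at the heads."""

    name = "lstm"

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.lstm = LSTM(cfg.n_linac, cfg.lstm_hidden, cfg.lstm_layers, rng)
        n_latent = (cfg.lstm_hidden + cfg.n_complexity + cfg.n_radiomic
                    + cfg.n_dosimetric)
        self.heads = Heads(n_latent, cfg, rng)

    def latent(self, batch, rng, training: bool) -> Tensor:
        from .autograd import cat
        h = self.lstm(batch["L"])
        return cat([h, batch["C"], batch["R"], batch["D"]], axis=1)

    def __call__(self, batch, rng=None, training: bool = False):
        return self.heads(self.latent(batch, rng, training), rng, training)


MODEL_CLASSES = {
    "informer_cnn": InformerCNN,
    "informer": InformerModel,
    "lstm": LSTMModel,
    "cnn": CNNModel,
}


def build_model(name: str, cfg: ModelConfig) -> Module:
    try:
        return MODEL_CLASSES[name](cfg)
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_CLASSES)}")


def _target_stats(model: Module) -> tuple[np.ndarray, np.ndarray]:
    return (getattr(model, "y_mean", np.zeros(4)),
            getattr(model, "y_sd", np.ones(4)))


def predict(model: Module, arrays: dict[str, np.ndarray]) -> list[GPRPrediction]:
    """Eval-mode forward pass over a batch of records."""
    mu, sd = _target_stats(model)
    with no_grad():
        gpr, logits = model(_as_batch(arrays), rng=None, training=False)
    probs = 1.0 / (1.0 + np.exp(-logits.data))
    return [GPRPrediction(gpr=np.clip(g * sd + mu, 0.0, 1.0), pass_prob=p)
            for g, p in zip(gpr.data, probs)]


def predict_arrays(model: Module, arrays: dict[str, np.ndarray],
                   batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """(gpr_hat, pass_prob) arrays for a whole dataset, batched."""
    n = len(arrays["C"])
    mu, sd = _target_stats(model)
    gprs, probs = [], []
    for s in range(0, n, batch_size):
        sub = {k: v[s:s + batch_size] for k, v in arrays.items()}
        with no_grad():
            g, z = model(_as_batch(sub), rng=None, training=False)
        gprs.append(g.data * sd + mu)
        probs.append(1.0 / (1.0 + np.exp(-z.data)))
    return np.concatenate(gprs), np.concatenate(probs)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

class Adam:
    """Adam with decoupled (AdamW-style) L2 weight decay.

    The penalty applies to weight matrices only: biases and layer-norm gains
    are excluded, as is standard — decaying an output bias would otherwise
    pin the regression head an O(l2/grad) offset below the label mean.
    Decay is decoupled from the adaptive gradient: folding l2*w into the
    Adam gradient would shrink any weakly driven weight at a constant ~lr
    per step (Adam normalizes gradient magnitude away), silently zeroing
    saturated heads such as a rare-class classifier."""

    def __init__(self, params: dict[str, Tensor], cfg: ModelConfig):
        self.params = params
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.decay_mask = {
            k: not k.rsplit(".", 1)[-1] in ("b", "beta", "gamma")
            for k in params
        }
        self.t = 0
        self.lr = cfg.lr

    def step(self) -> None:
        b1, b2 = self.cfg.betas
        self.t += 1
        c1 = 1.0 / (1 - b1**self.t)
        c2 = 1.0 / (1 - b2**self.t)
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m, v = self.m[k], self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            g = g * g
            v += (1 - b2) * g
            if self.decay_mask[k]:
                p.data -= self.lr * self.cfg.l2_coeff * p.data
            p.data -= self.lr * (m * c1) / (np.sqrt(v * c2) + self.cfg.eps)


def joint_loss(gpr_pred: Tensor, logits: Tensor, y: np.ndarray,
               passes: np.ndarray) -> Tensor:
    """MSE over the four GPR outputs plus BCE over the four pass logits.

    The L2 penalty enters through the optimizer's gradient term.
    """
    diff = gpr_pred - Tensor(y)
    mse = (diff * diff).mean()
    p = logits.sigmoid()
    t = Tensor(passes.astype(float))
    eps = 1e-7
    bce = -(t * (p + eps).log() + (1.0 - t) * (1.0 - p + eps).log()).mean()
    return mse + bce


def train(
    arrays: dict[str, np.ndarray],
    labels: np.ndarray,
    split,
    cfg: ModelConfig,
    model_name: str = "informer_cnn",
    verbose: bool = False,
):
    """Train a model with Adam, lr decay 0.95 / 20 epochs, batch 32; returns
    (model_with_best_validation_weights, history).

    ``arrays``: dict of L/C/R/D (+optional cal) arrays over all fields;
    ``labels``: (N, 4) GPR on [0, 1]; ``split``: a SplitAssignment.  The
    validation split is used only for checkpoint selection, never for
    gradient updates.
    """
    from ..evaluation import classify_pass

    model = build_model(model_name, cfg)
    params = model.parameters()
    opt = Adam(params, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    passes = classify_pass(labels).astype(float)

    # start the pass heads at the training-split class priors so rare-class
    # logits do not spend most of training crossing the saturation plateau
    prior = np.clip(passes[np.asarray(split.train)].mean(axis=0), 1e-3, 1 - 1e-3)
    model.heads.cls.b.data = np.log(prior / (1 - prior)).astype(
        model.heads.cls.b.data.dtype)

    # regress standardized targets (train-split statistics); predictions are
    # transformed back in the predict paths.  Per-criterion inverse-variance
    # scaling keeps the MSE term commensurate with the BCE term.
    model.y_mean = labels[np.asarray(split.train)].mean(axis=0)
    model.y_sd = np.maximum(labels[np.asarray(split.train)].std(axis=0), 1e-6)
    labels_std = (labels - model.y_mean) / model.y_sd

    tr = np.asarray(split.train)
    va = np.asarray(split.val)
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = None
    stale = 0

    for epoch in range(cfg.max_epochs):
        opt.lr = cfg.lr * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        order = rng.permutation(tr)
        tot, nb = 0.0, 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            batch = {k: Tensor(v[idx]) for k, v in arrays.items()}
            gpr_pred, logits = model(batch, rng=rng, training=True)
            loss = joint_loss(gpr_pred, logits, labels_std[idx], passes[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            model.zero_grad()
            loss.backward()
            opt.step()
            tot += float(loss.data)
            nb += 1

        with no_grad():
            vb = {k: Tensor(v[va]) for k, v in arrays.items()}
            vg, vl = model(vb, rng=None, training=False)
            val_loss = float(joint_loss(vg, vl, labels_std[va], passes[va]).data)
        history["epoch"].append(epoch)
        history["train_loss"].append(tot / max(nb, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if verbose:
            print(f"epoch {epoch:3d} train {tot / max(nb, 1):.5f} val {val_loss:.5f}")

        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: p.data.copy() for k, p in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    return model, history


def save_checkpoint(model: Module, path, extra: dict | None = None) -> None:
    state = {
        "model_name": model.name,
        "config": model.cfg.to_dict(),
        "params": {k: p.data for k, p in model.parameters().items()},
        "y_mean": getattr(model, "y_mean", np.zeros(4)),
        "y_sd": getattr(model, "y_sd", np.ones(4)),
        "extra": extra or {},
    }
    with open(path, "wb") as f:
        pickle.dump(state, f)


def load_checkpoint(path) -> tuple[Module, dict]:
    with open(path, "rb") as f:
        state = pickle.load(f)
    cfg_d = dict(state["config"])
    for key in ("betas", "conv_kernels", "conv_channels"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = ModelConfig(**cfg_d)
    model = build_model(state["model_name"], cfg)
    params = model.parameters()
    for k, p in params.items():
        p.data = np.array(state["params"][k])
    model.y_mean = np.array(state.get("y_mean", np.zeros(4)))
    model.y_sd = np.array(state.get("y_sd", np.ones(4)))
    return model, state["extra"]
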