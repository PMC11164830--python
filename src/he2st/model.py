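"""Multi-task network and loss terms for image-to-expression prediction.

The model is a hard-parameter-sharing multi-task network: one convolutional
encoder maps an H&E patch to a shared embedding, from which three linear
heads predict (i) the m target-gene expressions, (ii) the M - m non-target
gene expressions, and (iii) the probability that the spot is tumor.

The training objective is

    L = L_prim + lambda * L_aux + beta * L_tmr + gamma * L_spat

where L_prim and L_aux are mean squared errors over the target and
non-target genes, L_tmr is binary cross-entropy on the tumor label, and
L_spat is the spatial-aware constraint: over all (central spot, grid
neighbor) pairs that share the same pathological annotation, the mean
squared difference of their predicted target expressions, averaged over the
K such pairs.  The spatial term encodes the prior that adjacent tissue with
the same annotation expresses similarly.

Every loss has a hand-derived analytic gradient with respect to the
predictions; the same gradients drive training (backpropagated through the
encoder) and are validated against finite differences in the test suite.

The bundled backbone, ``tiny_cnn``, is a compact two-stage convolutional
encoder (3x3 convs, ReLU, 2x2 average pooling, one dense layer) implemented
directly on numpy with explicit backpropagation.  It is sized for desk-scale
patches (any side divisible by 4, e.g. 32 or 64 px).  The ``resnet50``
backbone name is reserved in the config surface for externally provided
pretrained encoders and is not bundled.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import ConfigError
from .preprocess import NeighborGraph

PROB_EPS = 1e-7  # clamp for probabilities inside the cross-entropy


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class LossWeights:
    """Weights of the auxiliary (lambda), tumor (beta) and spatial (gamma) terms."""

    lambda_aux: float = 1.0
    beta_tmr: float = 1.0
    gamma_spat: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_aux", "beta_tmr", "gamma_spat"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the multi-task network."""

    m: int
    n_nontarget: int = 0
    backbone: str = "tiny_cnn"
    pretrained: bool = False
    embed_dim: int = 64
    patch_px: int = 32
    conv_channels: tuple = (8, 16)
    spatial_reduction: str = "mean"  # per-pair reduction over genes: mean|sum
    spatial_on_target_only: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ConfigError("m must be >= 1")
        if self.n_nontarget < 0:
            raise ConfigError("n_nontarget must be >= 0")
        if self.backbone not in ("tiny_cnn", "resnet50"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.spatial_reduction not in ("mean", "sum"):
            raise ConfigError("spatial_reduction must be 'mean' or 'sum'")
        if self.patch_px % 4 != 0 or self.patch_px < 8:
            raise ConfigError("patch_px must be a multiple of 4 and >= 8")


@dataclass
class BatchPrediction:
    """Outputs of one forward pass over a batch of B patches."""

    g_hat_target: np.ndarray  # B x m
    g_hat_nontarget: np.ndarray  # B x (M - m)
    y_hat: np.ndarray  # B probabilities in (0, 1)

    def __post_init__(self) -> None:
        b = self.g_hat_target.shape[0]
        if self.g_hat_nontarget.shape[0] != b or self.y_hat.shape != (b,):
            raise ValueError("inconsistent batch sizes across heads")


# ---------------------------------------------------------------------------
# Loss terms (Eq. 1-6) and their analytic gradients
# ---------------------------------------------------------------------------


def _check_pair(g_true: np.ndarray, g_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g_true = np.asarray(g_true, float)
    g_hat = np.asarray(g_hat, float)
    if g_true.shape != g_hat.shape:
        raise ValueError(f"shape mismatch {g_true.shape} vs {g_hat.shape}")
    if not (np.isfinite(g_true).all() and np.isfinite(g_hat).all()):
        raise ValueError("NaN/inf in loss inputs")
    return g_true, g_hat


def loss_primary(g_true: np.ndarray, g_hat: np.ndarray) -> float:
    """Target-gene MSE: mean over spots and target genes of squared error."""
    g_true, g_hat = _check_pair(g_true, g_hat)
    return float(np.mean((g_true - g_hat) ** 2))


def loss_primary_grad(g_true: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    g_true, g_hat = _check_pair(g_true, g_hat)
    return 2.0 * (g_hat - g_true) / g_true.size


def loss_auxiliary(g_true: np.ndarray, g_hat: np.ndarray) -> float:
    """Non-target-gene MSE; same functional form with the B(M-m) denominator."""
    return loss_primary(g_true, g_hat)


def loss_auxiliary_grad(g_true: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    return loss_primary_grad(g_true, g_hat)


def loss_tumor(y_true: np.ndarray, y_hat: np.ndarray) -> float:
    """Binary cross-entropy on the tumor probability, probabilities clamped."""
    y_true = np.asarray(y_true, float)
    y_hat = np.asarray(y_hat, float)
    if y_true.shape != y_hat.shape:
        raise ValueError("shape mismatch between labels and probabilities")
    if not np.isin(y_true, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    p = np.clip(y_hat, PROB_EPS, 1.0 - PROB_EPS)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def loss_tumor_grad(y_true: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the predicted probabilities."""
    y_true = np.asarray(y_true, float)
    p = np.clip(np.asarray(y_hat, float), PROB_EPS, 1.0 - PROB_EPS)
    return ((1.0 - y_true) / (1.0 - p) - y_true / p) / y_true.size


def _spatial_pairs(
    labels: np.ndarray, graph: NeighborGraph, batch_index_map: Optional[np.ndarray]
) -> np.ndarray:
    """Directed same-annotation (central, neighbor) pairs as batch positions.

    ``batch_index_map[b]`` gives the graph node index of batch row b; the
    graph is restricted to nodes present in the batch.
    """
    labels = np.asarray(labels, float)
    if np.isnan(labels).any():
        raise ValueError("spatial loss requires an annotation for every spot in the batch")
    if batch_index_map is None:
        batch_index_map = np.arange(len(labels))
    batch_index_map = np.asarray(batch_index_map, int)
    pos_of = {int(g): b for b, g in enumerate(batch_index_map)}
    pairs = []
    for b, g in enumerate(batch_index_map):
        for j in graph.neighbors[int(g)]:
            bj = pos_of.get(int(j))
            if bj is not None and labels[b] == labels[bj]:
                pairs.append((b, bj))
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def loss_spatial(
    preds: np.ndarray,
    labels: np.ndarray,
    graph: NeighborGraph,
    batch_index_map: Optional[np.ndarray] = None,
    reduction: str = "mean",
) -> float:
    """Spatial-aware constraint over same-annotation neighbor pairs.

    For every (central i, grid-neighbor j) pair with matching annotation
    (weight w_ij = 1; 0 otherwise), accumulate the squared difference of the
    predicted target expression, reduced over genes by ``reduction``, and
    divide by K, the number of such pairs.  Returns 0 when K = 0.
    """
    preds = np.asarray(preds, float)
    pairs = _spatial_pairs(labels, graph, batch_index_map)
    if len(pairs) == 0:
        return 0.0
    diff = preds[pairs[:, 0]] - preds[pairs[:, 1]]
    per_pair = (diff**2).mean(axis=1) if reduction == "mean" else (diff**2).sum(axis=1)
    return float(per_pair.sum() / len(pairs))


def loss_spatial_grad(
    preds: np.ndarray,
    labels: np.ndarray,
    graph: NeighborGraph,
    batch_index_map: Optional[np.ndarray] = None,
    reduction: str = "mean",
) -> np.ndarray:
    """Gradient of :func:`loss_spatial` w.r.t. the predictions."""
    preds = np.asarray(preds, float)
    grad = np.zeros_like(preds)
    pairs = _spatial_pairs(labels, graph, batch_index_map)
    if len(pairs) == 0:
        return grad
    k = len(pairs)
    denom = k * (preds.shape[1] if reduction == "mean" else 1)
    for b, bj in pairs:
        d = 2.0 * (preds[b] - preds[bj]) / denom
        grad[b] += d
        grad[bj] -= d
    return grad


def loss_total(
    components: dict,
    weights: LossWeights,
) -> float:
    """Weighted multi-task objective: L_prim + lambda L_aux + beta L_tmr + gamma L_spat.

    ``components`` maps {"primary", "auxiliary", "tumor", "spatial"} to
    scalars; terms with weight 0 are skipped so the zero-weight total is
    bit-for-bit equal to the primary loss alone.
    """
    for k, v in components.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite loss component {k}={v}")
    total = float(components["primary"])
    if weights.lambda_aux:
        total += weights.lambda_aux * float(components["auxiliary"])
    if weights.beta_tmr:
        total += weights.beta_tmr * float(components["tumor"])
    if weights.gamma_spat:
        total += weights.gamma_spat * float(components["spatial"])
    return total


# ---------------------------------------------------------------------------
# tiny_cnn backbone: explicit forward / backward on numpy
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-size 3x3 convolution (pad 1).  Returns (out, padded input)."""
    B, H, W, _ = x.shape
    co = w.shape[3]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (B, H, W, co)).copy()
    for di in range(3):
        for dj in range(3):
            out += xp[:, di : di + H, dj : dj + W, :] @ w[di, dj]
    return out, xp


def _conv2d_backward(
    dout: np.ndarray, xp: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    B, H, W, _ = dout.shape
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            xs = xp[:, di : di + H, dj : dj + W, :]
            dw[di, dj] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, di : di + H, dj : dj + W, :] += dout @ w[di, dj].T
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    B, H, W, C = x.shape
    return x.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))


def _avgpool2_backward(dout: np.ndarray) -> np.ndarray:
    B, H2, W2, C = dout.shape
    d = np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2)
    return d / 4.0


class TinyCNN:
    """Compact shared convolutional encoder with three task heads.

    Layers: conv3x3(3 -> c1) + ReLU + avgpool2, conv3x3(c1 -> c2) + ReLU +
    avgpool2, flatten, dense(embed_dim) + ReLU, then three linear heads
    (target regression, non-target regression, tumor logit -> sigmoid).
    Weights use He initialization from the given seed; forward/backward are
    fully deterministic.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.backbone != "tiny_cnn":
            raise ConfigError(
                f"backbone {config.backbone!r} is not bundled with this package; "
                "only 'tiny_cnn' ships with weights that can be trained here"
            )
        if config.pretrained:
            raise ConfigError(
                "no pretrained weights are published for tiny_cnn; "
                "use init='warm-start' with an existing checkpoint instead"
            )
        self.config = config
        c1, c2 = config.conv_channels
        s = config.patch_px
        self.flat_dim = (s // 4) * (s // 4) * c2
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params = {
            "conv1_w": he((3, 3, 3, c1), 27),
            "conv1_b": np.zeros(c1, np.float32),
            "conv2_w": he((3, 3, c1, c2), 9 * c1),
            "conv2_b": np.zeros(c2, np.float32),
            "dense_w": he((self.flat_dim, config.embed_dim), self.flat_dim),
            "dense_b": np.zeros(config.embed_dim, np.float32),
            "head_t_w": he((config.embed_dim, config.m), config.embed_dim),
            "head_t_b": np.zeros(config.m, np.float32),
            "head_n_w": he((config.embed_dim, max(config.n_nontarget, 1)), config.embed_dim),
            "head_n_b": np.zeros(max(config.n_nontarget, 1), np.float32),
            "head_y_w": he((config.embed_dim, 1), config.embed_dim),
            "head_y_b": np.zeros(1, np.float32),
        }
        self._cache: Optional[dict] = None

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False) -> BatchPrediction:
        """Run a batch of normalized patches (B x S x S x 3) through all heads."""
        x = np.asarray(x, np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.patch_px or x.shape[3] != 3:
            raise ValueError(
                f"expected batch of {self.config.patch_px}px RGB patches, got {x.shape}"
            )
        if x.shape[0] == 0:
            raise ValueError("batch must be non-empty")
        p = self.params
        z1, xp1 = _conv2d(x, p["conv1_w"], p["conv1_b"])
        a1 = np.maximum(z1, 0.0)
        p1 = _avgpool2(a1)
        z2, xp2 = _conv2d(p1, p["conv2_w"], p["conv2_b"])
        a2 = np.maximum(z2, 0.0)
        p2 = _avgpool2(a2)
        flat = p2.reshape(x.shape[0], -1)
        ze = flat @ p["dense_w"] + p["dense_b"]
        e = np.maximum(ze, 0.0)
        g_t = e @ p["head_t_w"] + p["head_t_b"]
        g_n = e @ p["head_n_w"] + p["head_n_b"]
        logit = (e @ p["head_y_w"] + p["head_y_b"]).ravel()
        prob = np.clip(_sigmoid(logit), PROB_EPS, 1.0 - PROB_EPS)
        if self.config.n_nontarget == 0:
            g_n = g_n[:, :0]
        if cache:
            self._cache = {
                "xp1": xp1, "z1": z1, "xp2": xp2, "z2": z2,
                "flat": flat, "ze": ze, "e": e, "prob": prob, "shape1": a1.shape,
            }
        return BatchPrediction(
            g_t.astype(np.float64), g_n.astype(np.float64), prob.astype(np.float64)
        )

    # -- backward ----------------------------------------------------------

    def backward(
        self, d_target: np.ndarray, d_nontarget: np.ndarray, d_prob: np.ndarray
    ) -> dict:
        """Backpropagate gradients w.r.t. the head outputs into the parameters.

        ``d_prob`` is the gradient w.r.t. the tumor *probability*; it is
        chained through the sigmoid internally.
        """
        if self._cache is None:
            raise RuntimeError("call forward(..., cache=True) before backward()")
        c = self._cache
        p = self.params
        e = c["e"]
        d_target = np.asarray(d_target, np.float32)
        d_prob = np.asarray(d_prob, np.float32)
        prob = c["prob"]
        d_logit = (d_prob * prob * (1.0 - prob)).reshape(-1, 1)

        grads = {
            "head_t_w": e.T @ d_target,
            "head_t_b": d_target.sum(axis=0),
            "head_y_w": e.T @ d_logit,
            "head_y_b": d_logit.sum(axis=0),
        }
        de = d_target @ p["head_t_w"].T + d_logit @ p["head_y_w"].T
        if self.config.n_nontarget > 0:
            d_nontarget = np.asarray(d_nontarget, np.float32)
            grads["head_n_w"] = e.T @ d_nontarget
            grads["head_n_b"] = d_nontarget.sum(axis=0)
            de += d_nontarget @ p["head_n_w"].T
        else:
            grads["head_n_w"] = np.zeros_like(p["head_n_w"])
            grads["head_n_b"] = np.zeros_like(p["head_n_b"])

        dze = de * (c["ze"] > 0)
        grads["dense_w"] = c["flat"].T @ dze
        grads["dense_b"] = dze.sum(axis=0)
        dflat = dze @ p["dense_w"].T
        B = dflat.shape[0]
        s4 = self.config.patch_px // 4
        c2 = self.config.conv_channels[1]
        dp2 = dflat.reshape(B, s4, s4, c2)
        da2 = _avgpool2_backward(dp2)
        dz2 = da2 * (c["z2"] > 0)
        dp1, grads["conv2_w"], grads["conv2_b"] = _conv2d_backward(dz2, c["xp2"], p["conv2_w"])
        da1 = _avgpool2_backward(dp1)
        dz1 = da1 * (c["z1"] > 0)
        _, grads["conv1_w"], grads["conv1_b"] = _conv2d_backward(dz1, c["xp1"], p["conv1_w"])
        self._cache = None
        return grads

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            if k not in state:
                raise ValueError(f"checkpoint missing parameter {k}")
            if state[k].shape != self.params[k].shape:
                raise ConfigError(
                    f"parameter {k} shape {state[k].shape} incompatible with "
                    f"model shape {self.params[k].shape}"
                )
            self.params[k] = np.asarray(state[k], np.float32).copy()


def build_model(config: ModelConfig, seed: int = 0) -> TinyCNN:
    """Instantiate the configured backbone with seeded initialization."""
    return TinyCNN(config, seed=seed)


class Adam:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = np.asarray(g, np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Checkpoint I/O
# ---------------------------------------------------------------------------


def save_checkpoint(path: Path, model: TinyCNN, metadata: dict) -> Path:
    """Save weights (.npz) plus a JSON sidecar mirroring all non-weight metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    meta = dict(metadata)
    meta["model_config"] = dataclasses.asdict(model.config)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(_jsonable(meta), indent=2))
    return path


def load_checkpoint(path: Path) -> tuple[TinyCNN, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(meta["model_config"])
    cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
    config = ModelConfig(**cfg_d)
    model = TinyCNN(config, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
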