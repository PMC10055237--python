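"""The blood-pressure estimation network.

Each spatiotemporal feature-map slice (``S x cl x 3``, rows = ROI subsets,
columns = time) is encoded by a small residual CNN into a 64-d embedding; the
per-slice embedding sequence is fused by a bidirectional LSTM into a single
64-d clip feature ``F``.  Two heads share ``F``:

- a *BP-interval classifier* ``CLA``: one fully connected layer 64 -> 4
  producing logits ``F_cla`` and softmax probabilities ``R_cla`` over four
  blood-pressure groups, and
- a *BP-value calculator* ``REG``: one fully connected layer 68 -> 1 on the
  concatenation ``[F, F_cla]`` producing a value ``R_reg`` in mmHg.

The final estimate fuses both:  ``R = alpha * STA[argmax R_cla] + beta *
R_reg``, where ``STA`` holds one reference value per interval (midpoints by
default).  Turning the interval into an explicit, coarse prediction
regularizes the regression and anchors it to the label distribution.

The calculator's output is produced on a standardized internal scale and
mapped to mmHg by a *fixed* affine transform ``R_reg = mu + sigma * z`` with
``mu``/``sigma`` frozen from the training labels: predictions start at the
training mean and the head only has to learn the residual variation, which
keeps Adam at its default learning rate effective within few epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .sts_slicer import STSlice, slices_to_array

#: Default 4-interval grouping: bin edges and per-interval reference values (mmHg).
SBP_EDGES = (90.0, 110.0, 120.0, 130.0, 160.0)
SBP_STA = (100.0, 115.0, 125.0, 145.0)
DBP_EDGES = (50.0, 60.0, 70.0, 80.0, 100.0)
DBP_STA = (55.0, 65.0, 75.0, 90.0)


@dataclass(frozen=True)
class GroupScheme:
    """Four half-open BP intervals and their reference values (STA).

    ``bin_edges`` are 5 strictly increasing mmHg values defining intervals
    ``[e_k, e_{k+1})``; ``sta[k]`` is the reference value reported when the
    classifier picks interval ``k`` (interval midpoints by default).
    """

    target: str  # "sbp" or "dbp"
    bin_edges: tuple[float, ...]
    sta: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        sta = np.asarray(self.sta, dtype=float)
        if edges.size != sta.size + 1:
            raise ValueError("need len(bin_edges) == len(sta) + 1")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        for k, v in enumerate(sta):
            if not (edges[k] <= v < edges[k + 1]):
                raise ValueError(f"sta[{k}]={v} outside its interval [{edges[k]}, {edges[k+1]})")
        if self.target not in ("sbp", "dbp"):
            raise ValueError("target must be 'sbp' or 'dbp'")

    @property
    def n_groups(self) -> int:
        return len(self.sta)

    @classmethod
    def default_sbp(cls) -> "GroupScheme":
        return cls("sbp", SBP_EDGES, SBP_STA)

    @classmethod
    def default_dbp(cls) -> "GroupScheme":
        return cls("dbp", DBP_EDGES, DBP_STA)

    @classmethod
    def default_for(cls, target: str) -> "GroupScheme":
        return cls.default_sbp() if target == "sbp" else cls.default_dbp()


@dataclass
class ModelConfig:
    """Architecture and fusion hyper-parameters.

    width : channel width of the first CNN stage (the trunk widens to
        ``2 * width``); 12 keeps single-CPU training fast while leaving
        headroom for the waveform features.
    embed_dim : per-slice embedding and fused-feature dimension (64).
    bidirectional : temporal fusion over slices via BiLSTM (hidden size
        ``embed_dim / 2`` per direction) or plain LSTM (hidden ``embed_dim``).
    n_classes : number of BP intervals (4).
    alpha, beta : fusion weights of the interval reference value and the
        calculator output.
    """

    width: int = 12
    embed_dim: int = 64
    bidirectional: bool = True
    n_classes: int = 4
    alpha: float = 0.5
    beta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim != 64:
            raise ValueError("the fused feature F is 64-dimensional by design")
        if self.bidirectional and self.embed_dim % 2:
            raise ValueError("embed_dim must be even for a BiLSTM")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("fusion weights must be non-negative")


@dataclass
class ModelOutputs:
    """Per-clip network outputs: feature, logits, probabilities, values."""

    F: np.ndarray  # B x 64
    F_cla: np.ndarray  # B x 4 logits
    R_cla: np.ndarray  # B x 4 probabilities
    R_reg: np.ndarray  # B (mmHg)
    R: np.ndarray  # B fused estimate (mmHg)


def fuse_output(r_cla: np.ndarray, r_reg: np.ndarray | float, scheme: GroupScheme, alpha: float = 0.5, beta: float = 0.5) -> np.ndarray:
    """Fuse classifier and calculator: ``R = alpha * STA[argmax R_cla] + beta * R_reg``.

    Argmax ties break toward the lower class index.  ``alpha = 0`` reduces to
    pure regression (the "no classifier" ablation); ``beta = 0`` snaps to the
    interval reference value.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("fusion weights must be non-negative")
    r_cla = np.atleast_2d(np.asarray(r_cla, dtype=float))
    if r_cla.shape[-1] != scheme.n_groups:
        raise ValueError(f"R_cla has {r_cla.shape[-1]} classes; scheme has {scheme.n_groups}")
    sta = np.asarray(scheme.sta)
    picks = sta[np.argmax(r_cla, axis=-1)]
    return alpha * picks + beta * np.asarray(r_reg, dtype=float)


class BPENet:
    """Residual-CNN + (Bi)LSTM feature extractor with classifier/calculator heads.

    Weight layout is fully determined by :class:`ModelConfig`; initialization
    is seeded, and evaluation is deterministic (no dropout, no normalization
    statistics).
    """

    def __init__(self, config: ModelConfig, target_mean: float = 0.0, target_std: float = 1.0):
        self.config = config
        self.target_mean = float(target_mean)
        self.target_std = float(target_std)
        rng = np.random.default_rng(config.seed)
        w = config.width
        self.conv1 = nn.Conv2D(3, w, rng)
        self.bn1 = nn.BatchNorm2D(w)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.AvgPool2D(1, 3)
        self.res1 = nn.ResBlock(w, 2 * w, rng)
        self.pool2 = nn.AvgPool2D(3, 5)
        self.res2 = nn.ResBlock(2 * w, 2 * w, rng)
        self.gap = nn.GlobalAvgPool()
        self.proj = nn.Linear(2 * w, config.embed_dim, rng)
        if config.bidirectional:
            self.lstm = nn.BiLSTM(config.embed_dim, config.embed_dim // 2, rng)
        else:
            self.lstm = nn.LSTM(config.embed_dim, config.embed_dim, rng)
        self.cla = nn.Linear(config.embed_dim, config.n_classes, rng)
        self.reg = nn.Linear(config.embed_dim + config.n_classes, 1, rng)
        self._encoder = [self.conv1, self.bn1, self.relu1, self.pool1, self.res1, self.pool2, self.res2, self.gap, self.proj]
        self.layers = self._encoder + [self.lstm, self.cla, self.reg]
        self._batchnorms = [self.bn1] + self.res1.batchnorms + self.res2.batchnorms

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list:
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self) -> list:
        return [g for lay in self.layers for g in lay.grads]

    def state_dict(self) -> dict:
        return {
            "params": [p.copy() for p in self.params],
            "bn_state": [bn.state() for bn in self._batchnorms],
            "target_mean": self.target_mean,
            "target_std": self.target_std,
        }

    def load_state_dict(self, state: dict) -> None:
        saved = state["params"]
        own = self.params
        if len(saved) != len(own):
            raise ValueError("snapshot does not match this architecture")
        for p, s in zip(own, saved):
            if p.shape != np.asarray(s).shape:
                raise ValueError("snapshot does not match this architecture")
            p[...] = s
        for bn, s in zip(self._batchnorms, state.get("bn_state", [])):
            bn.load_state(s)
        self.target_mean = float(state["target_mean"])
        self.target_std = float(state["target_std"])

    # -- forward ------------------------------------------------------------
    def _encode(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lay in self._encoder:
            if isinstance(lay, (nn.BatchNorm2D, nn.ResBlock)):
                x = lay.forward(x, train)
            else:
                x = lay.forward(x)
        return x

    def forward(self, batch: np.ndarray, train: bool = False) -> ModelOutputs:
        """Full forward pass on a ``B x M x S x cl x 3`` slice batch.

        ``train=True`` uses batch statistics in the normalization layers;
        evaluation uses their running averages and is fully deterministic.
        """
        batch = np.asarray(batch, dtype=float)
        if batch.ndim != 5 or batch.shape[-1] != 3:
            raise ValueError(f"expected B x M x S x cl x 3, got {batch.shape}")
        b, m, s, cl, c = batch.shape
        self._bm = (b, m)
        emb = self._encode(batch.reshape(b * m, s, cl, c), train)  # (B*M) x 64
        feat = self.lstm.forward(emb.reshape(b, m, -1))  # B x 64
        logits = self.cla.forward(feat)
        self._reg_in = np.concatenate([feat, logits], axis=1)
        z = self.reg.forward(self._reg_in)[:, 0]
        r_reg = self.target_mean + self.target_std * z
        # R without a grouping scheme is just the calculator value; use
        # outputs() for the fused estimate.
        return ModelOutputs(F=feat, F_cla=logits, R_cla=nn.softmax(logits), R_reg=r_reg, R=r_reg.copy())

    def outputs(self, batch: np.ndarray, scheme: GroupScheme) -> ModelOutputs:
        """Forward pass plus output fusion against a grouping scheme."""
        out = self.forward(batch)
        fused = fuse_output(out.R_cla, out.R_reg, scheme, self.config.alpha, self.config.beta)
        return ModelOutputs(F=out.F, F_cla=out.F_cla, R_cla=out.R_cla, R_reg=out.R_reg, R=fused)

    # -- backward -----------------------------------------------------------
    def backward(self, g_logits: np.ndarray, g_rreg: np.ndarray) -> None:
        """Backpropagate gradients on the logits and on R_reg (mmHg scale)."""
        b, m = self._bm
        gz = (g_rreg * self.target_std)[:, None]
        g_reg_in = self.reg.backward(gz)
        g_feat = g_reg_in[:, : self.config.embed_dim]
        g_logits_total = g_logits + g_reg_in[:, self.config.embed_dim :]
        g_feat = g_feat + self.cla.backward(g_logits_total)
        g_emb = self.lstm.backward(g_feat).reshape(b * m, -1)
        g = g_emb
        for lay in reversed(self._encoder):
            g = lay.backward(g)

    def clone(self) -> "BPENet":
        other = BPENet(self.config, self.target_mean, self.target_std)
        other.load_state_dict(self.state_dict())
        return other


# -- functional surface ------------------------------------------------------

def extract_features(slices: list[STSlice], net: BPENet) -> np.ndarray:
    """64-d fused clip feature F from one clip's slice sequence."""
    if not slices:
        raise ValueError("need at least one slice")
    batch = slices_to_array(slices)[None, ...]
    return net.forward(batch).F[0]


def classify(net: BPENet, feature: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classifier head on a 64-d feature: (logits F_cla, probabilities R_cla)."""
    feature = np.atleast_2d(np.asarray(feature, dtype=float))
    if feature.shape[1] != net.config.embed_dim:
        raise ValueError(f"feature must be {net.config.embed_dim}-d, got {feature.shape[1]}")
    logits = net.cla.forward(feature)
    return logits, nn.softmax(logits)


def regress(net: BPENet, feature: np.ndarray, logits: np.ndarray) -> np.ndarray:
    """Calculator head on [F, F_cla] (68-d): the BP value R_reg in mmHg."""
    feature = np.atleast_2d(np.asarray(feature, dtype=float))
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    cat = np.concatenate([feature, logits], axis=1)
    expected = net.config.embed_dim + net.config.n_classes
    if cat.shape[1] != expected:
        raise ValueError(f"calculator input must be {expected}-d, got {cat.shape[1]}")
    z = net.reg.forward(cat)[:, 0]
    return net.target_mean + net.target_std * z
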