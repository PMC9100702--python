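"""Regional brain fusion (RBF) model assembly.

Three parallel GCN channels process the full brain (FB), the left hemisphere
(LH) and the right hemisphere (RH) of each subject; channels share no
parameters. Each channel's node-level output map is pooled into one
graph-level feature vector (global mean pooling by default), the three vectors
are fused by concatenation ``[h_f, h_l, h_r]`` or element-wise addition
``h_f + h_l + h_r``, and a 2-layer MLP with log-softmax predicts the stage.

The single-channel baseline (FB only, fusion bypassed) and the ANNA switch per
channel span the full ablation lattice:

    baseline, anna, rbf_c, rbf_a, rbf_gcn_c, rbf_gcn_a
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .hemisphere import extract_hemispheres
from .network_data import BrainNetwork
from .nn import (
    MLP,
    GCNStack,
    log_softmax,
    nll_loss,
    normalize_adjacency,
)

__all__ = [
    "ARMS",
    "RBFConfig",
    "FusedFeatures",
    "RBFGCNModel",
    "channel_forward",
    "fuse",
    "rbf_forward",
    "readout",
]

#: Ablation arms: single-channel baseline GCN, baseline + ANNA, RBF framework
#: with concat/add over plain GCN channels, and the full model (ANNA in every
#: channel) with concat/add fusion.
ARMS = ("baseline", "anna", "rbf_c", "rbf_a", "rbf_gcn_c", "rbf_gcn_a")

CHANNELS = ("FB", "LH", "RH")


@dataclass
class RBFConfig:
    """Architecture switches for the RBF-GCN and its ablations."""

    use_anna: dict[str, bool] = field(
        default_factory=lambda: {c: True for c in CHANNELS}
    )
    fusion: str = "concat"  # "concat" | "add"
    channels: tuple[str, ...] = CHANNELS
    readout: str = "mean"  # "mean" | "sum" | "max"
    n_classes: int = 3
    hidden: int = 32
    n_layers: int = 3
    mlp_hidden: int = 32
    activation: str = "relu"
    add_node_identity: bool = True
    anna_init: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.use_anna, bool):
            self.use_anna = {c: self.use_anna for c in CHANNELS}
        if self.fusion not in ("concat", "add"):
            raise ValueError(f"fusion must be 'concat' or 'add', got {self.fusion!r}")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}; valid: {CHANNELS}")
        if self.readout not in ("mean", "sum", "max"):
            raise ValueError(f"unknown readout {self.readout!r}")

    @property
    def fused_width(self) -> int:
        if self.fusion == "concat":
            return self.hidden * len(self.channels)
        return self.hidden

    @classmethod
    def from_arm(cls, arm: str, n_classes: int = 3, **overrides) -> "RBFConfig":
        """Build the configuration for one ablation arm."""
        if arm not in ARMS:
            raise ValueError(f"unknown arm {arm!r}; valid arms: {ARMS}")
        anna = arm in ("anna", "rbf_gcn_c", "rbf_gcn_a")
        channels = ("FB",) if arm in ("baseline", "anna") else CHANNELS
        fusion = "add" if arm.endswith("_a") and arm != "anna" else "concat"
        return cls(
            use_anna={c: anna for c in CHANNELS},
            fusion=fusion,
            channels=channels,
            n_classes=n_classes,
            **overrides,
        )


@dataclass(frozen=True)
class FusedFeatures:
    """Graph-level feature vector(s) after channel fusion."""

    vector: np.ndarray
    provenance: str


def readout(H: np.ndarray, rule: str = "mean") -> np.ndarray:
    """Pool node-level maps ``(n, m, d)`` into graph-level vectors ``(n, d)``."""
    if rule == "mean":
        return H.mean(axis=-2)
    if rule == "sum":
        return H.sum(axis=-2)
    if rule == "max":
        return H.max(axis=-2)
    raise ValueError(f"unknown readout {rule!r}")


def fuse(features_fb: np.ndarray, features_lh: np.ndarray,
         features_rh: np.ndarray, rule: str = "concat") -> FusedFeatures:
    """Merge the three channel outputs in fixed FB, LH, RH order."""
    fs = [np.atleast_2d(np.asarray(f, dtype=float))
          for f in (features_fb, features_lh, features_rh)]
    if rule == "concat":
        return FusedFeatures(np.concatenate(fs, axis=-1).squeeze(), "concat")
    if rule == "add":
        widths = {f.shape[-1] for f in fs}
        if len(widths) != 1:
            raise ValueError(
                "addition fusion requires equal channel widths (the three "
                f"feature maps must have the same shape); got {[f.shape[-1] for f in fs]}"
            )
        return FusedFeatures((fs[0] + fs[1] + fs[2]).squeeze(), "add")
    raise ValueError(f"unknown fusion rule {rule!r}")


def _channel_features(net: BrainNetwork, add_identity: bool) -> np.ndarray:
    F = net.attributes
    if add_identity:
        F = np.concatenate([F, np.eye(net.m)], axis=1)
    return F


def channel_forward(net: BrainNetwork, stack: GCNStack,
                    rule: str = "mean", add_identity: bool = False) -> np.ndarray:
    """Run one channel on one (sub)network: normalize, propagate, pool."""
    S = normalize_adjacency(net.adjacency).matrix
    H = _channel_features(net, add_identity)
    out = stack.forward(S[None], H[None])
    return readout(out, rule)[0]


class RBFGCNModel:
    """Trainable multi-channel GCN classifier over attributed brain networks.

    Hidden widths follow the reference setup: ``n_layers`` graph-convolution
    layers of ``hidden`` units per channel and a 2-layer MLP of ``mlp_hidden``
    units. Parameters are Xavier-normal initialized; ANNA gains start at
    ``config.anna_init`` (0 by default, i.e. at the plain-GCN point).
    """

    def __init__(self, config: RBFConfig, m: int, d: int, seed: int = 0):
        self.config = config
        self.m = m
        self.d = d
        rng = np.random.default_rng(seed)
        self.stacks: dict[str, GCNStack] = {}
        for ch in config.channels:
            m_ch = m if ch == "FB" else m // 2
            d_in = d + (m_ch if config.add_node_identity else 0)
            widths = [d_in] + [config.hidden] * config.n_layers
            self.stacks[ch] = GCNStack(
                widths, use_anna=config.use_anna[ch], rng=rng,
                activation=config.activation, anna_init=config.anna_init,
            )
        self.mlp = MLP(
            (config.fused_width, config.mlp_hidden, config.n_classes), rng,
            activation=config.activation,
        )

    # ---------------------------------------------------------------- inputs
    def prepare_inputs(self, networks: list[BrainNetwork]) -> dict[str, tuple]:
        """Precompute per-channel normalized adjacencies and feature tensors."""
        per_channel: dict[str, tuple] = {}
        parts = {"FB": networks}
        if any(ch in self.config.channels for ch in ("LH", "RH")):
            split = [extract_hemispheres(n) for n in networks]
            parts["LH"] = [s[0] for s in split]
            parts["RH"] = [s[1] for s in split]
        for ch in self.config.channels:
            nets = parts[ch]
            S = np.stack([normalize_adjacency(n.adjacency).matrix for n in nets])
            H = np.stack(
                [_channel_features(n, self.config.add_node_identity) for n in nets]
            )
            per_channel[ch] = (S, H)
        return per_channel

    @staticmethod
    def take(inputs: dict[str, tuple], idx: np.ndarray) -> dict[str, tuple]:
        """Index a subject subset out of prepared inputs."""
        return {ch: (S[idx], H[idx]) for ch, (S, H) in inputs.items()}

    # --------------------------------------------------------------- forward
    def forward(self, inputs: dict[str, tuple]) -> np.ndarray:
        """Log class probabilities, shape ``(n, n_classes)``."""
        pooled = {}
        self._node_counts = {}
        for ch in self.config.channels:
            S, H = inputs[ch]
            out = self.stacks[ch].forward(S, H)
            pooled[ch] = readout(out, self.config.readout)
            self._node_counts[ch] = out.shape[1]
            if self.config.readout == "max":
                self._argmax = getattr(self, "_argmax", {})
                self._argmax[ch] = out.argmax(axis=1)
        if len(self.config.channels) == 1:
            fused = pooled[self.config.channels[0]]
        elif self.config.fusion == "concat":
            fused = np.concatenate(
                [pooled[ch] for ch in self.config.channels], axis=1
            )
        else:
            fused = sum(pooled[ch] for ch in self.config.channels)
        scores = self.mlp.forward(fused)
        return log_softmax(scores)

    def loss_and_grads(
        self, inputs: dict[str, tuple], labels: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean NLL and gradients for every parameter, by backpropagation."""
        logp = self.forward(inputs)
        n, c = logp.shape
        loss = nll_loss(logp, labels)
        dz = np.exp(logp)
        dz[np.arange(n), labels] -= 1.0
        dz /= n
        grads: dict[str, np.ndarray] = {}
        for name, g in self.mlp.backward(dz).items():
            grads[f"mlp.{name}"] = g
        dfused = self.mlp.dX
        width = self.config.hidden
        for k, ch in enumerate(self.config.channels):
            if len(self.config.channels) == 1 or self.config.fusion == "add":
                dg = dfused
            else:
                dg = dfused[:, k * width:(k + 1) * width]
            m_ch = self._node_counts[ch]
            if self.config.readout == "mean":
                dH = np.repeat(dg[:, None, :], m_ch, axis=1) / m_ch
            elif self.config.readout == "sum":
                dH = np.repeat(dg[:, None, :], m_ch, axis=1)
            else:  # max
                dH = np.zeros((dg.shape[0], m_ch, dg.shape[1]))
                am = self._argmax[ch]
                rows = np.arange(dg.shape[0])[:, None]
                cols = np.arange(dg.shape[1])[None, :]
                dH[rows, am, cols] = dg
            for name, g in self.stacks[ch].backward(dH).items():
                grads[f"{ch}.{name}"] = g
        return loss, grads

    def predict(self, inputs: dict[str, tuple]) -> np.ndarray:
        """Argmax class prediction; ties break toward the lower class index."""
        logp = self.forward(inputs)
        return logp.argmax(axis=1)

    # ------------------------------------------------------------ parameters
    def get_params(self) -> dict[str, np.ndarray]:
        params = {f"mlp.{k}": v for k, v in self.mlp.get_params().items()}
        for ch, stack in self.stacks.items():
            for k, v in stack.get_params().items():
                params[f"{ch}.{k}"] = v
        return params

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.mlp.set_params(
            {k.split(".", 1)[1]: v for k, v in params.items() if k.startswith("mlp.")}
        )
        for ch, stack in self.stacks.items():
            stack.set_params(
                {k.split(".", 1)[1]: v for k, v in params.items()
                 if k.startswith(f"{ch}.")}
            )

    # ------------------------------------------------------------ checkpoint
    def save(self, path: str | Path) -> None:
        """Serialize config and parameters to ``<path>.npz`` + ``<path>.json``."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.get_params())
        meta = {"config": asdict(self.config), "m": self.m, "d": self.d}
        meta["config"]["channels"] = list(self.config.channels)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RBFGCNModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["config"]
        cfg["channels"] = tuple(cfg["channels"])
        model = cls(RBFConfig(**cfg), m=meta["m"], d=meta["d"])
        with np.load(path.with_suffix(".npz")) as data:
            model.set_params({k: data[k] for k in data.files})
        return model


def rbf_forward(net: BrainNetwork, model: RBFGCNModel) -> np.ndarray:
    """Log class probabilities for a single subject through the full pipeline."""
    inputs = model.prepare_inputs([net])
    return model.forward(inputs)[0]
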