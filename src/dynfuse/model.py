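"""The interaction-driven dynamic fusion network.

Architecture, per session (T utterances):

1. each modality block is projected into a shared d-dimensional latent
   space (visual blocks are layer-normalized before projection);
2. the semantic and head-pose visual streams fuse (``vis_fusion``);
3. acoustic features join the running stream (``audio_fusion``);
4. text features join (``text_fusion``);
5. attention-based temporal pooling (MIL-style) aggregates the T
   utterance embeddings into one session vector;
6. a sigmoid linear head produces the depression probability.

Each of the three fusion positions independently uses one of four
operators — concatenation (re-projected 2d->d), summation, sigmoid
gating, or single-head scaled-dot-product cross-attention — giving the
4^3 strategy grid.  Gated and attention stages record their gate vector
``g`` / attention map ``alpha`` in a :class:`TraceBundle` for post hoc
interpretability analysis.

Cross-attention uses the identity query (Q = h_a): with a single head
and d_k = d a learned query projection is redundant up to the
reparametrization W_Q^T W_K -> single matrix, and leaving it out makes
the stage's added weights exactly 4d^2 (K, V: d^2 each; output map on
[h_a ; c]: 2d^2), twice concatenation's 2d^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import MODALITIES, FusionConfig
from .synth import SessionRecord
from .tensor import Tensor, concat, no_grad

__all__ = [
    "ProjectionSpec", "TraceBundle", "FusionModel",
    "ConcatFusion", "SumFusion", "GatedFusion", "CrossAttentionFusion",
    "TemporalAttentionPool", "Classifier",
    "count_stage_params", "save_checkpoint", "load_checkpoint",
]


# ------------------------------------------------------------- projections

@dataclass
class ProjectionSpec:
    """Recipe for one modality's projection MLP into the shared space.

    ``recipe`` is a list of layer blocks; each block is
    (out_width, norm, activation) with norm in {None,'layer','batch'},
    activation in {'relu','gelu'}.  ``pre_norm`` layer-normalizes the raw
    features before the first linear (used for both visual streams).
    """

    modality: str
    input_dim: int
    output_dim: int
    recipe: list[tuple[int, str | None, str]]
    dropout: float = 0.3
    pre_norm: bool = False

    @classmethod
    def default(cls, modality: str, input_dim: int, d: int = 256,
                dropout: float = 0.3, audio_hidden: int = 128) -> "ProjectionSpec":
        if modality == "visual_semantic":
            return cls(modality, input_dim, d, [(d, None, "relu")],
                       dropout, pre_norm=True)
        if modality == "pose":
            # unspecified in the source design; mirrors the semantic recipe
            return cls(modality, input_dim, d, [(d, None, "relu")],
                       dropout, pre_norm=True)
        if modality == "audio":
            return cls(modality, input_dim, d,
                       [(audio_hidden, "batch", "relu"), (d, "batch", "relu")],
                       dropout)
        if modality == "text":
            return cls(modality, input_dim, d,
                       [(d, "layer", "gelu"), (d, "layer", "gelu")], dropout)
        raise ValueError(f"unknown modality {modality!r}")

    def build(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Module] = []
        if self.pre_norm:
            layers.append(nn.LayerNorm(self.input_dim, affine=False))
        width = self.input_dim
        for out_width, norm, act in self.recipe:
            layers.append(nn.Linear(width, out_width, rng=rng))
            if norm == "batch":
                layers.append(nn.BatchNorm1d(out_width))
            elif norm == "layer":
                layers.append(nn.LayerNorm(out_width))
            layers.append(nn.ReLU() if act == "relu" else nn.GELU())
            layers.append(nn.Dropout(self.dropout, rng=rng))
            width = out_width
        if width != self.output_dim:
            raise ValueError(
                f"{self.modality} recipe ends at width {width}, "
                f"shared space requires {self.output_dim}")
        return nn.Sequential(*layers)


def project(block: np.ndarray, projection: nn.Module) -> np.ndarray:
    """Evaluate a projection on one block (eval mode, no autodiff tape)."""
    projection.eval()
    with no_grad():
        return projection(Tensor(np.asarray(block, dtype=float))).data


# ------------------------------------------------------------ fusion stages

class ConcatFusion(nn.Module):
    """[h_a ; h_b] re-projected 2d -> d by a single linear map."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(2 * d, d, rng=rng)

    def forward(self, ha: Tensor, hb: Tensor):
        if ha.shape != hb.shape:
            raise ValueError(f"shape mismatch: {ha.shape} vs {hb.shape}")
        return self.proj(concat([ha, hb], axis=-1)), None


class SumFusion(nn.Module):
    """Elementwise sum; zero trainable parameters."""

    def forward(self, ha: Tensor, hb: Tensor):
        if ha.shape != hb.shape:
            raise ValueError(f"shape mismatch: {ha.shape} vs {hb.shape}")
        return ha + hb, None


class GatedFusion(nn.Module):
    """g = sigmoid(W_g [h_a ; h_b] + b_g); out = g*h_a + (1-g)*h_b.

    Vector gate (width d) by default, following the elementwise product
    in the fusion equations; ``scalar=True`` gives one gate per utterance.
    The gate values are returned as the interpretability trace.
    """

    def __init__(self, d: int, rng: np.random.Generator, scalar: bool = False):
        super().__init__()
        self.gate = nn.Linear(2 * d, 1 if scalar else d, rng=rng)

    def forward(self, ha: Tensor, hb: Tensor):
        if ha.shape != hb.shape:
            raise ValueError(f"shape mismatch: {ha.shape} vs {hb.shape}")
        g = self.gate(concat([ha, hb], axis=-1)).sigmoid()
        out = g * ha + (1.0 - g) * hb
        return out, {"gate": g.data.copy()}


class CrossAttentionFusion(nn.Module):
    """Single-head scaled dot-product attention of the running stream
    (queries) over the incoming modality's utterances (keys/values),
    followed by a 2d -> d output map on [h_a ; context]."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.wk = nn.Linear(d, d, rng=rng)
        self.wv = nn.Linear(d, d, rng=rng)
        self.wo = nn.Linear(2 * d, d, rng=rng)
        self.dk = d

    def forward(self, ha: Tensor, hb: Tensor):
        if hb.shape[0] == 0:
            raise ValueError("complementary stream has no utterances")
        if ha.shape[-1] != hb.shape[-1]:
            raise ValueError(f"latent width mismatch: {ha.shape} vs {hb.shape}")
        k = self.wk(hb)
        v = self.wv(hb)
        scores = (ha @ k.T) * (1.0 / np.sqrt(self.dk))
        alpha = scores.softmax(axis=-1)
        context = alpha @ v
        out = self.wo(concat([ha, context], axis=-1))
        return out, {"alpha": alpha.data.copy()}


_STAGE_BUILDERS = {
    "concat": lambda d, rng, scalar: ConcatFusion(d, rng),
    "sum": lambda d, rng, scalar: SumFusion(),
    "gated": lambda d, rng, scalar: GatedFusion(d, rng, scalar=scalar),
    "attention": lambda d, rng, scalar: CrossAttentionFusion(d, rng),
}


def count_stage_params(strategy: str, d: int,
                       scalar_gate: bool = False) -> dict[str, int]:
    """Exact trainable-parameter ledger for one fusion stage.

    weights: concat 2d^2, sum 0, gated 2d^2 (vector gate), attention 4d^2.
    """
    if strategy == "sum":
        counts = {"weights": 0, "biases": 0}
    elif strategy == "concat":
        counts = {"weights": 2 * d * d, "biases": d}
    elif strategy == "gated":
        if scalar_gate:
            counts = {"weights": 2 * d, "biases": 1}
        else:
            counts = {"weights": 2 * d * d, "biases": d}
    elif strategy == "attention":
        counts = {"weights": 4 * d * d, "biases": 3 * d}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    counts["total"] = counts["weights"] + counts["biases"]
    return counts


# ---------------------------------------------------------- pooling / head

class TemporalAttentionPool(nn.Module):
    """MIL-style attention pooling: alpha_t = softmax(w . h_t), h = sum alpha_t h_t."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.w = nn.Linear(d, 1, bias=False, rng=rng)

    def forward(self, h: Tensor):
        if h.shape[0] < 1:
            raise ValueError("cannot pool an empty utterance sequence")
        scores = self.w(h)              # (T, 1)
        alpha = scores.softmax(axis=0)  # sums to 1 over utterances
        pooled = alpha.T @ h            # (1, d)
        return pooled, alpha.data.ravel().copy()


class Classifier(nn.Module):
    """Binary head: sigmoid(W_o h + b_o)."""

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.head = nn.Linear(d, 1, rng=rng)

    def forward(self, h: Tensor) -> Tensor:
        if not np.all(np.isfinite(h.data)):
            raise ValueError("non-finite session representation")
        return self.head(h).sigmoid()


# ------------------------------------------------------------- full model

@dataclass
class TraceBundle:
    """Interpretability traces captured during one session forward pass."""

    gate_vectors: dict[str, np.ndarray] = field(default_factory=dict)
    attention_maps: dict[str, np.ndarray] = field(default_factory=dict)
    pooling_weights: np.ndarray | None = None


class FusionModel(nn.Module):
    """The full session-level classifier for one fusion configuration."""

    STAGES = ("vis", "audio", "text")

    def __init__(self, config: FusionConfig, dims: dict[str, int],
                 seed: int = 0):
        super().__init__()
        self.config = config
        self.dims = dict(dims)
        root = np.random.SeedSequence([int(seed), 7])
        rngs = [np.random.default_rng(s) for s in root.spawn(10)]
        d = config.d
        self.specs = {
            m: ProjectionSpec.default(m, dims[m], d=d, dropout=config.dropout,
                                      audio_hidden=config.audio_hidden)
            for m in self._needed_modalities()}
        self.projections = {m: self.specs[m].build(rngs[i])
                            for i, m in enumerate(sorted(self.specs))}
        scalar = config.scalar_gate
        self.stages = {"vis": _STAGE_BUILDERS[config.vis_fusion](d, rngs[4], scalar)}
        if config.use_audio:
            self.stages["audio"] = _STAGE_BUILDERS[config.audio_fusion](d, rngs[5], scalar)
        if config.use_text:
            self.stages["text"] = _STAGE_BUILDERS[config.text_fusion](d, rngs[6], scalar)
        self.pool = TemporalAttentionPool(d, rngs[7])
        self.classifier = Classifier(d, rngs[8])

    def _needed_modalities(self) -> list[str]:
        mods = ["visual_semantic", "pose"]
        if self.config.use_audio:
            mods.append("audio")
        if self.config.use_text:
            mods.append("text")
        return mods

    # ------------------------------------------------------------ forward
    def forward_session(self, record: SessionRecord):
        """One session -> (probability Tensor (1,1), TraceBundle)."""
        h: dict[str, Tensor] = {}
        for m in self._needed_modalities():
            if m not in record.blocks:
                raise KeyError(f"record {record.subject_id} is missing the "
                               f"configured modality block {m!r}")
            block = record.blocks[m]
            if block.shape[1] != self.dims[m]:
                raise ValueError(
                    f"{m} block width {block.shape[1]} != configured {self.dims[m]}")
            h[m] = self.projections[m](Tensor(block))

        trace = TraceBundle()
        stream, info = self.stages["vis"](h["visual_semantic"], h["pose"])
        self._record(trace, "vis", info)
        if self.config.use_audio:
            stream, info = self.stages["audio"](stream, h["audio"])
            self._record(trace, "audio", info)
        if self.config.use_text:
            stream, info = self.stages["text"](stream, h["text"])
            self._record(trace, "text", info)
        pooled, alpha_t = self.pool(stream)
        trace.pooling_weights = alpha_t
        prob = self.classifier(pooled)
        return prob, trace

    @staticmethod
    def _record(trace: TraceBundle, stage: str, info: dict | None) -> None:
        if not info:
            return
        if "gate" in info:
            trace.gate_vectors[stage] = info["gate"]
        if "alpha" in info:
            trace.attention_maps[stage] = info["alpha"]

    def predict_proba(self, records: list[SessionRecord],
                      with_traces: bool = False):
        """Deterministic eval-mode probabilities for a list of sessions."""
        was_training = self.training
        self.eval()
        probs = np.empty(len(records))
        traces: list[TraceBundle] = []
        with no_grad():
            for i, rec in enumerate(records):
                p, tr = self.forward_session(rec)
                probs[i] = p.data.item()
                if with_traces:
                    traces.append(tr)
        if was_training:
            self.train()
        return (probs, traces) if with_traces else probs


# ------------------------------------------------------------ checkpoints

def save_checkpoint(module: nn.Module, outdir: str | Path,
                    meta: dict | None = None) -> Path:
    """Bit-exact checkpoint: named arrays (.npz) + JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = module.state_dict()
    np.savez(outdir / "weights.npz", **state)
    info = dict(meta or {})
    info["arrays"] = {k: list(v.shape) for k, v in state.items()}
    (outdir / "meta.json").write_text(json.dumps(info, indent=2))
    return outdir


def load_checkpoint(indir: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    with np.load(indir / "weights.npz") as data:
        state = {k: data[k].copy() for k in data.files}
    return state, meta
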