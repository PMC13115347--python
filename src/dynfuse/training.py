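"""Losses, the training loop, and affective pretraining of projections.

Class imbalance is handled by weighting, never by resampling: the
positive-class weight w_pos = n_neg / n_pos is recomputed from the
*training-fold* labels at every fold.  Optimization is AdamW
(lr 1e-3, weight decay 1e-4) with gradient clipping at global norm 1.0
and early stopping on validation AUC.

A focal-loss variant (alpha=0.25, gamma=2.0, combined with w_pos) is
available by configuration but is not used in the default grid, keeping
one consistent objective across all conditions.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd

from . import nn
from .config import FusionConfig, TrainSpec
from .model import FusionModel, ProjectionSpec
from .stats import roc_auc
from .synth import PretrainCorpus, SessionRecord
from .tensor import Tensor, concat

__all__ = [
    "pos_weight", "weighted_bce", "focal_loss",
    "train_model", "pretrain_projection",
]

#: probabilities are clamped into [EPS, 1-EPS] inside the losses
EPS = 1e-7


def pos_weight(labels) -> float:
    """Per-fold positive class weight n_neg / n_pos from training labels."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("cannot compute pos_weight: no positive labels")
    return n_neg / n_pos


def _as_prob_tensor(probs) -> Tensor:
    p = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs, dtype=float))
    return p.clip(EPS, 1.0 - EPS)


def weighted_bce(probs, labels, w_pos: float = 1.0) -> Tensor:
    """Weighted binary cross-entropy, mean over samples; minority (y=1)
    terms scaled by ``w_pos``.  Accepts a Tensor (differentiable) or any
    array-like of probabilities in (0,1); values at 0/1 are clamped at 1e-7.
    """
    p = _as_prob_tensor(probs)
    y = np.asarray(labels, dtype=float).reshape(p.shape)
    term = Tensor(w_pos * y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -term.mean()


def focal_loss(probs, labels, w_pos: float = 1.0, alpha: float = 0.25,
               gamma: float = 2.0) -> Tensor:
    """Focal modulation of the weighted BCE.

    Per sample: (1 - p_t)^gamma * [alpha * w_pos * y * (-log p)
    + (1 - y) * (-log(1 - p))], mean-reduced.  The alpha factor scales
    only the positive term (so gamma=0, alpha=1 reduces exactly to
    :func:`weighted_bce`).
    """
    p = _as_prob_tensor(probs)
    y = np.asarray(labels, dtype=float).reshape(p.shape)
    p_t = Tensor(y) * p + Tensor(1.0 - y) * (1.0 - p)
    mod = (1.0 - p_t).pow(gamma) if gamma != 0 else Tensor(np.ones_like(y))
    ce = Tensor(alpha * w_pos * y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -(mod * ce).mean()


def _session_loss(spec: TrainSpec, probs: Tensor, labels, w_pos: float) -> Tensor:
    if spec.loss == "focal":
        return focal_loss(probs, labels, w_pos=w_pos,
                          alpha=spec.focal_alpha, gamma=spec.focal_gamma)
    return weighted_bce(probs, labels, w_pos=w_pos)


def train_model(train_records: list[SessionRecord],
                val_records: list[SessionRecord],
                config: FusionConfig,
                spec: TrainSpec,
                init_checkpoints: dict[str, dict[str, np.ndarray]] | None = None,
                w_pos: float | None = None,
                ) -> tuple[FusionModel, pd.DataFrame]:
    """Train one fusion model; return best-validation-AUC weights + history.

    ``init_checkpoints`` maps modality -> projection state dict (affective
    pretraining initialization); all parameters remain trainable.
    """
    train_ids = {r.subject_id for r in train_records}
    val_ids = {r.subject_id for r in val_records}
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"subject overlap between train and val: {sorted(overlap)}")
    labels = np.array([r.label for r in train_records])
    if w_pos is None:
        w_pos = pos_weight(labels)

    dims = {m: b.shape[1] for m, b in train_records[0].blocks.items()}
    model = FusionModel(config, dims, seed=spec.seed)
    for modality, state in (init_checkpoints or {}).items():
        if modality not in model.projections:
            raise KeyError(f"checkpoint for unused modality {modality!r}")
        model.projections[modality].load_state_dict(state)

    params = model.named_parameters()
    opt = nn.AdamW(params, lr=spec.lr, weight_decay=spec.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))

    best_auc = -np.inf
    best_state = model.state_dict()
    epochs_since_best = 0
    history = []
    for epoch in range(spec.max_epochs):
        model.train()
        order = rng.permutation(len(train_records))
        total_loss = 0.0
        for start in range(0, len(order), spec.batch_size):
            idx = order[start:start + spec.batch_size]
            probs = concat([model.forward_session(train_records[i])[0]
                            for i in idx], axis=0)
            loss = _session_loss(spec, probs, labels[idx], w_pos)
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, spec.grad_clip_norm)
            opt.step()
            total_loss += float(loss.data) * len(idx)
        val_scores = model.predict_proba(val_records)
        val_labels = [r.label for r in val_records]
        val_auc = roc_auc(val_scores, val_labels)
        history.append({"epoch": epoch, "loss": total_loss / len(order),
                        "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = copy.deepcopy(model.state_dict())
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= spec.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(history)


def pretrain_projection(corpus: PretrainCorpus, spec: TrainSpec,
                        d: int = 256, dropout: float = 0.3,
                        audio_hidden: int = 128, batch_size: int = 64,
                        ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Affectively pretrain one modality's projection head.

    Trains projection + a throwaway softmax affect-classification head on
    the corpus for ``spec.pretrain_epochs`` epochs; returns only the
    projection state dict (the downstream initialization) and a history
    of per-epoch loss / training accuracy.
    """
    n_classes = corpus.n_classes
    if n_classes < 2:
        raise ValueError("pretraining requires >= 2 affect classes")
    dim = corpus.features.shape[1]
    root = np.random.SeedSequence([int(spec.seed), 13])
    rng_init, rng_shuffle = (np.random.default_rng(s) for s in root.spawn(2))
    proj_spec = ProjectionSpec.default(corpus.modality, dim, d=d,
                                       dropout=dropout, audio_hidden=audio_hidden)
    proj = proj_spec.build(rng_init)
    head = nn.Linear(d, n_classes, rng=rng_init)

    params = proj.named_parameters("proj")
    params.update(head.named_parameters("head"))
    opt = nn.AdamW(params, lr=spec.lr, weight_decay=spec.weight_decay)
    onehot = np.eye(n_classes)[corpus.affect_labels]

    history = []
    n = corpus.features.shape[0]
    for epoch in range(spec.pretrain_epochs):
        proj.train()
        head.train()
        order = rng_shuffle.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            x = Tensor(corpus.features[idx])
            logits = head(proj(x))
            p = logits.softmax(axis=-1)
            picked = (p * Tensor(onehot[idx])).sum(axis=-1)
            loss = -(picked.clip(EPS, 1.0).log()).mean()
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, spec.grad_clip_norm)
            opt.step()
            total_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1)
                            == corpus.affect_labels[idx]).sum())
        history.append({"epoch": epoch, "loss": total_loss / n,
                        "accuracy": correct / n})
    proj.eval()
    return proj.state_dict(), pd.DataFrame(history)
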