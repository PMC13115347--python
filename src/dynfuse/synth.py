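"""Synthetic multimodal interview corpora and subject-independent folds.

The generator emulates the structure of a PHQ-9-labelled interview study
(74 subjects, 13 depressed, ~1:4.7 imbalance): per subject a session of
utterance-level feature vectors in four modality blocks (visual-semantic
embedding, head pose angles, acoustic functionals, text embedding).

Generative model (linear-Gaussian latent factor):

    z_i   = y_i + subject_sd * b_i            (per-subject affect score)
    z_it  = z_i + utterance_sd * e_it         (per-utterance jitter)
    x_mit = effect_m * z_it * L_m + noise_sd * eps     (one block row)

with one affect factor shared across modalities through fixed unit
loadings ``L_m``, so modalities are complementary views of the same
latent signal and gating can meaningfully redistribute weight.

Affective pretraining corpora carry a balanced discrete affect label
whose class means are graded along an affect axis.  The domain-shift
knob delta moves a corpus away from the target domain three ways at
once: an additive mean shift (delta * u_m), covariance inflation
(noise scaled by 1 + 0.25 delta), and a rotation of the affect axis
away from the target's loading (fully orthogonal at delta >= 2) — the
"recording conditions" boundary that makes large-shift pretraining
actively misleading rather than merely off-center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MODALITIES, PRETRAINABLE, ConfigError, SynthConfig

__all__ = [
    "SessionRecord", "PretrainCorpus", "FoldAssignment",
    "generate_target_dataset", "generate_pretrain_corpus",
    "make_subject_folds", "modality_loading", "oracle_modality_scores",
    "mean_discrepancy", "write_dataset", "read_dataset", "export_csv",
]

# child-stream tags for the single-seed splitting scheme
_TAG_LOADINGS = 1
_TAG_TARGET = 2
_TAG_PRETRAIN = 3
_TAG_FOLDS = 4


@dataclass
class SessionRecord:
    """One subject's session: label + per-modality utterance feature blocks."""

    subject_id: str
    label: int
    blocks: dict[str, np.ndarray]

    @property
    def t_utt(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be binary")
        lengths = {m: b.shape[0] for m, b in self.blocks.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"blocks disagree on utterance count: {lengths}")
        for m, b in self.blocks.items():
            if not np.all(np.isfinite(b)):
                raise ValueError(f"non-finite values in block {m!r}")


@dataclass
class PretrainCorpus:
    """Utterance-level affective pretraining corpus for one modality."""

    modality: str
    features: np.ndarray        # (N, dim)
    affect_labels: np.ndarray   # (N,) integer classes
    shift: float

    def __post_init__(self):
        if len(np.unique(self.affect_labels)) < 2:
            raise ValueError("pretraining corpus needs >= 2 affect classes")
        if self.features.shape[0] != self.affect_labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")

    @property
    def n_classes(self) -> int:
        return int(self.affect_labels.max()) + 1


@dataclass
class FoldAssignment:
    """Partition of subjects into k label-stratified, disjoint folds."""

    fold_of: dict[str, int]
    k: int
    labels: dict[str, int] = field(default_factory=dict)

    def subjects_in(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.fold_of.items() if f == fold)

    def split(self, test_fold: int, val_fold: int | None = None):
        """(train, val, test) subject-id lists; val rotates within training."""
        test = self.subjects_in(test_fold)
        if val_fold is None:
            val_fold = (test_fold + 1) % self.k
        if val_fold == test_fold:
            raise ValueError("validation fold must differ from test fold")
        val = self.subjects_in(val_fold)
        train = sorted(s for s, f in self.fold_of.items()
                       if f not in (test_fold, val_fold))
        return train, val, test


def _child_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


def modality_loading(cfg: SynthConfig, modality: str) -> np.ndarray:
    """The fixed unit loading vector L_m of the shared affect factor."""
    idx = MODALITIES.index(modality)
    rng = _child_rng(cfg.seed, _TAG_LOADINGS, idx)
    v = rng.normal(size=cfg.dims[modality])
    return v / np.linalg.norm(v)


def _orthogonal_to(loading: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector orthogonal to `loading` (Gram-Schmidt on a random draw)."""
    if loading.size < 2:
        return loading.copy()
    for _ in range(10):
        v = rng.normal(size=loading.size)
        v = v - (v @ loading) * loading
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm
    raise RuntimeError("failed to draw an orthogonal direction")


def generate_target_dataset(cfg: SynthConfig) -> list[SessionRecord]:
    """Sample the target-task corpus: ``n_subjects`` sessions, exactly
    ``n_positive`` labelled depressed.  Deterministic given ``cfg.seed``."""
    rng = _child_rng(cfg.seed, _TAG_TARGET)
    labels = np.zeros(cfg.n_subjects, dtype=int)
    labels[:cfg.n_positive] = 1
    rng.shuffle(labels)
    loadings = {m: modality_loading(cfg, m) for m in MODALITIES}

    records = []
    width = max(3, len(str(cfg.n_subjects - 1)))
    for i in range(cfg.n_subjects):
        y = int(labels[i])
        z_subject = y + cfg.subject_sd * rng.normal()
        t_utt = int(rng.integers(cfg.utterances_min, cfg.utterances_max + 1))
        z_utt = z_subject + cfg.utterance_sd * rng.normal(size=t_utt)
        blocks = {}
        for m in MODALITIES:
            signal = cfg.effect_size[m] * np.outer(z_utt, loadings[m])
            noise = cfg.noise_sd * rng.normal(size=(t_utt, cfg.dims[m]))
            blocks[m] = signal + noise
        records.append(SessionRecord(subject_id=f"S{i:0{width}d}", label=y,
                                     blocks=blocks))
    return records


def generate_pretrain_corpus(cfg: SynthConfig, modality: str,
                             n_samples: int) -> PretrainCorpus:
    """Sample a modality's affective pretraining corpus at its configured
    domain shift ``cfg.pretrain_shift[modality]``."""
    if modality not in PRETRAINABLE:
        raise ConfigError(
            f"unknown or non-pretrainable modality {modality!r}; "
            f"expected one of {PRETRAINABLE}")
    delta = cfg.pretrain_shift[modality]
    idx = PRETRAINABLE.index(modality)
    rng = _child_rng(cfg.seed, _TAG_PRETRAIN, idx)
    dim = cfg.dims[modality]
    loading = modality_loading(cfg, modality)
    perp = _orthogonal_to(loading, rng)
    shift_dir = rng.normal(size=dim)
    shift_dir /= np.linalg.norm(shift_dir)

    # affect axis rotates from the target loading toward an orthogonal
    # direction as delta grows; fully rotated at delta >= 2
    w = min(1.0, delta / 2.0)
    axis = (1.0 - w) * loading + w * perp
    axis /= np.linalg.norm(axis)

    n_classes = cfg.pretrain_classes
    labels = np.arange(n_samples) % n_classes
    rng.shuffle(labels)
    # graded class means along the affect axis, symmetric about the target
    # corpus grand mean so the delta=0 corpus is distributionally matched
    spread = 1.5
    grades = spread * (2.0 * labels / (n_classes - 1) - 1.0)
    mean_z_target = cfg.n_positive / cfg.n_subjects
    center = cfg.effect_size[modality] * mean_z_target

    noise_scale = cfg.noise_sd * (1.0 + 0.25 * delta)
    features = (center * loading[None, :]
                + grades[:, None] * axis[None, :]
                + delta * shift_dir[None, :]
                + noise_scale * rng.normal(size=(n_samples, dim)))
    return PretrainCorpus(modality=modality, features=features,
                          affect_labels=labels, shift=delta)


def mean_discrepancy(corpus: PretrainCorpus,
                     records: list[SessionRecord]) -> float:
    """L2 distance between the corpus feature mean and the target corpus
    pooled-utterance feature mean for the same modality."""
    target = np.concatenate([r.blocks[corpus.modality] for r in records])
    return float(np.linalg.norm(corpus.features.mean(axis=0)
                                - target.mean(axis=0)))


def oracle_modality_scores(cfg: SynthConfig,
                           records: list[SessionRecord],
                           modality: str) -> np.ndarray:
    """Oracle single-modality subject scores: session-mean feature projected
    on the true loading.  Diagnostic only — uses generator-side knowledge."""
    loading = modality_loading(cfg, modality)
    return np.array([r.blocks[modality].mean(axis=0) @ loading for r in records])


def make_subject_folds(records: list[SessionRecord], k: int = 5,
                       seed: int = 0) -> FoldAssignment:
    """Label-stratified partition of subjects into ``k`` disjoint folds.

    Every fold receives at least one positive and one negative subject;
    singleton folds (leave-one-subject-out) are rejected.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate subject_id in records")
    pos = [r.subject_id for r in records if r.label == 1]
    neg = [r.subject_id for r in records if r.label == 0]
    if len(pos) < k:
        raise ConfigError(f"cannot stratify: {len(pos)} positives < {k} folds")
    if len(neg) < k:
        raise ConfigError(f"cannot stratify: {len(neg)} negatives < {k} folds")
    if k >= len(records):
        raise ConfigError("singleton folds are not supported; reduce k")
    rng = _child_rng(seed, _TAG_FOLDS)
    pos = list(pos)
    neg = list(neg)
    rng.shuffle(pos)
    rng.shuffle(neg)
    fold_of: dict[str, int] = {}
    for i, sid in enumerate(pos):
        fold_of[sid] = i % k
    # deal negatives continuing round-robin so fold sizes stay balanced
    for i, sid in enumerate(neg):
        fold_of[sid] = (len(pos) + i) % k
    labels = {r.subject_id: r.label for r in records}
    return FoldAssignment(fold_of=fold_of, k=k, labels=labels)


# --------------------------------------------------------------------- io

def write_dataset(records: list[SessionRecord], outdir: str | Path,
                  cfg: SynthConfig | None = None) -> Path:
    """Write a corpus: JSON manifest + one portable .npz of all blocks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subjects": [{"id": r.subject_id, "label": r.label, "t_utt": r.t_utt}
                     for r in records],
        "modalities": list(MODALITIES),
        "dims": {m: int(records[0].blocks[m].shape[1]) for m in records[0].blocks},
        "config": cfg.model_dump(mode="json") if cfg is not None else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {f"{r.subject_id}::{m}": r.blocks[m] for r in records
              for m in r.blocks}
    np.savez_compressed(outdir / "sessions.npz", **arrays)
    return outdir


def read_dataset(indir: str | Path) -> tuple[list[SessionRecord], dict]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    with np.load(indir / "sessions.npz") as data:
        records = []
        for sub in manifest["subjects"]:
            blocks = {m: data[f"{sub['id']}::{m}"] for m in manifest["modalities"]}
            records.append(SessionRecord(subject_id=sub["id"],
                                         label=sub["label"], blocks=blocks))
    return records, manifest


def export_csv(records: list[SessionRecord], path: str | Path) -> None:
    """Flat long-format export (subject, utterance, modality, feature, value)."""
    frames = []
    for r in records:
        for m, block in r.blocks.items():
            t, d = block.shape
            frames.append(pd.DataFrame({
                "subject_id": np.repeat(r.subject_id, t * d),
                "utterance_idx": np.repeat(np.arange(t), d),
                "modality": m,
                "feature_idx": np.tile(np.arange(d), t),
                "value": block.ravel(),
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
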