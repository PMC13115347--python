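"""Canned parameter-recovery experiments on the desk-scale profile.

These reproduce, qualitatively and at desk scale, the transfer and gate
phenomena the full grid analyses: matched-domain visual pretraining
helps, large-shift acoustic pretraining does not, and a planted
visually-dominant signal pulls the intra-visual gate toward the
semantic stream.

Design (frozen; see docs/methods.md for rationale):

* world: :func:`dynfuse.config.desk_scale_config` (n=200 subjects,
  35 positive, k=3 subject-independent folds);
* pretraining: 2000 corpus samples, 30 epochs, dropout 0 — a strongly
  committed initialization;
* transfer arms fine-tune on a short budget (8 epochs, batch 8):
  initialization effects are only visible while training cannot fully
  wash out the starting point;
* the visual arm spans all four vis-fusion strategies (pretrained vs
  scratch compared across conditions, the way the grid-level transfer
  table is built); the audio arm uses summation at the audio stage,
  where an incoming stream cannot be down-weighted — the configuration
  in which pretraining-quality effects are strongest;
* the gate arm trains gated-visual models at the full desk budget
  (30 epochs) and pools per-subject gate means across test folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import desk_scale_config
from .stats import gate_dominance, mann_whitney_delta, roc_auc
from .synth import generate_pretrain_corpus, generate_target_dataset, make_subject_folds
from .training import pretrain_projection, train_model

__all__ = ["TransferArmResult", "transfer_experiment", "gate_experiment"]

#: large domain shift used for the negative-transfer acoustic arm
LARGE_AUDIO_SHIFT = 5.0
_PRETRAIN_SAMPLES = 2000
_PRETRAIN_EPOCHS = 30
_SHORT_BUDGET = {"max_epochs": 8, "patience": 7, "batch_size": 8}


@dataclass
class TransferArmResult:
    arm: str
    pretrained_aucs: np.ndarray
    scratch_aucs: np.ndarray
    delta: float
    p_value: float


def _pretrain_state(cfg, modality):
    corpus = generate_pretrain_corpus(cfg.synth, modality,
                                      _PRETRAIN_SAMPLES)
    spec = cfg.train.model_copy(update={"pretrain_epochs": _PRETRAIN_EPOCHS})
    state, _ = pretrain_projection(corpus, spec, d=cfg.fusion.d, dropout=0.0,
                                   audio_hidden=cfg.fusion.audio_hidden)
    return state


def transfer_experiment(arm: str, seeds=(0, 1, 2)) -> TransferArmResult:
    """Pretrained-vs-scratch downstream AUC comparison for one modality.

    ``arm='visual'``: matched-domain (delta=0) visual pretraining, all
    four vis-fusion strategies.  ``arm='audio'``: large-shift acoustic
    pretraining with summation audio fusion.  Returns per-run AUCs and
    a two-sided Mann-Whitney comparison (delta = mean_PT - mean_SC).
    """
    if arm == "visual":
        modality = "visual_semantic"
        variants = [{"vis_fusion": s, "audio_fusion": "concat",
                     "text_fusion": "concat"}
                    for s in ("gated", "concat", "sum", "attention")]
    elif arm == "audio":
        modality = "audio"
        variants = [{"vis_fusion": s, "audio_fusion": "sum",
                     "text_fusion": "concat"}
                    for s in ("gated", "concat")]
    else:
        raise ValueError(f"unknown arm {arm!r}")

    pt_aucs, sc_aucs = [], []
    for seed in seeds:
        cfg = desk_scale_config(seed)
        if arm == "audio":
            cfg.synth.pretrain_shift = dict(cfg.synth.pretrain_shift,
                                            audio=LARGE_AUDIO_SHIFT)
        records = generate_target_dataset(cfg.synth)
        folds = make_subject_folds(records, k=cfg.grid.k_folds, seed=seed)
        by = {r.subject_id: r for r in records}
        state = _pretrain_state(cfg, modality)
        for variant in variants:
            fusion = cfg.fusion.model_copy(update=variant)
            for fold in range(folds.k):
                tr, va, te = folds.split(fold)
                train = [by[s] for s in tr]
                val = [by[s] for s in va]
                test = [by[s] for s in te]
                y = [r.label for r in test]
                spec = cfg.train.model_copy(
                    update={**_SHORT_BUDGET, "seed": seed * 100 + fold})
                for init, sink in ((None, sc_aucs),
                                   ({modality: state}, pt_aucs)):
                    model, _ = train_model(train, val, fusion, spec,
                                           init_checkpoints=init)
                    sink.append(roc_auc(model.predict_proba(test), y))
    pt = np.asarray(pt_aucs)
    sc = np.asarray(sc_aucs)
    _, p, delta = mann_whitney_delta(pt, sc)
    return TransferArmResult(arm=arm, pretrained_aucs=pt, scratch_aucs=sc,
                             delta=delta, p_value=p)


def gate_experiment(seeds=(0, 1, 2)) -> dict:
    """Gate dominance under a planted visually-dominant signal.

    Trains gated-visual models (full desk budget) per fold and pools
    the per-subject vis-stage gate means over test folds, so every
    subject contributes exactly once per seed.  Returns per-seed and
    pooled (delta, t, p, class) from the paired gate analysis.
    """
    per_seed = {}
    pooled: list[float] = []
    for seed in seeds:
        cfg = desk_scale_config(seed)
        records = generate_target_dataset(cfg.synth)
        folds = make_subject_folds(records, k=cfg.grid.k_folds, seed=seed)
        by = {r.subject_id: r for r in records}
        fusion = cfg.fusion.model_copy(update={
            "vis_fusion": "gated", "audio_fusion": "concat",
            "text_fusion": "concat"})
        gates: list[float] = []
        for fold in range(folds.k):
            tr, va, te = folds.split(fold)
            spec = cfg.train.model_copy(update={"seed": seed * 100 + fold})
            model, _ = train_model([by[s] for s in tr], [by[s] for s in va],
                                   fusion, spec)
            _, traces = model.predict_proba([by[s] for s in te],
                                            with_traces=True)
            gates.extend(float(np.mean(t.gate_vectors["vis"])) for t in traces)
        delta, t, p, klass = gate_dominance(gates)
        per_seed[seed] = {"delta": delta, "t": t, "p": p, "class": klass,
                          "n_subjects": len(gates)}
        pooled.extend(gates)
    delta, t, p, klass = gate_dominance(pooled)
    return {"per_seed": per_seed,
            "pooled": {"delta": delta, "t": t, "p": p, "class": klass,
                       "n_subjects": len(pooled)}}
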