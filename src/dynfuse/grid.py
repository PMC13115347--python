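"""Enumeration and execution of the controlled fusion x pretraining grid.

The full grid crosses the four fusion strategies at each of the three
integration positions (4^3 = 64 triples) with the three binary
pretraining flags (2^3 = 8), yielding 512 conditions.  Architecture and
training hyperparameters are held constant across conditions; only the
strategy triple and the projection initialization vary.

Every condition is evaluated under subject-independent k-fold CV: the
test fold is held out, the next fold rotates in as the early-stopping
validation set, the rest train.  The per-fold positive class weight is
recomputed from that fold's training labels.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PRETRAINABLE, STRATEGIES, FusionConfig, TrainSpec
from .stats import pr_auc, roc_auc, threshold_metrics
from .synth import FoldAssignment, SessionRecord
from .training import pos_weight, train_model

__all__ = [
    "Condition", "RunResult", "enumerate_conditions", "stratified_subset",
    "run_condition", "run_grid", "aggregate_results",
]


@dataclass(frozen=True)
class Condition:
    """One grid cell: a strategy triple + three pretraining flags."""

    index: int
    vis_fusion: str
    audio_fusion: str
    text_fusion: str
    pt_visual: bool
    pt_audio: bool
    pt_text: bool

    @property
    def condition_id(self) -> str:
        flags = "".join(str(int(f)) for f in
                        (self.pt_visual, self.pt_audio, self.pt_text))
        return (f"c{self.index:03d}_v-{self.vis_fusion}_a-{self.audio_fusion}"
                f"_t-{self.text_fusion}_pt-{flags}")

    @property
    def n_pretrained(self) -> int:
        return int(self.pt_visual) + int(self.pt_audio) + int(self.pt_text)

    def pretrained_modalities(self) -> list[str]:
        return [m for m, on in zip(PRETRAINABLE,
                                   (self.pt_visual, self.pt_audio, self.pt_text))
                if on]

    def fusion_config(self, template: FusionConfig) -> FusionConfig:
        return template.model_copy(update={
            "vis_fusion": self.vis_fusion,
            "audio_fusion": self.audio_fusion,
            "text_fusion": self.text_fusion,
        })

    def group_labels(self) -> dict:
        return {"vis_fusion": self.vis_fusion, "audio_fusion": self.audio_fusion,
                "text_fusion": self.text_fusion, "pt_visual": self.pt_visual,
                "pt_audio": self.pt_audio, "pt_text": self.pt_text,
                "n_pretrained": self.n_pretrained}


@dataclass
class RunResult:
    """Metrics for one (condition, fold, seed) evaluation."""

    condition_id: str
    fold_id: int
    seed: int
    metrics: dict[str, float]
    group_labels: dict
    gate_delta_vis: float = float("nan")
    subject_gates: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"condition_id": self.condition_id, "fold_id": self.fold_id,
               "seed": self.seed, **self.metrics,
               "gate_delta_vis": self.gate_delta_vis}
        row.update(self.group_labels)
        return row


def enumerate_conditions(strategies: tuple[str, ...] = STRATEGIES,
                         ) -> list[Condition]:
    """Deterministically ordered grid; the default full grid has 512 cells."""
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    conditions = []
    combos = itertools.product(strategies, strategies, strategies,
                               (False, True), (False, True), (False, True))
    for i, (vis, aud, txt, pv, pa, pt) in enumerate(combos):
        conditions.append(Condition(index=i, vis_fusion=vis, audio_fusion=aud,
                                    text_fusion=txt, pt_visual=pv,
                                    pt_audio=pa, pt_text=pt))
    return conditions


def stratified_subset(conditions: list[Condition], n: int,
                      seed: int = 0) -> list[Condition]:
    """A strategy-balanced random subset: round-robin over the shuffled
    strategy triples, drawing one pretraining combination per visit."""
    if n >= len(conditions):
        return list(conditions)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    by_triple: dict[tuple, list[Condition]] = {}
    for c in conditions:
        by_triple.setdefault((c.vis_fusion, c.audio_fusion, c.text_fusion),
                             []).append(c)
    triples = sorted(by_triple)
    rng.shuffle(triples)
    for t in triples:
        rng.shuffle(by_triple[t])
    picked: list[Condition] = []
    while len(picked) < n:
        for t in triples:
            if by_triple[t] and len(picked) < n:
                picked.append(by_triple[t].pop())
    return sorted(picked, key=lambda c: c.index)


def _child_seed(base: int, *tags: int) -> int:
    return int(np.random.SeedSequence([int(base), *tags]).generate_state(1)[0]
               % (2 ** 31))


def run_condition(cond: Condition,
                  records: list[SessionRecord],
                  folds: FoldAssignment,
                  spec: TrainSpec,
                  template: FusionConfig,
                  checkpoints: dict[str, dict] | None = None,
                  seed: int = 0) -> list[RunResult]:
    """Evaluate one condition under subject-independent k-fold CV.

    ``checkpoints`` maps modality -> projection state dict; a flagged
    modality without a checkpoint raises an error naming it.
    """
    checkpoints = checkpoints or {}
    init = {}
    for modality in cond.pretrained_modalities():
        if modality not in checkpoints:
            raise KeyError(f"condition {cond.condition_id} requires a "
                           f"pretraining checkpoint for {modality!r}")
        init[modality] = checkpoints[modality]

    by_id = {r.subject_id: r for r in records}
    fusion_cfg = cond.fusion_config(template)
    results = []
    for test_fold in range(folds.k):
        train_ids, val_ids, test_ids = folds.split(test_fold)
        train = [by_id[s] for s in train_ids]
        val = [by_id[s] for s in val_ids]
        test = [by_id[s] for s in test_ids]
        fold_spec = spec.model_copy(
            update={"seed": _child_seed(seed, cond.index, test_fold)})
        w_pos = pos_weight([r.label for r in train])
        model, _ = train_model(train, val, fusion_cfg, fold_spec,
                               init_checkpoints=init, w_pos=w_pos)
        scores, traces = model.predict_proba(test, with_traces=True)
        labels = np.array([r.label for r in test])
        metrics = {"auc": roc_auc(scores, labels),
                   "pr_auc": pr_auc(scores, labels)}
        metrics.update(threshold_metrics(scores, labels))
        subject_gates = {}
        gate_delta = float("nan")
        if cond.vis_fusion == "gated":
            subject_gates = {rec.subject_id: float(np.mean(tr.gate_vectors["vis"]))
                             for rec, tr in zip(test, traces)}
            gate_delta = float(np.mean(
                [2 * g - 1 for g in subject_gates.values()]))
        results.append(RunResult(
            condition_id=cond.condition_id, fold_id=test_fold, seed=seed,
            metrics=metrics, group_labels=cond.group_labels(),
            gate_delta_vis=gate_delta, subject_gates=subject_gates))
    return results


def run_grid(conditions: list[Condition],
             records: list[SessionRecord],
             folds: FoldAssignment,
             spec: TrainSpec,
             template: FusionConfig,
             checkpoints: dict[str, dict] | None = None,
             seeds: list[int] | None = None,
             cache_dir: str | Path | None = None,
             progress=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run many conditions; returns (results table, subject gate table).

    With ``cache_dir`` set, finished conditions leave a done-marker JSON
    and are skipped on re-run (resumability).
    """
    seeds = seeds or [0]
    rows = []
    gate_rows = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for cond in conditions:
        for seed in seeds:
            marker = cache / f"{cond.condition_id}_s{seed}.json" if cache else None
            if marker is not None and marker.exists():
                payload = json.loads(marker.read_text())
            else:
                results = run_condition(cond, records, folds, spec, template,
                                        checkpoints=checkpoints, seed=seed)
                payload = {
                    "rows": [r.to_row() for r in results],
                    "gates": [{"condition_id": r.condition_id, "seed": seed,
                               "fold_id": r.fold_id, "subject_id": sid,
                               "gate_mean": g}
                              for r in results
                              for sid, g in r.subject_gates.items()],
                }
                if marker is not None:
                    marker.write_text(json.dumps(payload))
            rows.extend(payload["rows"])
            gate_rows.extend(payload["gates"])
            if progress is not None:
                progress(cond, seed)
    results_df = aggregate_results(rows)
    gates_df = pd.DataFrame(gate_rows, columns=["condition_id", "seed",
                                                "fold_id", "subject_id",
                                                "gate_mean"])
    return results_df, gates_df


def aggregate_results(rows) -> pd.DataFrame:
    """Long-format results table, one row per (condition, fold, seed)."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = [r.to_row() if isinstance(r, RunResult) else r for r in rows]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no results to aggregate")
    key = ["condition_id", "fold_id", "seed"]
    if df.duplicated(subset=key).any():
        dupes = df.loc[df.duplicated(subset=key), key].drop_duplicates()
        raise ValueError(f"duplicate result rows: {dupes.to_dict('records')}")
    return df.reset_index(drop=True)
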