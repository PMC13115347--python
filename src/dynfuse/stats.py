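"""Evaluation metrics and the statistical analysis layer.

Covers: rank AUC and average-precision PR-AUC (random baseline =
positive prevalence), thresholded confusion-matrix metrics,
Kruskal-Wallis across fusion strategies with the effect size
eta^2 = H / (N - 1) — applied with the *per-cell* N, the convention the
grouped strategy tables use — Mann-Whitney pretraining-transfer deltas
(Delta = mean_PT - mean_SC), and the paired-t gate-dominance analysis
(Delta = g_semantic - g_pose) with its verbal dominance classes.

All tests are two-sided at alpha = 0.05 with mid-rank tie handling and
no multiple-testing correction (raw p-values are reported).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score

__all__ = [
    "roc_auc", "pr_auc", "pr_baseline", "threshold_metrics",
    "eta_squared", "kruskal_wallis_eta2", "mann_whitney_delta",
    "gate_dominance", "classify_dominance", "StatReport", "analyze_results",
]

ALPHA = 0.05


# ----------------------------------------------------------------- metrics

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Ties receive mid-ranks, i.e. tied positive/negative pairs count 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = sps.rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve (average precision,
    step-function definition).  Random-baseline value equals the
    positive-class prevalence (:func:`pr_baseline`)."""
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("pr_auc requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def pr_baseline(labels) -> float:
    """Prevalence of the positive class: the chance-level PR-AUC."""
    labels = np.asarray(labels)
    return float((labels == 1).mean())


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at a decision threshold (ties count positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    if 2 * tp + fp + fn == 0:
        warnings.warn("F1 undefined (no positives predicted or present); "
                      "returning 0", stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
    return {
        "f1": f1,
        "balanced_accuracy": 0.5 * (sensitivity + specificity),
        "sensitivity": sensitivity,
        "specificity": specificity,
    }


# -------------------------------------------------------- hypothesis tests

def eta_squared(h: float, n_cell: int) -> float:
    """Kruskal-Wallis effect size eta^2 = H / (N - 1) for a given H.

    ``n_cell`` is the per-cell sample size (the convention the grouped
    strategy tables apply; see :func:`kruskal_wallis_eta2`).
    """
    if n_cell < 2:
        raise ValueError("n_cell must be >= 2")
    return float(h) / (n_cell - 1)


def kruskal_wallis_eta2(groups, n_cell: int | None = None,
                        use_total_n: bool = False) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected) with effect size eta^2 = H/(N-1).

    By default N is the *per-cell* (per-group) sample size ``n_cell``
    (inferred from the first group when not given) — the convention the
    grouped strategy tables apply.  ``use_total_n=True`` switches to the
    conventional pooled-N formula.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    n_total = sum(len(g) for g in groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset:offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts ** 3 - counts).sum() / (n_total ** 3 - n_total)
    if tie_term > 0:
        h /= tie_term
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    if use_total_n:
        denom_n = n_total
    else:
        denom_n = n_cell if n_cell is not None else len(groups[0])
    eta2 = h / (denom_n - 1)
    return float(h), p, float(eta2)


def mann_whitney_delta(a, b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with mean difference.

    Returns (U, p, delta) with delta = mean(a) - mean(b) and U counting
    pairs where a exceeds b (ties count 1/2), i.e. U = 0 when every value
    in ``a`` is below every value in ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), float(a.mean() - b.mean())


def _sign_label(delta: float, p: float) -> str:
    if p >= ALPHA:
        return "n.s."
    return "Positive" if delta > 0 else "Negative"


# ----------------------------------------------------------- gate analysis

def classify_dominance(delta: float, p: float) -> str:
    """Verbal dominance class for the intra-visual gate difference."""
    if p >= ALPHA:
        return "balanced"
    if delta < 0:
        return "reversal"
    return "strong_semantic" if delta > 0.5 else "moderate_semantic"


def gate_dominance(subject_gates) -> tuple[float, float, float, str]:
    """Paired comparison of semantic vs pose gate weight across subjects.

    ``subject_gates`` is one value or array of vis-stage gate values g per
    subject (averaged over utterances and gate dimensions here).  The
    per-subject difference is Delta_s = g_s - (1 - g_s); a paired t-test
    across subjects (equivalently a one-sample t on Delta) yields t and p.

    Returns (delta, t, p, dominance_class).  A zero-variance nonzero
    Delta (saturated gate) is reported with t = +/-inf and the p floor 0.
    """
    g = np.asarray([np.mean(x) for x in subject_gates], dtype=float)
    if g.size < 2:
        raise ValueError("gate dominance needs >= 2 subjects with gate traces")
    deltas = 2.0 * g - 1.0
    delta = float(deltas.mean())
    if np.allclose(deltas.std(ddof=1), 0.0):
        if np.isclose(delta, 0.0):
            t, p = 0.0, 1.0
        else:  # saturated: identical nonzero differences
            t, p = float(np.sign(delta) * np.inf), 0.0
    else:
        t, p = sps.ttest_1samp(deltas, 0.0)
        t, p = float(t), float(p)
    return delta, t, p, classify_dominance(delta, p)


# ----------------------------------------------------------- full analysis

@dataclass
class StatReport:
    """Grouped analysis mirroring the strategy / pretraining / gate tables."""

    fusion_tables: dict[str, pd.DataFrame]   # metric -> per-position table
    pretrain_table: pd.DataFrame
    gate_table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "fusion": {metric: df.to_dict(orient="records")
                       for metric, df in self.fusion_tables.items()},
            "pretraining": self.pretrain_table.to_dict(orient="records"),
            "gates": self.gate_table.to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True,
                          default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _sd(x) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


_POSITIONS = ("vis_fusion", "audio_fusion", "text_fusion")
_PT_FLAGS = {"visual_semantic": "pt_visual", "audio": "pt_audio",
             "text": "pt_text"}


def analyze_results(results: pd.DataFrame,
                    gates: pd.DataFrame | None = None,
                    metrics: tuple[str, ...] = ("auc", "pr_auc")) -> StatReport:
    """Build the grouped statistical report from the long results table.

    ``results`` has one row per (condition, fold, seed) with the grouping
    columns produced by the grid module.  Grouped tests operate on
    condition-level means (folds averaged within condition first).
    ``gates`` optionally has one row per (condition, subject) with the
    subject-level vis-stage gate mean for gated conditions.
    """
    if results.empty:
        raise ValueError("empty results table")
    group_cols = list(_POSITIONS) + list(_PT_FLAGS.values()) + ["n_pretrained"]
    cond = (results.groupby(["condition_id"] + group_cols, as_index=False)
            [list(metrics)].mean())

    fusion_tables = {}
    for metric in metrics:
        rows = []
        for position in _POSITIONS:
            strategies = sorted(cond[position].unique())
            groups = [cond.loc[cond[position] == s, metric].to_numpy()
                      for s in strategies]
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
                h, p, eta2 = kruskal_wallis_eta2(groups, n_cell=len(groups[0]))
            else:
                h = p = eta2 = float("nan")
            for s, g in zip(strategies, groups):
                rows.append({"position": position, "strategy": s,
                             "mean": float(np.mean(g)),
                             "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                             "n": len(g), "H": h, "p": p, "eta2": eta2})
        fusion_tables[metric] = pd.DataFrame(rows)

    pt_rows = []
    for modality, flag in _PT_FLAGS.items():
        if results[flag].nunique() < 2:
            continue
        pt = cond.loc[cond[flag], "auc"].to_numpy()
        sc = cond.loc[~cond[flag].astype(bool), "auc"].to_numpy()
        _, p, delta = mann_whitney_delta(pt, sc)
        pt_rows.append({"modality": modality,
                        "pt_mean": float(pt.mean()), "pt_sd": _sd(pt),
                        "sc_mean": float(sc.mean()), "sc_sd": _sd(sc),
                        "delta": delta, "p": p, "effect": _sign_label(delta, p)})
    all_pt = cond.loc[cond[list(_PT_FLAGS.values())].all(axis=1), "auc"].to_numpy()
    all_sc = cond.loc[~cond[list(_PT_FLAGS.values())].any(axis=1), "auc"].to_numpy()
    if len(all_pt) and len(all_sc):
        _, p, delta = mann_whitney_delta(all_pt, all_sc)
        pt_rows.append({"modality": "all3",
                        "pt_mean": float(all_pt.mean()), "pt_sd": _sd(all_pt),
                        "sc_mean": float(all_sc.mean()), "sc_sd": _sd(all_sc),
                        "delta": delta, "p": p, "effect": _sign_label(delta, p)})
    pretrain_table = pd.DataFrame(pt_rows)

    gate_rows = []
    if gates is not None and not gates.empty:
        for cond_id, grp in gates.groupby("condition_id"):
            if len(grp) < 2:
                continue
            delta, t, p, klass = gate_dominance(grp["gate_mean"].to_numpy())
            gate_rows.append({"condition_id": cond_id, "n_subjects": len(grp),
                              "delta": delta, "t": t, "p": p, "class": klass})
    gate_table = pd.DataFrame(
        gate_rows, columns=["condition_id", "n_subjects", "delta", "t", "p", "class"])
    return StatReport(fusion_tables=fusion_tables,
                      pretrain_table=pretrain_table, gate_table=gate_table)
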