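"""ROC analysis: AUC with DeLong confidence intervals, Youden operating
points, and the paired DeLong test for correlated AUCs.

The AUC is computed as the Mann-Whitney U statistic (ties counted half),
its variance by DeLong's structural-components method, and the paired test
uses the joint covariance of two AUC estimators evaluated on the same
cases.  The operating threshold maximizes Youden's
J = sensitivity + specificity - 1; a score is called positive when it is
at or above the threshold.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "RocCurve",
    "RocReport",
    "DeLongResult",
    "roc_auc",
    "auc_ci_delong",
    "auc_ci_bootstrap",
    "youden",
    "delong_test",
    "roc_report",
    "make_report",
]


def _validate(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return scores, labels


@dataclasses.dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over the distinct scores plus the Mann-Whitney AUC.

    Positive call at threshold t means score >= t; ties between classes
    contribute half a concordant pair.
    """
    scores, labels = _validate(scores, labels)
    pos, neg = scores[labels], scores[~labels]
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))

    thresholds = np.unique(scores)[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / len(pos)
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / len(neg)
    return RocCurve(thresholds, sens, spec, float(auc))


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the V10 (per-positive) and V01 (per-negative) structural
    components."""
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI from the DeLong variance, clipped to [0, 1]."""
    scores, labels = _validate(scores, labels)
    m, n = int(labels.sum()), int((~labels).sum())
    if m < 2 or n < 2:
        raise ValueError("need >= 2 members per class for a DeLong CI")
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        if auc in (0.0, 1.0):
            warnings.warn("degenerate DeLong variance at perfect separation; "
                          "returning a point interval")
        return (auc, auc)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def auc_ci_bootstrap(scores, labels, level: float = 0.95, n_boot: int = 2000,
                     seed: int = 0) -> tuple[float, float]:
    """Stratified percentile-bootstrap alternative to the DeLong CI."""
    scores, labels = _validate(scores, labels)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 11])))
    pos_idx, neg_idx = np.flatnonzero(labels), np.flatnonzero(~labels)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(pos_idx, len(pos_idx)),
                               rng.choice(neg_idx, len(neg_idx))])
        aucs[b] = roc_auc(scores[take], labels[take]).auc
    lo, hi = np.percentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return (float(lo), float(hi))


def youden(curve: RocCurve) -> tuple[float, float, float, float]:
    """(threshold, J, sensitivity, specificity) maximizing J; ties break
    toward higher sensitivity, then lower threshold."""
    if len(curve.thresholds) == 0:
        raise ValueError("empty ROC curve")
    j = curve.sensitivity + curve.specificity - 1.0
    # lexicographic: max J, then max sens, then min threshold; J is
    # quantized so float noise cannot break exact ties like 1 + 2/3 - 1
    jq = np.round(j, 10)
    order = sorted(
        range(len(j)),
        key=lambda i: (-jq[i], -curve.sensitivity[i], curve.thresholds[i]),
    )
    i = order[0]
    return (float(curve.thresholds[i]), float(j[i]),
            float(curve.sensitivity[i]), float(curve.specificity[i]))


@dataclasses.dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    diff: float
    variance: float
    z: float
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for the difference of two correlated AUCs."""
    scores_a, labels = _validate(scores_a, labels)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_b.shape != scores_a.shape:
        raise ValueError("paired design requires equal-length score vectors")
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    s = s10 / m + s01 / n
    var = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, diff, var, float(z), p)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RocReport:
    auc: float
    ci: tuple[float, float]
    youden_threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    curve: RocCurve

    def to_json(self) -> str:
        d = {
            "auc": self.auc, "ci": list(self.ci),
            "youden_threshold": self.youden_threshold, "youden_j": self.youden_j,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }
        return json.dumps(d, indent=2)


def _operating_point_cis(scores, labels, threshold, level=0.95, n_boot=2000, seed=0):
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 13])))
    pos = scores[labels] >= threshold
    neg = scores[~labels] < threshold
    sens_b = rng.choice(pos.astype(float), size=(n_boot, len(pos))).mean(axis=1)
    spec_b = rng.choice(neg.astype(float), size=(n_boot, len(neg))).mean(axis=1)
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    return (tuple(np.percentile(sens_b, q)), tuple(np.percentile(spec_b, q)))


def roc_report(scores, labels, ci_method: str = "delong", n_boot: int = 2000,
               seed: int = 0) -> RocReport:
    scores, labels = _validate(scores, labels)
    curve = roc_auc(scores, labels)
    if ci_method == "delong":
        ci = auc_ci_delong(scores, labels)
    elif ci_method == "bootstrap":
        ci = auc_ci_bootstrap(scores, labels, n_boot=n_boot, seed=seed)
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    thr, j, sens, spec = youden(curve)
    sens_ci, spec_ci = _operating_point_cis(scores, labels, thr,
                                            n_boot=n_boot, seed=seed)
    return RocReport(curve.auc, ci, thr, j, sens, spec, sens_ci, spec_ci,
                     int(labels.sum()), int((~labels).sum()), curve)


def make_report(scores_by_model: dict[str, np.ndarray], labels,
                out: str | Path, n_boot: int = 2000) -> dict[str, Path]:
    """Per-model report JSON + curve CSV, pairwise DeLong table, ROC plot."""
    if not scores_by_model:
        raise ValueError("need at least one model")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels).astype(bool)
    paths: dict[str, Path] = {}

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, scores in scores_by_model.items():
        rep = roc_report(scores, labels, n_boot=n_boot)
        jpath = out / f"{name}_report.json"
        jpath.write_text(rep.to_json())
        pd.DataFrame({
            "threshold": rep.curve.thresholds,
            "sensitivity": rep.curve.sensitivity,
            "specificity": rep.curve.specificity,
        }).to_csv(out / f"{name}_curve.csv", index=False)
        ax.plot(1 - rep.curve.specificity, rep.curve.sensitivity,
                label=f"{name} (AUC {rep.auc:.3f})")
        paths[name] = jpath

    rows = []
    names = list(scores_by_model)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = delong_test(scores_by_model[names[i]],
                              scores_by_model[names[j]], labels)
            rows.append({"model_a": names[i], "model_b": names[j],
                         "auc_a": res.auc_a, "auc_b": res.auc_b,
                         "z": res.z, "p": res.p_value})
    pd.DataFrame(rows, columns=["model_a", "model_b", "auc_a", "auc_b", "z", "p"]
                 ).to_csv(out / "pairwise_delong.csv", index=False)

    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(out / "roc.png", dpi=120)
    plt.close(fig)
    paths["pairwise"] = out / "pairwise_delong.csv"
    return paths
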