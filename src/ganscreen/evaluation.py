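"""Confusion-matrix metrics, threshold sweeps, and hyperparameter ANOVA.

The positive class is OOD throughout (detection target); accuracy,
precision, recall and F1 follow the usual definitions with the documented
zero-denominator convention (precision/recall/F1 = 0 when undefined).
Metrics are kept at full precision internally and rounded to 3 decimals
only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import InversionConfig, detect_from_trajectory, invert_trajectories
from .errors import ValidationError
from .gan import GanModels
from .stats import AnovaResult, anova_oneway
from .synthetic import ImageSample, ViewLabel


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def from_pairs(truth_ood, predicted_ood) -> "ConfusionMatrix":
        t = np.asarray(truth_ood, dtype=bool)
        p = np.asarray(predicted_ood, dtype=bool)
        if t.shape != p.shape:
            raise ValidationError("truth/prediction: length mismatch")
        return ConfusionMatrix(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                               fn=int((~p & t).sum()), tn=int((~p & ~t).sum()))


@dataclass
class MetricsRow:
    hyperparameters: dict = field(default_factory=dict)
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0

    def rounded(self, ndigits: int = 3) -> dict:
        """Reporting form (3 decimals, matching standard results tables)."""
        out = dict(self.hyperparameters)
        for name in ("accuracy", "precision", "recall", "f1"):
            out[name] = round(getattr(self, name), ndigits)
        return out


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValidationError(f"precision/recall: must be in [0, 1], "
                              f"got ({precision}, {recall})")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsRow:
    if cm.total < 1:
        raise ValidationError("confusion matrix: total must be >= 1")
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else 0.0
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else 0.0
    return MetricsRow(accuracy=(cm.tp + cm.tn) / cm.total,
                      precision=precision, recall=recall,
                      f1=f1_from_pr(precision, recall))


def sweep_detector(models: GanModels, test_set: list[ImageSample], taus: list[float],
                   extra_steps: int, base_config: InversionConfig,
                   ood_label: ViewLabel = ViewLabel.LATERAL) -> list[MetricsRow]:
    """One MetricsRow per loss threshold on a labeled test set.

    Latent trajectories are computed once per image (they do not depend on
    tau) and the stopping rule is re-evaluated exactly per threshold, so
    caching cannot change any decision.  ``ood_label`` names the view
    treated as out-of-distribution (the view the model was *not* trained on).
    """
    if not taus:
        return []
    labels = [s.label for s in test_set]
    if ViewLabel.UNKNOWN in labels or len(set(labels)) < 2:
        raise ValidationError("test_set: needs labeled samples of both views")
    trajs = invert_trajectories(models, test_set, base_config)
    rows = []
    for tau in taus:
        cfg = InversionConfig(learning_rate=base_config.learning_rate,
                              loss_threshold=tau, extra_steps=extra_steps,
                              max_steps=base_config.max_steps, alpha=base_config.alpha,
                              z_seed=base_config.z_seed, restarts=base_config.restarts)
        preds, truths = [], []
        for x, tj in zip(test_set, trajs):
            d = detect_from_trajectory(models, x, tj, cfg)
            preds.append(d.is_ood)
            truths.append(x.label is ood_label)
        row = metrics_from_confusion(ConfusionMatrix.from_pairs(truths, preds))
        row.hyperparameters = {"loss_threshold": tau, "extra_steps": extra_steps}
        rows.append(row)
    return rows


def anova_over_replicates(accuracy_table: dict) -> AnovaResult:
    """One-way ANOVA over per-setting replicate accuracies.

    With 5 settings x 3 replicates the degrees of freedom are (4, 10).
    """
    if len(accuracy_table) < 2:
        raise ValidationError("accuracy_table: need >= 2 settings")
    return anova_oneway([accuracy_table[k] for k in sorted(accuracy_table, key=str)])
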