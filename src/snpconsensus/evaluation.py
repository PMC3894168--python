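"""Performance metrics: coverage, normalized accuracy/MCC, AUC, phi.

Benchmark class balance varies between datasets, so accuracy and MCC are
computed on a class-normalized confusion matrix: each true-class row is
rescaled to carry half the total mass.  This leaves sensitivity and
specificity untouched and turns plain accuracy into balanced accuracy.
AUC is the rank (Mann-Whitney) statistic and is unaffected by the
reweighting, so it is computed once on the raw scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr, rankdata
from sklearn.metrics import roc_curve

from .errors import NormalizationError, SnpConsensusError
from .records import (
    AMINO_ACIDS,
    DELETERIOUS,
    NEUTRAL,
    UNKNOWN,
    EvaluationReport,
    MutationKey,
    MutationRecord,
    ToolPrediction,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 confusion counts; deleterious is the positive class.

    Entries are reals because class normalization reweights the counts.
    """

    tp: float
    tn: float
    fp: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise SnpConsensusError("confusion entries must be >= 0")
        if self.total <= 0:
            raise SnpConsensusError("confusion matrix is empty")

    @property
    def total(self) -> float:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_from_calls(
    predicted: Mapping[MutationKey, str],
    labels: Mapping[MutationKey, str],
) -> ConfusionMatrix:
    """Count the 2x2 table over keys that are both labeled and predicted."""
    tp = tn = fp = fn = 0
    for key, cls in predicted.items():
        label = labels.get(key)
        if label is None or label == UNKNOWN:
            continue
        if label == DELETERIOUS:
            if cls == DELETERIOUS:
                tp += 1
            else:
                fn += 1
        else:
            if cls == NEUTRAL:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def coverage(
    predictions: Sequence[ToolPrediction],
    mutations: Sequence[MutationRecord],
) -> float:
    """Fraction of mutations with a non-missing prediction."""
    if not mutations:
        raise SnpConsensusError("coverage of an empty mutation set")
    covered = {p.key for p in predictions if not p.is_missing}
    return sum(m.key in covered for m in mutations) / len(mutations)


def normalize(cm: ConfusionMatrix) -> ConfusionMatrix:
    """Rescale each true-class row to half the total mass.

    Class-conditional rates (sensitivity, specificity) are preserved;
    accuracy of the result equals (sensitivity + specificity) / 2.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0 or neg == 0:
        raise NormalizationError(
            "both true classes must be present to normalize"
        )
    half = cm.total / 2.0
    return ConfusionMatrix(
        tp=cm.tp * half / pos,
        fn=cm.fn * half / pos,
        tn=cm.tn * half / neg,
        fp=cm.fp * half / neg,
    )


def accuracy(cm: ConfusionMatrix) -> float:
    return (cm.tp + cm.tn) / cm.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when a marginal vanishes."""
    denom = (
        (cm.tp + cm.fp)
        * (cm.tp + cm.fn)
        * (cm.tn + cm.fp)
        * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Rank AUC with mid-rank tie handling, plus the ROC curve.

    Higher score must mean more deleterious.  Returns
    (auc, false-positive rates, true-positive rates); the curve has a point
    at every distinct threshold.  The AUC equals the Mann-Whitney
    probability P(score_pos > score_neg) + 0.5 * P(tie).
    """
    y = np.array([lab == DELETERIOUS for lab in labels], dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise SnpConsensusError("AUC requires both classes present")
    ranks = rankdata(s)  # mid-ranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y, s)
    return float(auc), fpr, tpr


def pairwise_tool_correlation(
    preds_a: Sequence[ToolPrediction],
    preds_b: Sequence[ToolPrediction],
) -> float:
    """Phi coefficient of two tools' class calls over shared mutations.

    Phi is the Pearson correlation of the binary call vectors (deleterious
    = 1) restricted to mutations both tools evaluated.  Returns NaN when a
    tool is constant on the shared set (correlation undefined).
    """
    a = {p.key: p.predicted_class for p in preds_a if not p.is_missing}
    b = {p.key: p.predicted_class for p in preds_b if not p.is_missing}
    shared = sorted(set(a) & set(b))
    if len(shared) < 2:
        raise SnpConsensusError(
            "phi requires >= 2 mutations predicted by both tools"
        )
    x = np.array([a[k] == DELETERIOUS for k in shared], dtype=float)
    y = np.array([b[k] == DELETERIOUS for k in shared], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def aa_distribution_bias(
    mutations: Sequence[MutationRecord],
    expected_freqs: Mapping[str, float],
) -> dict:
    """Compare wild-type/mutant residue usage against expected frequencies.

    Tallies observed counts of the 20 residues separately for the wild-type
    and mutant positions, sets expected counts to ``freq * n``, and reports
    the Pearson correlation over the 40 pooled observed/expected pairs plus
    per-residue fold deviations (observed / expected).
    """
    if not mutations:
        raise SnpConsensusError("empty dataset")
    total = sum(expected_freqs.get(aa, 0.0) for aa in AMINO_ACIDS)
    if abs(total - 1.0) > 1e-6:
        raise SnpConsensusError(
            f"expected frequencies must sum to 1, got {total}"
        )
    n = len(mutations)
    wt_obs = {aa: 0 for aa in AMINO_ACIDS}
    mut_obs = {aa: 0 for aa in AMINO_ACIDS}
    for m in mutations:
        wt_obs[m.wt_aa] += 1
        mut_obs[m.mut_aa] += 1
    expected = {aa: expected_freqs[aa] * n for aa in AMINO_ACIDS}
    obs = np.array(
        [wt_obs[aa] for aa in AMINO_ACIDS]
        + [mut_obs[aa] for aa in AMINO_ACIDS],
        dtype=float,
    )
    exp = np.array([expected[aa] for aa in AMINO_ACIDS] * 2)
    if obs.std() == 0 or exp.std() == 0:
        # constant vectors: correlation is defined only by agreement
        r = 1.0 if np.allclose(obs, exp) else float("nan")
    else:
        r = float(pearsonr(obs, exp).statistic)
    fold = {
        aa: {
            "wt": wt_obs[aa] / expected[aa] if expected[aa] else math.inf,
            "mut": mut_obs[aa] / expected[aa] if expected[aa] else math.inf,
        }
        for aa in AMINO_ACIDS
    }
    return {
        "observed_wt": wt_obs,
        "observed_mut": mut_obs,
        "expected": expected,
        "pearson_r": r,
        "fold": fold,
    }


def tool_signed_scores(
    predictions: Sequence[ToolPrediction], model
) -> dict[MutationKey, float]:
    """Deleteriousness scores for one tool: sign * calibrated confidence.

    Orients every tool's raw scale the same way (higher = more
    deleterious) through its calibrated per-class curves, so ROC analysis
    is comparable across tools regardless of native score direction.
    """
    from .calibration import transform
    from .consensus import prediction_sign

    scores = {}
    for p in predictions:
        if p.is_missing:
            continue
        c = transform(model, p.tool, p.predicted_class, p.raw_confidence)
        scores[p.key] = prediction_sign(p.predicted_class) * c
    return scores


def evaluate(
    predicted: Mapping[MutationKey, str],
    scores: Mapping[MutationKey, float] | None,
    mutations: Sequence[MutationRecord],
) -> EvaluationReport:
    """Full report for one predictor: coverage + normalized metrics.

    ``predicted`` maps evaluated mutation keys to class calls (missing
    mutations are simply absent); ``scores`` optionally maps keys to a
    deleteriousness score for the AUC (NaN when omitted).  Metrics are
    computed only over mutations the predictor evaluated.
    """
    if not mutations:
        raise SnpConsensusError("empty mutation set")
    cov = sum(m.key in predicted for m in mutations) / len(mutations)
    labels = {m.key: m.label for m in mutations if m.label != UNKNOWN}
    cm = confusion_from_calls(predicted, labels)
    norm = normalize(cm)
    if scores is not None:
        keys = [k for k in labels if k in scores and k in predicted]
        auc, _, _ = roc_auc(
            [scores[k] for k in keys], [labels[k] for k in keys]
        )
    else:
        auc = float("nan")
    return EvaluationReport(
        coverage=cov,
        tp=cm.tp,
        tn=cm.tn,
        fp=cm.fp,
        fn=cm.fn,
        accuracy_norm=accuracy(norm),
        mcc_norm=mcc(norm),
        auc=auc,
        n_neutral=sum(
            1 for k in predicted if labels.get(k) == NEUTRAL
        ),
        n_deleterious=sum(
            1 for k in predicted if labels.get(k) == DELETERIOUS
        ),
    )
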