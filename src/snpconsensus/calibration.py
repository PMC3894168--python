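"""Calibration of raw tool confidences to observed accuracy.

Every constituent tool reports confidence on its own scale, continuous or
categorical.  To make them comparable, each tool's confidences are mapped
onto the observed accuracy — the empirical fraction of correct predictions
among benchmark mutations at that confidence level — fitted separately per
predicted class, because the confidence/accuracy relationship generally
differs between neutral and deleterious calls.

Categorical tools: observed accuracy is counted per category token within
each predicted-class stratum.

Continuous tools: labeled predictions are sorted by raw confidence,
partitioned into equal-count bins (60 by default), the per-bin accuracy is
smoothed with a centered moving average over five neighbouring bins, and
each bin is represented by the mean raw confidence of its members.
Evaluation interpolates linearly between bin representatives and clamps
outside the fitted range.  The consensus score itself is calibrated the same
way, using |score| as the continuous confidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CalibrationDomainError, FitError, FormatError
from .records import (
    CATEGORICAL,
    CLASSES,
    CONSENSUS_TOOL,
    CONTINUOUS,
    CalibrationModel,
    CategoricalEntry,
    CurveEntry,
    MutationKey,
    MutationRecord,
    ToolPrediction,
    labels_by_key,
)


@dataclass(frozen=True)
class BinSpec:
    """Binning parameters for continuous calibration.

    n_bins: number of equal-count bins the sorted confidences are split into.
    smooth_window: width of the centered moving average, in bins (odd).
    min_per_bin: bins are reduced so each holds at least this many records.
    """

    n_bins: int = 60
    smooth_window: int = 5
    min_per_bin: int = 5

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.min_per_bin < 1:
            raise ValueError("min_per_bin must be >= 1")


def _labeled_stratum(
    predictions: Iterable[ToolPrediction],
    labels: Mapping[MutationKey, str],
    predicted_class: str,
) -> list[tuple[ToolPrediction, bool]]:
    """Pairs (prediction, correct?) for one predicted-class stratum."""
    out = []
    for p in predictions:
        if p.is_missing or p.predicted_class != predicted_class:
            continue
        label = labels.get(p.key)
        if label is None:
            continue
        out.append((p, p.predicted_class == label))
    return out


def fit_categorical(
    predictions: Sequence[ToolPrediction],
    labels: Mapping[MutationKey, str],
    predicted_class: str,
) -> CategoricalEntry:
    """Observed accuracy per category token within one class stratum."""
    stratum = _labeled_stratum(predictions, labels, predicted_class)
    if not stratum:
        tool = predictions[0].tool if predictions else "?"
        raise FitError(
            f"no labeled records for tool {tool!r}, class {predicted_class!r}"
        )
    counts: dict[str, int] = {}
    correct: dict[str, int] = {}
    for p, ok in stratum:
        token = str(p.raw_confidence)
        counts[token] = counts.get(token, 0) + 1
        correct[token] = correct.get(token, 0) + int(ok)
    category_map = {t: correct[t] / counts[t] for t in counts}
    return CategoricalEntry(category_map=category_map, n_records=len(stratum))


def _smooth(raw: np.ndarray, window: int, weights: np.ndarray) -> np.ndarray:
    """Centered moving average with edge truncation, weighted by bin size."""
    half = window // 2
    n = len(raw)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = weights[lo:hi]
        out[i] = float(np.average(raw[lo:hi], weights=w))
    return out


def fit_continuous(
    predictions: Sequence[ToolPrediction],
    labels: Mapping[MutationKey, str],
    predicted_class: str,
    spec: BinSpec = BinSpec(),
) -> CurveEntry:
    """Fit the binned calibration curve for one continuous-class stratum.

    Records are sorted ascending by raw confidence (ties broken by mutation
    key for reproducibility) and split into equal-count bins; when the count
    does not divide evenly the first ``n % bins`` bins take one extra
    record.  If the stratum is small the bin count is reduced to
    ``min(n_bins, n // min_per_bin)`` (at least 1) rather than failing.
    """
    stratum = _labeled_stratum(predictions, labels, predicted_class)
    if not stratum:
        tool = predictions[0].tool if predictions else "?"
        raise FitError(
            f"no labeled records for tool {tool!r}, class {predicted_class!r}"
        )
    for p, _ in stratum:
        if not isinstance(p.raw_confidence, (int, float)):
            raise FormatError(
                f"tool {p.tool!r} has non-numeric confidence "
                f"{p.raw_confidence!r} in a continuous fit"
            )
    stratum.sort(key=lambda pair: (float(pair[0].raw_confidence), pair[0].key))
    conf = np.array([float(p.raw_confidence) for p, _ in stratum])
    ok = np.array([c for _, c in stratum], dtype=float)

    n = len(stratum)
    bins = max(1, min(spec.n_bins, n // spec.min_per_bin))
    base, extra = divmod(n, bins)
    edges = np.zeros(bins + 1, dtype=int)
    sizes = np.full(bins, base)
    sizes[:extra] += 1
    np.cumsum(sizes, out=edges[1:])

    reps, raw_acc, counts = [], [], []
    for b in range(bins):
        lo, hi = edges[b], edges[b + 1]
        reps.append(float(conf[lo:hi].mean()))
        raw_acc.append(float(ok[lo:hi].mean()))
        counts.append(int(hi - lo))

    # Mass ties in raw confidence can make adjacent bins share a
    # representative; merge them (count-weighted) to keep the curve a
    # function of confidence.
    m_reps, m_acc, m_cnt = [reps[0]], [raw_acc[0]], [counts[0]]
    for r, a, c in zip(reps[1:], raw_acc[1:], counts[1:]):
        if r == m_reps[-1]:
            tot = m_cnt[-1] + c
            m_acc[-1] = (m_acc[-1] * m_cnt[-1] + a * c) / tot
            m_cnt[-1] = tot
        else:
            m_reps.append(r)
            m_acc.append(a)
            m_cnt.append(c)

    smoothed = _smooth(
        np.array(m_acc), spec.smooth_window, np.array(m_cnt, dtype=float)
    )
    return CurveEntry(
        representatives=tuple(m_reps),
        accuracies=tuple(np.clip(smoothed, 0.0, 1.0)),
        n_bins=len(m_reps),
        smooth_window=spec.smooth_window,
        n_records=n,
    )


def fit_tool(
    predictions: Sequence[ToolPrediction],
    labels: Mapping[MutationKey, str],
    spec: BinSpec = BinSpec(),
) -> dict[tuple[str, str], CategoricalEntry | CurveEntry]:
    """Fit both class strata of one tool, choosing the fit by score kind."""
    present = [p for p in predictions if not p.is_missing]
    if not present:
        raise FitError("tool has no non-missing predictions")
    tool = present[0].tool
    kind = present[0].score_kind
    entries: dict[tuple[str, str], CategoricalEntry | CurveEntry] = {}
    for cls in CLASSES:
        stratum_exists = any(
            p.predicted_class == cls and labels.get(p.key) is not None
            for p in present
        )
        if not stratum_exists:
            continue
        if kind == CATEGORICAL:
            entries[(tool, cls)] = fit_categorical(present, labels, cls)
        else:
            entries[(tool, cls)] = fit_continuous(present, labels, cls, spec)
    if not entries:
        raise FitError(f"no labeled records for tool {tool!r}")
    return entries


def fit_calibration(
    predictions: Sequence[ToolPrediction],
    mutations: Sequence[MutationRecord],
    spec: BinSpec = BinSpec(),
) -> CalibrationModel:
    """Fit calibration entries for every tool present in ``predictions``."""
    labels = labels_by_key(mutations)
    by_tool: dict[str, list[ToolPrediction]] = {}
    for p in predictions:
        by_tool.setdefault(p.tool, []).append(p)
    model = CalibrationModel()
    for tool in sorted(by_tool):
        model.entries.update(fit_tool(by_tool[tool], labels, spec))
    return model


def transform(
    model: CalibrationModel,
    tool: str,
    predicted_class: str,
    raw_confidence: float | str,
) -> float:
    """Map a raw confidence to calibrated observed accuracy in [0, 1].

    Categorical entries are exact lookups; curve entries interpolate
    linearly between bin representatives, clamping to the terminal bin
    values outside the fitted range.
    """
    entry = model.entry(tool, predicted_class)
    if isinstance(entry, CategoricalEntry):
        token = str(raw_confidence)
        try:
            return entry.category_map[token]
        except KeyError:
            raise CalibrationDomainError(
                f"category {token!r} never fitted for tool {tool!r}, "
                f"class {predicted_class!r}"
            ) from None
    value = float(raw_confidence)
    return float(
        np.interp(value, entry.representatives, entry.accuracies)
    )


def fit_consensus_calibration(
    results,
    mutations: Sequence[MutationRecord],
    spec: BinSpec = BinSpec(),
) -> dict[tuple[str, str], CurveEntry]:
    """Calibrate the consensus score exactly like a continuous tool.

    |score| plays the role of the raw confidence; the fit is stratified by
    the consensus class call.  Returns entries keyed under the pseudo-tool
    ``"consensus"``, to be merged into a :class:`CalibrationModel`.
    """
    pseudo = [
        ToolPrediction(
            protein_id=r.key[0],
            position=r.key[1],
            wt_aa=r.key[2],
            mut_aa=r.key[3],
            tool=CONSENSUS_TOOL,
            predicted_class=r.predicted_class,
            raw_confidence=abs(r.score),
            score_kind=CONTINUOUS,
        )
        for r in results
    ]
    labels = labels_by_key(mutations)
    entries: dict[tuple[str, str], CurveEntry] = {}
    for cls in CLASSES:
        if any(
            p.predicted_class == cls and labels.get(p.key) is not None
            for p in pseudo
        ):
            entries[(CONSENSUS_TOOL, cls)] = fit_continuous(
                pseudo, labels, cls, spec
            )
    if not entries:
        raise FitError("no labeled consensus results to calibrate")
    return entries
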