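"""Domain types for consensus variant-effect prediction.

The unit of analysis is a single amino-acid substitution
(:class:`MutationRecord`).  Each constituent predictor contributes a
:class:`ToolPrediction` — a binary class call (neutral / deleterious) plus a
raw confidence on the tool's own scale, either continuous or categorical.
Calibration maps raw confidences onto one comparable scale, the observed
accuracy, stored in a :class:`CalibrationModel`; the weighted majority vote
produces a :class:`ConsensusResult` with a signed score in [-1, +1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NEUTRAL = "neutral"
DELETERIOUS = "deleterious"
UNKNOWN = "unknown"
MISSING = "missing"

CLASSES = (NEUTRAL, DELETERIOUS)
LABELS = (NEUTRAL, DELETERIOUS, UNKNOWN)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Key identifying one substitution: (protein_id, position, wt_aa, mut_aa).
MutationKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class MutationRecord:
    """One amino-acid substitution with an optional functional label.

    Positions are 1-based residue indices, following standard mutation
    nomenclature (e.g. p.R117H is position 117).
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    label: str = UNKNOWN
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"position must be >= 1, got {self.position} "
                f"({self.protein_id})"
            )
        for name, aa in (("wt_aa", self.wt_aa), ("mut_aa", self.mut_aa)):
            if aa not in AMINO_ACIDS or len(aa) != 1:
                raise ValidationError(
                    f"{name} must be a standard one-letter amino-acid code, "
                    f"got {aa!r} ({self.protein_id}:{self.position})"
                )
        if self.wt_aa == self.mut_aa:
            raise ValidationError(
                f"wild-type and mutant residues are identical "
                f"({self.protein_id}:{self.position}{self.wt_aa})"
            )
        if self.label not in LABELS:
            raise ValidationError(
                f"label must be one of {LABELS}, got {self.label!r}"
            )

    @property
    def key(self) -> MutationKey:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    def check_sequence(self, sequence: str) -> None:
        """Raise unless the residue at ``position`` in ``sequence`` is wt_aa."""
        if self.position > len(sequence):
            raise ValidationError(
                f"position {self.position} beyond sequence of length "
                f"{len(sequence)} ({self.protein_id})"
            )
        found = sequence[self.position - 1]
        if found != self.wt_aa:
            raise ValidationError(
                f"sequence {self.protein_id} has {found} at position "
                f"{self.position}, record claims {self.wt_aa}"
            )


RawConfidence = Union[float, str, None]


@dataclass(frozen=True)
class ToolPrediction:
    """One tool's class call and raw confidence for one mutation.

    ``predicted_class == "missing"`` encodes the tool returning no result;
    in that case ``raw_confidence`` must be absent (None), and vice versa.
    ``score_kind`` states whether the tool reports confidence on a continuous
    numeric scale or as categorical tokens; it is constant per tool.
    """

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    tool: str
    predicted_class: str
    raw_confidence: RawConfidence
    score_kind: str

    def __post_init__(self) -> None:
        if self.predicted_class not in (NEUTRAL, DELETERIOUS, MISSING):
            raise ValidationError(
                f"predicted_class must be neutral/deleterious/missing, "
                f"got {self.predicted_class!r}"
            )
        if (self.predicted_class == MISSING) != (self.raw_confidence is None):
            raise ValidationError(
                "raw_confidence must be absent exactly when the prediction "
                f"is missing ({self.tool} @ {self.protein_id}:{self.position})"
            )
        if self.score_kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(
                f"score_kind must be continuous or categorical, "
                f"got {self.score_kind!r}"
            )
        if (
            self.score_kind == CONTINUOUS
            and self.raw_confidence is not None
            and not isinstance(self.raw_confidence, (int, float))
        ):
            raise ValidationError(
                f"continuous tool {self.tool} has non-numeric confidence "
                f"{self.raw_confidence!r}"
            )

    @property
    def key(self) -> MutationKey:
        return (self.protein_id, self.position, self.wt_aa, self.mut_aa)

    @property
    def is_missing(self) -> bool:
        return self.predicted_class == MISSING


@dataclass(frozen=True)
class CategoricalEntry:
    """Per-category observed accuracy for one (tool, predicted class)."""

    category_map: Mapping[str, float]
    n_records: int

    def __post_init__(self) -> None:
        for token, acc in self.category_map.items():
            if not 0.0 <= acc <= 1.0:
                raise ValidationError(
                    f"observed accuracy for category {token!r} outside "
                    f"[0, 1]: {acc}"
                )


@dataclass(frozen=True)
class CurveEntry:
    """Binned calibration curve for one (tool, predicted class).

    ``representatives`` are the mean raw confidences of each equal-count
    bin (strictly increasing); ``accuracies`` are the smoothed observed
    accuracies of those bins.
    """

    representatives: tuple[float, ...]
    accuracies: tuple[float, ...]
    n_bins: int
    smooth_window: int
    n_records: int

    def __post_init__(self) -> None:
        if len(self.representatives) != len(self.accuracies):
            raise ValidationError("curve arrays differ in length")
        if not self.representatives:
            raise ValidationError("curve must contain at least one bin")
        for a, b in zip(self.representatives, self.representatives[1:]):
            if not a < b:
                raise ValidationError(
                    "representative confidences must be strictly increasing"
                )
        for acc in self.accuracies:
            if not 0.0 <= acc <= 1.0:
                raise ValidationError(f"accuracy outside [0, 1]: {acc}")


CalibrationEntry = Union[CategoricalEntry, CurveEntry]

#: Name of the pseudo-tool under which the consensus score is calibrated.
CONSENSUS_TOOL = "consensus"


@dataclass
class CalibrationModel:
    """Per (tool, predicted_class) mapping from raw confidence to accuracy."""

    entries: dict[tuple[str, str], CalibrationEntry] = field(
        default_factory=dict
    )

    def entry(self, tool: str, predicted_class: str) -> CalibrationEntry:
        from .errors import CalibrationDomainError

        try:
            return self.entries[(tool, predicted_class)]
        except KeyError:
            raise CalibrationDomainError(
                f"no calibration fitted for tool {tool!r}, "
                f"class {predicted_class!r}"
            ) from None

    @property
    def tools(self) -> list[str]:
        return sorted({tool for tool, _ in self.entries})


@dataclass(frozen=True)
class Contribution:
    """One tool's term in the consensus sum: sign * calibrated confidence."""

    tool: str
    sign: int  # +1 deleterious, -1 neutral
    confidence: float  # calibrated observed accuracy in [0, 1]


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus score, class call and calibrated consensus confidence."""

    key: MutationKey
    score: float
    predicted_class: str
    consensus_confidence: float | None
    n_tools_used: int
    contributions: tuple[Contribution, ...]

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise ValidationError(f"score outside [-1, +1]: {self.score}")


@dataclass(frozen=True)
class EvaluationReport:
    """Coverage plus normalized performance metrics for one predictor."""

    coverage: float
    tp: float
    tn: float
    fp: float
    fn: float
    accuracy_norm: float
    mcc_norm: float
    auc: float
    n_neutral: int
    n_deleterious: int


def labels_by_key(
    mutations: Sequence[MutationRecord],
) -> dict[MutationKey, str]:
    """Map mutation keys to labels, dropping unlabeled records."""
    return {m.key: m.label for m in mutations if m.label != UNKNOWN}
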