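"""Readers and writers for mutation/prediction tables, FASTA and models.

Tables are tab-separated with a mandatory header (free-text protein ids make
other delimiters ambiguous).  Readers validate every row against the domain
invariants and reject offending rows with their 1-based data-row number.
Calibration models persist to a JSON document with a schema version; the
round trip is exact because JSON serialises Python floats via their shortest
faithful repr.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

from .errors import FormatError, ValidationError
from .records import (
    CATEGORICAL,
    CONTINUOUS,
    DELETERIOUS,
    MISSING,
    NEUTRAL,
    UNKNOWN,
    CalibrationModel,
    CategoricalEntry,
    CurveEntry,
    MutationRecord,
    ToolPrediction,
)

MUTATION_COLUMNS = ("protein_id", "position", "wt_aa", "mut_aa", "label", "source")
PREDICTION_COLUMNS = (
    "protein_id",
    "position",
    "wt_aa",
    "mut_aa",
    "tool",
    "predicted_class",
    "raw_confidence",
    "score_kind",
)

CALIBRATION_SCHEMA_VERSION = 1


def _open_rows(path: str | Path, delimiter: str, required: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such table: {path}")
    handle = path.open(newline="")
    reader = csv.DictReader(handle, delimiter=delimiter)
    header = reader.fieldnames or []
    missing = [c for c in required if c not in header]
    if missing:
        handle.close()
        raise FormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return handle, reader


def read_mutation_table(
    path: str | Path, delimiter: str = "\t"
) -> list[MutationRecord]:
    """Read a mutation TSV into validated :class:`MutationRecord` objects.

    The ``label`` and ``source`` columns are optional; absent labels become
    ``unknown``.  Rows violating any invariant raise ``ValidationError``
    naming the offending data row.
    """
    required = ("protein_id", "position", "wt_aa", "mut_aa")
    handle, reader = _open_rows(path, delimiter, required)
    records: list[MutationRecord] = []
    try:
        for rownum, row in enumerate(reader, start=1):
            try:
                position = int(row["position"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path} row {rownum}: position {row.get('position')!r} "
                    "is not an integer"
                ) from None
            try:
                records.append(
                    MutationRecord(
                        protein_id=row["protein_id"],
                        position=position,
                        wt_aa=row["wt_aa"],
                        mut_aa=row["mut_aa"],
                        label=row.get("label") or UNKNOWN,
                        source=row.get("source") or "",
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path} row {rownum}: {exc}") from None
    finally:
        handle.close()
    return records


def write_mutation_table(
    records: Iterable[MutationRecord],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(MUTATION_COLUMNS)
        for r in records:
            writer.writerow(
                (r.protein_id, r.position, r.wt_aa, r.mut_aa, r.label, r.source)
            )


def read_prediction_table(
    path: str | Path, delimiter: str = "\t"
) -> list[ToolPrediction]:
    """Read a per-tool prediction TSV.

    Rows with an empty class and empty confidence encode missing
    predictions.  A tool mixing continuous and categorical score kinds is a
    format error: the kind is a property of the tool, not of the row.
    """
    handle, reader = _open_rows(path, delimiter, PREDICTION_COLUMNS)
    predictions: list[ToolPrediction] = []
    kinds: dict[str, str] = {}
    try:
        for rownum, row in enumerate(reader, start=1):
            tool = row["tool"]
            kind = row["score_kind"]
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise FormatError(
                    f"{path} row {rownum}: score_kind {kind!r} must be "
                    f"'{CONTINUOUS}' or '{CATEGORICAL}'"
                )
            if kinds.setdefault(tool, kind) != kind:
                raise FormatError(
                    f"{path} row {rownum}: tool {tool!r} mixes score kinds "
                    f"({kinds[tool]} and {kind})"
                )
            cls = row["predicted_class"] or ""
            raw_field = row["raw_confidence"] or ""
            if cls == "" and raw_field == "":
                cls, raw = MISSING, None
            elif cls == MISSING:
                raw = None
            else:
                raw = float(raw_field) if kind == CONTINUOUS else raw_field
            try:
                position = int(row["position"])
                predictions.append(
                    ToolPrediction(
                        protein_id=row["protein_id"],
                        position=position,
                        wt_aa=row["wt_aa"],
                        mut_aa=row["mut_aa"],
                        tool=tool,
                        predicted_class=cls,
                        raw_confidence=raw,
                        score_kind=kind,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} row {rownum}: {exc}") from None
    finally:
        handle.close()
    return predictions


def write_prediction_table(
    predictions: Iterable[ToolPrediction],
    path: str | Path,
    delimiter: str = "\t",
) -> None:
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for p in predictions:
            cls = "" if p.is_missing else p.predicted_class
            if p.raw_confidence is None:
                raw = ""
            elif p.score_kind == CONTINUOUS:
                raw = repr(float(p.raw_confidence))
            else:
                raw = p.raw_confidence
            writer.writerow(
                (
                    p.protein_id,
                    p.position,
                    p.wt_aa,
                    p.mut_aa,
                    p.tool,
                    cls,
                    raw,
                    p.score_kind,
                )
            )


class Pph1Coercion(NamedTuple):
    predicted_class: str
    raw_confidence: str


#: Raw-confidence anchor of the coerced "possibly deleterious" category on
#: the tool's own 0-1 scale.
PPH1_POSSIBLY_DELETERIOUS_ANCHOR = 0.5

_PPH1_CLASSES = (NEUTRAL, "possibly deleterious", DELETERIOUS)


def coerce_pph1(class_token: str, raw: str) -> Pph1Coercion:
    """Fold PolyPhen-1's three-class output onto the binary scheme.

    PolyPhen-1 emits neutral / possibly deleterious / deleterious.  The
    middle class is treated as deleterious with a raw confidence of 0.5 on
    the tool's own scale; it becomes the categorical token ``"0.5"`` so
    categorical calibration measures its observed accuracy like any other
    category.  The outer two classes pass through with their own tokens.
    """
    if class_token not in _PPH1_CLASSES:
        raise FormatError(
            f"unknown PolyPhen-1 class {class_token!r}; "
            f"expected one of {_PPH1_CLASSES}"
        )
    if class_token == "possibly deleterious":
        return Pph1Coercion(DELETERIOUS, str(PPH1_POSSIBLY_DELETERIOUS_ANCHOR))
    return Pph1Coercion(class_token, raw)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                handle.write(seq[i : i + 60] + "\n")


def _entry_to_json(entry) -> dict:
    if isinstance(entry, CategoricalEntry):
        return {
            "kind": "categorical",
            "category_map": dict(entry.category_map),
            "n_records": entry.n_records,
        }
    return {
        "kind": "curve",
        "representatives": list(entry.representatives),
        "accuracies": list(entry.accuracies),
        "n_bins": entry.n_bins,
        "smooth_window": entry.smooth_window,
        "n_records": entry.n_records,
    }


def _entry_from_json(obj: dict):
    if obj["kind"] == "categorical":
        return CategoricalEntry(
            category_map=dict(obj["category_map"]),
            n_records=int(obj["n_records"]),
        )
    if obj["kind"] == "curve":
        return CurveEntry(
            representatives=tuple(float(x) for x in obj["representatives"]),
            accuracies=tuple(float(x) for x in obj["accuracies"]),
            n_bins=int(obj["n_bins"]),
            smooth_window=int(obj["smooth_window"]),
            n_records=int(obj["n_records"]),
        )
    raise FormatError(f"unknown calibration entry kind {obj.get('kind')!r}")


def persist_calibration(model: CalibrationModel, path: str | Path) -> None:
    """Write a calibration model as a versioned JSON document."""
    doc = {
        "schema_version": CALIBRATION_SCHEMA_VERSION,
        "entries": [
            {
                "tool": tool,
                "predicted_class": cls,
                **_entry_to_json(entry),
            }
            for (tool, cls), entry in sorted(model.entries.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_calibration(path: str | Path) -> CalibrationModel:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such calibration model: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupted calibration model {path}: {exc}") from None
    if not isinstance(doc, dict) or "entries" not in doc:
        raise FormatError(f"{path}: not a calibration model document")
    version = doc.get("schema_version")
    if version != CALIBRATION_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema version {version!r}"
        )
    model = CalibrationModel()
    for obj in doc["entries"]:
        model.entries[(obj["tool"], obj["predicted_class"])] = _entry_from_json(
            obj
        )
    return model


def write_results_table(results, path: str | Path, delimiter: str = "\t") -> None:
    """Write consensus results with per-tool contribution columns."""
    tools = sorted(
        {c.tool for r in results for c in r.contributions}
    )
    header = [
        "protein_id",
        "position",
        "wt_aa",
        "mut_aa",
        "score",
        "predicted_class",
        "consensus_confidence",
        "n_tools_used",
    ]
    for tool in tools:
        header += [f"{tool}_class", f"{tool}_confidence"]
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        for r in results:
            conf = (
                ""
                if r.consensus_confidence is None
                or math.isnan(r.consensus_confidence)
                else repr(r.consensus_confidence)
            )
            row = list(r.key) + [
                repr(r.score),
                r.predicted_class,
                conf,
                r.n_tools_used,
            ]
            by_tool = {c.tool: c for c in r.contributions}
            for tool in tools:
                c = by_tool.get(tool)
                if c is None:
                    row += [MISSING, ""]
                else:
                    row += [
                        DELETERIOUS if c.sign > 0 else NEUTRAL,
                        repr(c.confidence),
                    ]
            writer.writerow(row)
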