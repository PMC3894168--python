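"""Construction of independence-guaranteed benchmark datasets.

Benchmark leakage — mutations (or homologous positions) shared between a
predictor's training set and the benchmark — inflates measured performance.
The builder removes it in stages: purge mutations with conflicting
neutral/deleterious annotations across sources, drop exact duplicates, then
remove every mutation whose position maps, through a sufficiently
significant and identical alignment fragment, to a position mutated in a
reference (training or held-out) set.

Alignments come from a pluggable fragment producer: either an adapter over
standard 12-column BLAST tabular output, or a built-in Smith-Waterman
aligner (BLOSUM62, gap open 11 / extend 1) suitable for desk-scale inputs,
where a minimum aligned-fragment length stands in for the e-value cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FormatError, SnpConsensusError, ValidationError
from .records import DELETERIOUS, NEUTRAL, MutationKey, MutationRecord

#: (protein_id, 1-based residue position)
Position = tuple[str, int]


@dataclass(frozen=True)
class AlignedFragmentPair:
    """A local alignment fragment between a query and subject sequence.

    ``column_map`` pairs aligned residue positions (1-based, non-gap on
    both sides).  ``identity`` is matched columns over total alignment
    columns (gaps included).
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    column_map: tuple[tuple[int, int], ...]
    identity: float
    evalue: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValidationError(f"identity outside [0, 1]: {self.identity}")
        if self.evalue < 0:
            raise ValidationError(f"negative e-value: {self.evalue}")
        for q, s in self.column_map:
            if not (self.query_start <= q <= self.query_end):
                raise ValidationError(
                    f"mapped query position {q} outside fragment range"
                )
            if not (self.subject_start <= s <= self.subject_end):
                raise ValidationError(
                    f"mapped subject position {s} outside fragment range"
                )


@dataclass(frozen=True)
class OverlapSpec:
    """Thresholds defining when an alignment fragment transmits overlap."""

    max_evalue: float = 1e-10
    min_identity: float = 0.5

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValidationError("max_evalue must be > 0")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValidationError("min_identity must be in [0, 1]")


class FragmentProducer(Protocol):
    def __call__(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> Iterable[AlignedFragmentPair]: ...


def purge_conflicts(
    records: Sequence[MutationRecord],
) -> list[MutationRecord]:
    """Drop every record of any mutation labeled both neutral and deleterious.

    A mutation annotated deleterious in one source but neutral in another is
    unusable as ground truth, so all of its records are removed.
    """
    labels: dict[MutationKey, set[str]] = {}
    for r in records:
        labels.setdefault(r.key, set()).add(r.label)
    conflicted = {
        key
        for key, labs in labels.items()
        if NEUTRAL in labs and DELETERIOUS in labs
    }
    return [r for r in records if r.key not in conflicted]


def deduplicate(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Collapse duplicate mutations to one record per key.

    Requires conflicts to have been purged (duplicates must agree on
    label).  The survivor carries the union of contributing sources,
    comma-joined in sorted order; output is sorted by key for determinism.
    """
    by_key: dict[MutationKey, list[MutationRecord]] = {}
    for r in records:
        by_key.setdefault(r.key, []).append(r)
    out = []
    for key in sorted(by_key):
        group = by_key[key]
        if len({g.label for g in group}) > 1:
            raise SnpConsensusError(
                f"conflicting labels for {key}; run purge_conflicts first"
            )
        sources = sorted(
            {s for g in group for s in (g.source.split(",") if g.source else [])}
        )
        first = group[0]
        out.append(
            MutationRecord(
                protein_id=first.protein_id,
                position=first.position,
                wt_aa=first.wt_aa,
                mut_aa=first.mut_aa,
                label=first.label,
                source=",".join(sources),
            )
        )
    return out


class PairwiseLocalAligner:
    """Smith-Waterman fragment producer for desk-scale overlap checks.

    BLOSUM62 scoring with gap open 11 / extend 1.  Statistical e-value
    calibration is out of scope for a plain Smith-Waterman scorer, so
    fragments shorter than ``min_length`` alignment columns are suppressed
    instead, and emitted fragments carry ``evalue = 0.0`` (always passing
    the e-value gate).  This is an approximation of a BLAST search that is
    conservative on unrelated sequences of a few hundred residues.
    """

    def __init__(self, min_length: int = 30):
        self.min_length = min_length
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(
            "BLOSUM62"
        )
        self._aligner.open_gap_score = -11.0
        self._aligner.extend_gap_score = -1.0

    def __call__(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> list[AlignedFragmentPair]:
        alignments = self._aligner.align(query_seq, subject_seq)
        if len(alignments) == 0:
            return []
        aln = alignments[0]
        blocks_q, blocks_s = aln.aligned
        if len(blocks_q) == 0:
            return []
        column_map = []
        matches = 0
        for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
            for dq in range(qe - qs):
                qpos, spos = qs + dq, ss + dq
                column_map.append((qpos + 1, spos + 1))
                if query_seq[qpos] == subject_seq[spos]:
                    matches += 1
        q_start = int(blocks_q[0][0]) + 1
        q_end = int(blocks_q[-1][1])
        s_start = int(blocks_s[0][0]) + 1
        s_end = int(blocks_s[-1][1])
        # columns incl. gaps = max of the two spans plus the other's gaps;
        # equivalently total columns of the local alignment path
        n_columns = (q_end - q_start + 1) + (s_end - s_start + 1) - len(
            column_map
        )
        if n_columns < self.min_length:
            return []
        return [
            AlignedFragmentPair(
                query_id=query_id,
                subject_id=subject_id,
                query_start=q_start,
                query_end=q_end,
                subject_start=s_start,
                subject_end=s_end,
                column_map=tuple(column_map),
                identity=matches / n_columns,
                evalue=0.0,
            )
        ]


class BlastTabularAligner:
    """Fragment producer backed by precomputed BLAST tabular output.

    Expects the standard 12-column format (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).  The tabular
    format does not carry the alignment path, so the column map is
    reconstructed as a linear offset when the query and subject spans have
    equal length (gapless HSP); gapped HSPs are re-aligned with the
    built-in aligner when sequences are supplied, and rejected otherwise.
    """

    def __init__(
        self,
        path: str | Path,
        sequences: Mapping[str, str] | None = None,
    ):
        self._hsp: dict[tuple[str, str], list[dict]] = {}
        self._sequences = sequences
        self._fallback = PairwiseLocalAligner(min_length=1)
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such BLAST tabular file: {path}")
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path} line {lineno}: expected 12 tab-separated "
                    f"columns, got {len(parts)}"
                )
            rec = {
                "qseqid": parts[0],
                "sseqid": parts[1],
                "pident": float(parts[2]),
                "length": int(parts[3]),
                "qstart": int(parts[6]),
                "qend": int(parts[7]),
                "sstart": int(parts[8]),
                "send": int(parts[9]),
                "evalue": float(parts[10]),
            }
            self._hsp.setdefault((rec["qseqid"], rec["sseqid"]), []).append(rec)

    def __call__(
        self, query_id: str, query_seq: str, subject_id: str, subject_seq: str
    ) -> list[AlignedFragmentPair]:
        out = []
        for rec in self._hsp.get((query_id, subject_id), []):
            qspan = rec["qend"] - rec["qstart"] + 1
            sspan = rec["send"] - rec["sstart"] + 1
            if qspan == sspan:
                column_map = tuple(
                    (rec["qstart"] + i, rec["sstart"] + i)
                    for i in range(qspan)
                )
                out.append(
                    AlignedFragmentPair(
                        query_id=query_id,
                        subject_id=subject_id,
                        query_start=rec["qstart"],
                        query_end=rec["qend"],
                        subject_start=rec["sstart"],
                        subject_end=rec["send"],
                        column_map=column_map,
                        identity=rec["pident"] / 100.0,
                        evalue=rec["evalue"],
                    )
                )
            elif self._sequences is not None:
                qsub = self._sequences[query_id][
                    rec["qstart"] - 1 : rec["qend"]
                ]
                ssub = self._sequences[subject_id][
                    rec["sstart"] - 1 : rec["send"]
                ]
                for frag in self._fallback(query_id, qsub, subject_id, ssub):
                    shifted = tuple(
                        (q + rec["qstart"] - 1, s + rec["sstart"] - 1)
                        for q, s in frag.column_map
                    )
                    out.append(
                        AlignedFragmentPair(
                            query_id=query_id,
                            subject_id=subject_id,
                            query_start=rec["qstart"],
                            query_end=rec["qend"],
                            subject_start=rec["sstart"],
                            subject_end=rec["send"],
                            column_map=shifted,
                            identity=rec["pident"] / 100.0,
                            evalue=rec["evalue"],
                        )
                    )
            else:
                raise FormatError(
                    f"gapped HSP {query_id}/{subject_id} cannot be mapped "
                    "without sequences"
                )
        return out


def find_overlapping_positions(
    query_positions: Iterable[Position],
    query_sequences: Mapping[str, str],
    reference_positions: Iterable[Position],
    reference_sequences: Mapping[str, str],
    aligner: FragmentProducer,
    spec: OverlapSpec = OverlapSpec(),
) -> set[Position]:
    """Query positions that map onto mutated reference positions.

    A query position overlaps a reference set when some fragment pair with
    e-value <= ``spec.max_evalue`` and identity >= ``spec.min_identity``
    aligns it (as a non-gap/non-gap column) to a position mutated in the
    reference; identical protein identifiers overlap directly at identical
    positions.
    """
    query_positions = set(query_positions)
    ref_by_protein: dict[str, set[int]] = {}
    for pid, pos in reference_positions:
        ref_by_protein.setdefault(pid, set()).add(pos)

    overlaps: set[Position] = set()
    query_proteins = sorted({pid for pid, _ in query_positions})
    for qid in query_proteins:
        q_positions = {pos for pid, pos in query_positions if pid == qid}
        # direct overlap: same identifier, same position
        if qid in ref_by_protein:
            overlaps.update(
                (qid, pos) for pos in q_positions & ref_by_protein[qid]
            )
        if qid not in query_sequences:
            raise SnpConsensusError(f"no sequence for query protein {qid!r}")
        for sid in sorted(ref_by_protein):
            if sid not in reference_sequences:
                raise SnpConsensusError(
                    f"no sequence for reference protein {sid!r}"
                )
            for frag in aligner(
                qid, query_sequences[qid], sid, reference_sequences[sid]
            ):
                if frag.evalue > spec.max_evalue:
                    continue
                if frag.identity < spec.min_identity:
                    continue
                mapped = {
                    q
                    for q, s in frag.column_map
                    if s in ref_by_protein[sid]
                }
                overlaps.update(
                    (qid, pos) for pos in mapped & q_positions
                )
    return overlaps


def remove_overlaps(
    records: Sequence[MutationRecord],
    overlapping: set[Position],
) -> tuple[list[MutationRecord], dict[str, int]]:
    """Drop records at overlapping positions; report removals per source."""
    kept = []
    removed: dict[str, int] = {}
    for r in records:
        if (r.protein_id, r.position) in overlapping:
            removed[r.source] = removed.get(r.source, 0) + 1
        else:
            kept.append(r)
    return kept, removed


def label_pmd(annotation_tokens: Iterable[str]) -> str:
    """Functional label from activity-annotation tokens.

    '=' alone (no change of activity) is neutral; any other annotation is
    deleterious; a record carrying '=' together with a change annotation is
    contradictory and excluded.
    """
    tokens = set(annotation_tokens)
    if not tokens:
        raise FormatError("empty annotation token set")
    if tokens == {"="}:
        return NEUTRAL
    if "=" in tokens:
        return "excluded"
    return DELETERIOUS


def label_by_activity(relative_change: float, threshold: float = 0.5) -> str:
    """Deleterious when the relative activity change strictly exceeds threshold."""
    if relative_change < 0:
        raise ValidationError(
            f"activity change must be >= 0, got {relative_change}"
        )
    return DELETERIOUS if relative_change > threshold else NEUTRAL


@dataclass
class BuildAudit:
    """Record counts after each stage of the build pipeline."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def log(self, stage: str, n: int) -> None:
        self.stages.append((stage, n))

    def as_dict(self) -> dict[str, int]:
        return dict(self.stages)


def build_independent_dataset(
    sources: Sequence[Sequence[MutationRecord]],
    training_positions: Iterable[Position],
    training_sequences: Mapping[str, str],
    holdout_positions: Iterable[Position],
    holdout_sequences: Mapping[str, str],
    query_sequences: Mapping[str, str],
    aligner: FragmentProducer,
    spec: OverlapSpec = OverlapSpec(),
) -> tuple[list[MutationRecord], BuildAudit]:
    """Concatenate sources and remove conflicts, duplicates and overlaps.

    Pipeline: concatenate -> purge_conflicts -> deduplicate ->
    remove_overlaps(vs. training sets) -> remove_overlaps(vs. held-out
    sets).  The audit records the surviving count after each stage, plus
    how many records each overlap stage removed.
    """
    audit = BuildAudit()
    records: list[MutationRecord] = [r for src in sources for r in src]
    audit.log("concatenated", len(records))
    records = purge_conflicts(records)
    audit.log("after_conflict_purge", len(records))
    records = deduplicate(records)
    audit.log("after_deduplication", len(records))

    for stage, ref_positions, ref_sequences in (
        ("training", training_positions, training_sequences),
        ("holdout", holdout_positions, holdout_sequences),
    ):
        positions = {(r.protein_id, r.position) for r in records}
        overlapping = find_overlapping_positions(
            positions,
            query_sequences,
            ref_positions,
            ref_sequences,
            aligner,
            spec,
        )
        records, _ = remove_overlaps(records, overlapping)
        audit.log(f"after_{stage}_overlap_removal", len(records))
    return records, audit
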