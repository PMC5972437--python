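"""Amplicon read alignment and editing-outcome classification.

Each sequenced (or simulated) amplicon read is aligned to a short local
reference with a semi-global affine-gap aligner — global over the read, with
free end gaps where the reference extends past the read — and the resulting
M/I/D CIGAR is inspected within a window extending 40 bp up- and downstream
of the spacer:

* NHEJ scheme: any insertion event in the window and no deletion ->
  ``Insertion``; any deletion and no insertion -> ``Deletion``; neither ->
  ``Match`` (substitution-only reads are matches); both -> the longest event
  decides, ties going to ``Deletion``.
* HDR scheme (alignment against the donor-modified reference): the
  restriction site counts as *present* when the recognition sequence occurs
  exactly within the read segment aligned to the window. Present + Match ->
  ``Correct`` incorporation; present + Insertion/Deletion -> ``Wrong``;
  absent -> ``No``.

Reads whose alignment identity falls below a threshold (default 0.75) are
``Unaligned`` and excluded from all denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

__all__ = [
    "AlignScores",
    "AlignmentResult",
    "AmpliconExperiment",
    "ReadOutcome",
    "EditingSummary",
    "align_read",
    "classify_nhej",
    "classify_hdr",
    "classify_read",
    "classify_reads",
    "summarize",
]


@dataclass(frozen=True)
class AlignScores:
    """Affine alignment scores. A gap of length k costs open + (k-1)*extend."""

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


def _make_aligner(scores: AlignScores) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        match_score=scores.match,
        mismatch_score=scores.mismatch,
        open_gap_score=scores.gap_open,
        extend_gap_score=scores.gap_extend,
        mode="global",
    )
    # free end gaps on the read's flanks (reference overhang is unpenalised)
    aligner.end_deletion_score = 0
    return aligner


@dataclass
class AlignmentResult:
    """A read-to-reference alignment.

    ``cigar`` covers the read with M/I/D runs (indels left-normalised);
    ``ref_offset`` is the reference coordinate of the first CIGAR column;
    ``identity`` is matches / aligned columns (M+I+D).
    """

    cigar: str
    score: float
    identity: float
    ref_offset: int
    events: list[tuple[str, int, int]] = field(default_factory=list)


def _cigar_ops(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def _ops_to_cigar(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops if n > 0)


def _merge_ops(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _left_normalize(
    ref: str, read: str, ref_offset: int, ops: list[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Shift every indel run as far left as the flanking sequence allows."""
    changed = True
    while changed:
        changed = False
        ops = _merge_ops(ops)
        rpos, qpos = ref_offset, 0
        for k, (op, n) in enumerate(ops):
            if op in ("I", "D") and k > 0 and ops[k - 1][0] == "M" and ops[k - 1][1] > 0:
                if op == "D":
                    movable = ref[rpos + n - 1] == ref[rpos - 1]
                else:
                    movable = read[qpos + n - 1] == read[qpos - 1]
                if movable:
                    ops[k - 1] = ("M", ops[k - 1][1] - 1)
                    if k + 1 < len(ops) and ops[k + 1][0] == "M":
                        ops[k + 1] = ("M", ops[k + 1][1] + 1)
                    else:
                        ops.insert(k + 1, ("M", 1))
                    changed = True
                    break
            if op in ("M", "D"):
                rpos += n
            if op in ("M", "I"):
                qpos += n
    return _merge_ops(ops)


def align_read(
    read: str,
    reference: str,
    scores: AlignScores | None = None,
    min_identity: float = 0.75,
    min_read_len: int = 30,
) -> AlignmentResult | None:
    """Semi-global alignment of a read to a reference.

    Returns ``None`` for reads shorter than ``min_read_len`` or whose
    alignment identity falls below ``min_identity`` — such reads are treated
    as Unaligned, not as errors.
    """
    read = read.upper()
    reference = reference.upper()
    if len(read) < min_read_len:
        return None
    scores = scores or AlignScores()
    aligner = _make_aligner(scores)
    aln = aligner.align(reference, read)[0]
    t_blocks, q_blocks = aln.aligned

    ops: list[tuple[str, int]] = []
    if len(t_blocks) == 0:
        return None
    ref_offset = int(t_blocks[0][0])
    # read prefix unaligned to the reference (read overhang) -> insertion
    if q_blocks[0][0] > 0:
        ops.append(("I", int(q_blocks[0][0])))
    prev_t, prev_q = t_blocks[0], q_blocks[0]
    ops.append(("M", int(prev_t[1] - prev_t[0])))
    for (t0, t1), (q0, q1) in zip(t_blocks[1:], q_blocks[1:]):
        dt, dq = int(t0 - prev_t[1]), int(q0 - prev_q[1])
        if dt > 0:
            ops.append(("D", dt))
        if dq > 0:
            ops.append(("I", dq))
        ops.append(("M", int(t1 - t0)))
        prev_t, prev_q = (t0, t1), (q0, q1)
    if int(prev_q[1]) < len(read):
        ops.append(("I", len(read) - int(prev_q[1])))

    ops = _left_normalize(reference, read, ref_offset, ops)
    # leading insertion after normalisation cannot shift further; leading
    # deletions would only arise without free end gaps

    # identity over the aligned span
    rpos, qpos, matches, columns = ref_offset, 0, 0, 0
    events: list[tuple[str, int, int]] = []
    for op, n in ops:
        columns += n
        if op == "M":
            matches += sum(
                1 for a, b in zip(reference[rpos : rpos + n], read[qpos : qpos + n]) if a == b
            )
            rpos += n
            qpos += n
        elif op == "D":
            events.append(("D", rpos, n))
            rpos += n
        else:
            events.append(("I", rpos, n))
            qpos += n
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    return AlignmentResult(
        cigar=_ops_to_cigar(ops),
        score=float(aln.score),
        identity=identity,
        ref_offset=ref_offset,
        events=events,
    )


@dataclass
class AmpliconExperiment:
    """One amplicon locus: reference, spacer coordinates, optional HDR donor edit.

    ``spacer_start``/``spacer_end`` are on the unmodified reference. In HDR
    mode (``insert_seq`` + ``insertion_point`` + ``recognition_seq`` given),
    reads are aligned against the donor-modified reference and spacer/window
    coordinates are shifted past the insert accordingly. The classification
    window extends ``flank`` bp (default 40) up- and downstream of the spacer
    (including the insert in HDR mode), clipped to the reference.
    """

    reference_seq: str
    spacer_start: int
    spacer_end: int
    flank: int = 40
    insert_seq: str | None = None
    insertion_point: int | None = None
    recognition_seq: str | None = None

    def __post_init__(self) -> None:
        self.reference_seq = self.reference_seq.upper()
        if not (0 <= self.spacer_start < self.spacer_end <= len(self.reference_seq)):
            raise ValueError("spacer interval outside reference")
        if (self.insert_seq is None) != (self.insertion_point is None):
            raise ValueError("insert_seq and insertion_point must be given together")
        if self.insert_seq is not None:
            self.insert_seq = self.insert_seq.upper()

    @property
    def hdr_mode(self) -> bool:
        return self.insert_seq is not None

    @property
    def modified_reference_seq(self) -> str | None:
        if not self.hdr_mode:
            return None
        ip = self.insertion_point
        return self.reference_seq[:ip] + self.insert_seq + self.reference_seq[ip:]

    @property
    def active_reference(self) -> str:
        return self.modified_reference_seq if self.hdr_mode else self.reference_seq

    def _active_spacer(self) -> tuple[int, int]:
        s, e = self.spacer_start, self.spacer_end
        if self.hdr_mode:
            k, ip = len(self.insert_seq), self.insertion_point
            if ip <= s:
                s += k
            if ip < e or ip <= s:
                e += k
        return s, e

    @property
    def window(self) -> tuple[int, int]:
        s, e = self._active_spacer()
        return max(0, s - self.flank), min(len(self.active_reference), e + self.flank)


def _events_in_window(
    events: Sequence[tuple[str, int, int]], window: tuple[int, int]
) -> list[tuple[str, int, int]]:
    ws, we = window
    hits = []
    for op, pos, n in events:
        if op == "D":
            if pos < we and pos + n > ws:
                hits.append((op, pos, n))
        else:  # insertion at inter-base coordinate pos
            if ws <= pos <= we:
                hits.append((op, pos, n))
    return hits


def classify_nhej(aln: AlignmentResult, experiment: AmpliconExperiment) -> str:
    """NHEJ label from indel events intersecting the spacer window."""
    hits = _events_in_window(aln.events, experiment.window)
    has_i = any(op == "I" for op, _, _ in hits)
    has_d = any(op == "D" for op, _, _ in hits)
    if has_i and not has_d:
        return "Insertion"
    if has_d and not has_i:
        return "Deletion"
    if not hits:
        return "Match"
    longest_i = max(n for op, _, n in hits if op == "I")
    longest_d = max(n for op, _, n in hits if op == "D")
    return "Insertion" if longest_i > longest_d else "Deletion"


def _window_read_segment(
    read: str, aln: AlignmentResult, window: tuple[int, int]
) -> str:
    """The read substring aligned to the reference window (insertions included)."""
    ws, we = window
    rpos, qpos = aln.ref_offset, 0
    lo, hi = None, None
    for op, n in _cigar_ops(aln.cigar):
        if op == "M":
            for k in range(n):
                if ws <= rpos + k < we:
                    if lo is None:
                        lo = qpos + k
                    hi = qpos + k + 1
            rpos += n
            qpos += n
        elif op == "D":
            rpos += n
        else:  # I
            if ws <= rpos <= we:
                if lo is None:
                    lo = qpos
                hi = qpos + n
            qpos += n
    if lo is None:
        return ""
    return read[lo:hi]


def classify_hdr(
    read: str, aln: AlignmentResult, experiment: AmpliconExperiment, nhej_label: str
) -> str:
    """HDR label: Correct/Wrong/No incorporation of the restriction site."""
    if not experiment.hdr_mode or experiment.recognition_seq is None:
        raise ValueError("HDR classification requires a modified reference and recognition_seq")
    segment = _window_read_segment(read, aln, experiment.window)
    present = experiment.recognition_seq.upper() in segment
    if not present:
        return "No"
    return "Correct" if nhej_label == "Match" else "Wrong"


@dataclass
class ReadOutcome:
    read_id: str
    nhej_label: str  # Insertion | Deletion | Match | Unaligned
    hdr_label: str  # Correct | Wrong | No | NA
    alignment_identity: float
    events_in_window: list[tuple[str, int, int]] = field(default_factory=list)


def classify_read(
    read_id: str,
    read_seq: str,
    experiment: AmpliconExperiment,
    scores: AlignScores | None = None,
    min_identity: float = 0.75,
    min_read_len: int = 30,
) -> ReadOutcome:
    """Align one read against the experiment's active reference and label it."""
    aln = align_read(
        read_seq,
        experiment.active_reference,
        scores=scores,
        min_identity=min_identity,
        min_read_len=min_read_len,
    )
    if aln is None:
        return ReadOutcome(read_id, "Unaligned", "NA", 0.0)
    nhej = classify_nhej(aln, experiment)
    if experiment.hdr_mode and experiment.recognition_seq is not None:
        hdr = classify_hdr(read_seq, aln, experiment, nhej)
    else:
        hdr = "NA"
    return ReadOutcome(
        read_id,
        nhej,
        hdr,
        aln.identity,
        _events_in_window(aln.events, experiment.window),
    )


def classify_reads(
    reads: Iterable,
    experiment: AmpliconExperiment,
    scores: AlignScores | None = None,
    min_identity: float = 0.75,
    min_read_len: int = 30,
) -> tuple[list[ReadOutcome], "EditingSummary"]:
    """Classify an iterable of reads (SeqRecords or ``(id, seq)`` pairs)."""
    outcomes = []
    for i, rec in enumerate(reads):
        if hasattr(rec, "seq"):
            rid, seq = str(rec.id), str(rec.seq)
        else:
            rid, seq = str(rec[0]), str(rec[1])
        outcomes.append(
            classify_read(rid, seq, experiment, scores, min_identity, min_read_len)
        )
    return outcomes, summarize(outcomes)


@dataclass
class EditingSummary:
    """Per-experiment counts and percentages (denominator: aligned reads)."""

    n_total: int
    n_aligned: int
    n_insertion: int
    n_deletion: int
    n_match: int
    indel_pct: float
    n_hdr_correct: int
    n_hdr_wrong: int
    n_hdr_no: int
    hdr_correct_pct: float


def summarize(outcomes: Sequence[ReadOutcome]) -> EditingSummary:
    """Tally classification labels into an :class:`EditingSummary`.

    Percentages use aligned reads as the denominator; with zero aligned reads
    they are NaN and a warning is emitted.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    n_total = len(outcomes)
    labels = [o.nhej_label for o in outcomes]
    n_ins = labels.count("Insertion")
    n_del = labels.count("Deletion")
    n_match = labels.count("Match")
    n_aligned = n_ins + n_del + n_match
    hdr = [o.hdr_label for o in outcomes]
    n_ok, n_wrong, n_no = hdr.count("Correct"), hdr.count("Wrong"), hdr.count("No")
    if n_aligned == 0:
        warnings.warn("no aligned reads; percentages are undefined", stacklevel=2)
        indel_pct = hdr_pct = float("nan")
    else:
        indel_pct = 100.0 * (n_ins + n_del) / n_aligned
        hdr_pct = 100.0 * n_ok / n_aligned
    return EditingSummary(
        n_total=n_total,
        n_aligned=n_aligned,
        n_insertion=n_ins,
        n_deletion=n_del,
        n_match=n_match,
        indel_pct=indel_pct,
        n_hdr_correct=n_ok,
        n_hdr_wrong=n_wrong,
        n_hdr_no=n_no,
        hdr_correct_pct=hdr_pct,
    )
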