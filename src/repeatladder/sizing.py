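"""Unique assignment of amplicon reads to ladder references.

Each read is scored against every ladder member by semi-global edit
distance (the read must align to a *prefix* of the reference, matching the
single-end amplicon geometry where read 1 starts at the upstream primer).
Unit costs for mismatches and indels; both orientations are tried.  A read
is assigned to ladder index i only when the minimal cost is unique within a
margin, below an error budget, and the read reaches far enough past the
tract to anchor the downstream side.  Ties are never broken — they yield
UNASSIGNED, because biased tie-breaking would systematically shift the
repeat-length histogram by one unit.
"""

from __future__ import annotations

import gzip
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .locus import LadderReference

UNASSIGNED = None

READ_ALPHABET = frozenset("ACGTN")

#: Rejection reasons recorded in the QC summary.
REASON_AMBIGUOUS = "ambiguous"
REASON_MAX_ERROR = "max_error"
REASON_TOO_SHORT = "too_short"
REASON_INVALID = "invalid_characters"
REASON_EMPTY = "empty_read"


@dataclass(frozen=True)
class SizingParams:
    """Tunable thresholds for read-to-ladder assignment.

    margin: minimal cost gap to the second-best ladder member required for
        a unique call (1 = any exact tie is rejected).
    max_error_frac: alignment cost budget as a fraction of read length.
    min_downstream_anchor: nucleotides of post-tract sequence a read must
        cover beyond the variable tract; realizes the detection ceiling of
        a fixed-length read.
    """

    margin: int = 1
    max_error_frac: float = 0.10
    min_downstream_anchor: int = 12


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    assigned_i: int | None
    best_score: int | None
    margin: int | None
    orientation: str | None  # "forward" | "reverse"
    reason: str | None = None  # set iff assigned_i is None

    @property
    def assigned(self) -> bool:
        return self.assigned_i is not None


@dataclass
class RepeatHistogram:
    """Counts R_i of reads uniquely assigned to each ladder member."""

    locus_id: str
    sample_id: str
    counts: dict[int, int]
    n_assigned: int
    n_unassigned: int
    unassigned_reasons: Counter = field(default_factory=Counter)
    i_min: int = 1
    i_max: int = 113

    def r(self, i: int) -> int:
        return self.counts.get(i, 0)

    @property
    def n_reads(self) -> int:
        return self.n_assigned + self.n_unassigned


def _scan_ladder(seq: str, ladder: LadderReference, cap: int, margin: int):
    """Return (best_i, best_d, second_d) over one orientation.

    ``cap`` is the maximum interesting distance; the effective edlib band
    shrinks to best + margin - 1 once a good hit is found, which is enough
    both to detect a strictly better member and any competitor within the
    uniqueness margin.
    """
    best_i, best_d, second_d = None, None, None
    read_len = len(seq)
    for i, ref in ladder.entries:
        k = cap if best_d is None else min(cap, best_d + margin - 1)
        # a reference shorter than the read forces >= read_len - ref_len edits
        if read_len - len(ref) > k:
            continue
        d = edlib.align(seq, ref, mode="SHW", task="distance", k=k)["editDistance"]
        if d < 0:
            continue
        if best_d is None or d < best_d:
            best_i, best_d, second_d = i, d, best_d
        elif second_d is None or d < second_d:
            second_d = d
    return best_i, best_d, second_d


def assign_read(
    seq: str,
    ladder: LadderReference,
    params: SizingParams = SizingParams(),
    read_id: str = "",
) -> ReadAssignment:
    """Assign one read to the ladder member with uniquely minimal edit cost."""
    seq = seq.upper()
    if not seq:
        return ReadAssignment(read_id, UNASSIGNED, None, None, None, REASON_EMPTY)
    if not set(seq) <= READ_ALPHABET:
        return ReadAssignment(read_id, UNASSIGNED, None, None, None, REASON_INVALID)

    cap = math.ceil(params.max_error_frac * len(seq))
    fwd = _scan_ladder(seq, ladder, cap, params.margin)
    rev = _scan_ladder(reverse_complement(seq), ladder, cap, params.margin)

    candidates = [(d, i, "forward", s) for i, d, s in [fwd] if d is not None]
    candidates += [(d, i, "reverse", s) for i, d, s in [rev] if d is not None]
    if not candidates:
        return ReadAssignment(read_id, UNASSIGNED, None, None, None, REASON_MAX_ERROR)

    candidates.sort(key=lambda c: c[0])
    best_d, best_i, orientation, within_second = candidates[0]
    # second-best across both orientations, unless the other orientation's
    # best lands on the same ladder member (same molecule, not a competitor)
    others = [s for _, _, _, s in candidates if s is not None]
    others += [d for d, i, _, _ in candidates[1:] if i != best_i]
    second_d = min(others) if others else None

    if second_d is not None and second_d - best_d < params.margin:
        return ReadAssignment(
            read_id, UNASSIGNED, best_d, second_d - best_d, orientation, REASON_AMBIGUOUS
        )
    if best_d > cap:
        return ReadAssignment(
            read_id, UNASSIGNED, best_d, None, orientation, REASON_MAX_ERROR
        )
    required = (
        len(ladder.template.upstream_flank)
        + 3 * best_i
        + params.min_downstream_anchor
    )
    if len(seq) < required:
        return ReadAssignment(
            read_id, UNASSIGNED, best_d, None, orientation, REASON_TOO_SHORT
        )
    margin = (second_d - best_d) if second_d is not None else cap + 1 - best_d
    return ReadAssignment(read_id, best_i, best_d, margin, orientation)


def _open_fastq(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path):
    """Yield (read_id, sequence) from a (possibly gzipped) FASTQ file."""
    with _open_fastq(path) as handle:
        index = 0
        try:
            for record in SeqIO.parse(handle, "fastq"):
                yield record.id, str(record.seq)
                index += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc


def size_reads(
    reads,
    ladder: LadderReference,
    params: SizingParams = SizingParams(),
    sample_id: str = "sample",
) -> tuple[RepeatHistogram, list[ReadAssignment]]:
    """Size an iterable of (read_id, sequence) pairs against a ladder."""
    counts: dict[int, int] = {}
    assignments: list[ReadAssignment] = []
    reasons: Counter = Counter()
    cache: dict[str, ReadAssignment] = {}
    n_assigned = 0
    n_unassigned = 0
    for read_id, seq in reads:
        cached = cache.get(seq)
        if cached is None:
            cached = assign_read(seq, ladder, params, read_id=read_id)
            cache[seq] = cached
        assignment = ReadAssignment(
            read_id,
            cached.assigned_i,
            cached.best_score,
            cached.margin,
            cached.orientation,
            cached.reason,
        )
        assignments.append(assignment)
        if assignment.assigned:
            counts[assignment.assigned_i] = counts.get(assignment.assigned_i, 0) + 1
            n_assigned += 1
        else:
            reasons[assignment.reason] += 1
            n_unassigned += 1
    if n_assigned + n_unassigned == 0:
        warnings.warn(f"sample {sample_id}: no reads", stacklevel=2)
    return (
        RepeatHistogram(
            locus_id=ladder.locus_id,
            sample_id=sample_id,
            counts=dict(sorted(counts.items())),
            n_assigned=n_assigned,
            n_unassigned=n_unassigned,
            unassigned_reasons=reasons,
            i_min=ladder.i_min,
            i_max=ladder.i_max,
        ),
        assignments,
    )


def size_sample(
    fastq_path,
    ladder: LadderReference,
    params: SizingParams = SizingParams(),
    sample_id: str | None = None,
) -> tuple[RepeatHistogram, list[ReadAssignment]]:
    """Size every read of a FASTQ file against a ladder.

    Deterministic and order-invariant in the histogram; base qualities are
    ignored.  An empty file yields an empty histogram with a warning.
    """
    if sample_id is None:
        sample_id = str(fastq_path)
    return size_reads(iter_fastq(fastq_path), ladder, params, sample_id=sample_id)
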