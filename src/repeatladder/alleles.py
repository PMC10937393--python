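"""Progenitor-allele calling and tract-structure detection.

The inherited allele lengths of a donor — N for the normal allele and M
for the unexpanded mutant allele — are read off the two modes of the
repeat-length histogram of a *non-expanding* reference cell type (glia or
granule cells), where both alleles still sit at their progenitor lengths
surrounded only by PCR-stutter shoulders.  Expanding cell types may lack
an unexpanded mode entirely, which is why the reference role is explicit.

Tract structure (presence of the interruption cassette, CCG-tract length)
is detected directly from reads by anchoring the upstream flank, counting
the uninterrupted repeat run, and parsing the expected cassettes in order.
Donors with an atypical structure are re-sized against a ladder rebuilt
from the matching template.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy.signal import find_peaks

from .locus import LadderReference, LocusTemplate, apply_structure, build_ladder
from .sizing import ReadAssignment, RepeatHistogram, SizingParams, size_reads


class AlleleCallError(ValueError):
    """Raised when progenitor alleles cannot be determined."""


@dataclass(frozen=True)
class AlleleCallParams:
    min_reads: int = 200
    min_separation: int = 5  # repeat units between the two modes
    prominence_frac: float = 0.05  # secondary peak height / primary peak height
    smooth: bool = False  # optional 3-point moving average before peak finding


@dataclass(frozen=True)
class TractStructure:
    """Detected post-tract cassette structure of one donor's amplicon."""

    locus_id: str
    interruption_present: bool
    cassette_codon_counts: dict[str, int]
    atypical: bool
    # (structure-signature -> frequency) when two structural alleles are
    # detected at near-equal frequency; empty otherwise
    alternatives: tuple[tuple[tuple[tuple[str, int], ...], float], ...] = ()

    @property
    def conflicting(self) -> bool:
        return len(self.alternatives) > 1


@dataclass(frozen=True)
class AlleleCall:
    N: int
    M: int
    source_sample_id: str
    structure: TractStructure | None = None

    def __post_init__(self) -> None:
        if self.N >= self.M:
            raise AlleleCallError(
                f"degenerate allele call N={self.N} >= M={self.M}: "
                "homozygous or single-allele samples are unsupported"
            )


def call_progenitor_lengths(
    hist: RepeatHistogram, params: AlleleCallParams = AlleleCallParams()
) -> AlleleCall:
    """Call (N, M) from the two modes of a non-expanding histogram.

    N and M are the repeat counts of the two highest local maxima separated
    by at least ``min_separation`` units, the secondary mode reaching at
    least ``prominence_frac`` of the primary mode's count; N is the smaller.
    """
    if hist.n_assigned < params.min_reads:
        raise AlleleCallError(
            f"insufficient reads: {hist.n_assigned} assigned, "
            f"need >= {params.min_reads}"
        )
    lo, hi = hist.i_min, hist.i_max
    counts = np.zeros(hi - lo + 1, dtype=float)
    for i, r in hist.counts.items():
        counts[i - lo] = r
    if params.smooth:
        counts = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    # pad so maxima at the histogram edges are still peaks
    padded = np.concatenate(([-1.0], counts, [-1.0]))
    peak_pos, _ = find_peaks(padded)
    peaks = sorted(
        ((counts[p - 1], p - 1 + lo) for p in peak_pos), reverse=True
    )
    if not peaks:
        raise AlleleCallError("no modes found in histogram")
    primary_count, primary_i = peaks[0]
    secondary = next(
        (
            (c, i)
            for c, i in peaks[1:]
            if abs(i - primary_i) >= params.min_separation
            and c >= params.prominence_frac * primary_count
        ),
        None,
    )
    if secondary is None:
        raise AlleleCallError(
            "single-mode histogram: cannot distinguish N from M "
            "(possible homozygosity or absent mutant allele)"
        )
    _, secondary_i = secondary
    n, m = sorted((int(primary_i), int(secondary_i)))
    return AlleleCall(N=n, M=m, source_sample_id=hist.sample_id)


# ---------------------------------------------------------------------------
# Structure detection

def _locate_flank_end(read: str, flank: str, max_edits: int = 2) -> int | None:
    """0-based position just past the upstream flank in ``read``, or None."""
    hit = edlib.align(flank, read, mode="HW", task="locations", k=max_edits)
    if hit["editDistance"] < 0 or not hit["locations"]:
        return None
    return hit["locations"][0][1] + 1


def _count_unit_run(seq: str, pos: int, unit: str) -> int:
    n = 0
    step = len(unit)
    while seq[pos : pos + step] == unit:
        n += 1
        pos += step
    return n


def _parse_read_structure(
    read: str, template: LocusTemplate, max_cassette_edits: int = 1
) -> tuple[tuple[str, int], ...] | None:
    """Per-read cassette codon counts, or None if the read cannot be parsed.

    The upstream flank is located approximately, the uninterrupted repeat
    run is skipped, then each expected cassette is consumed in order:
    single-codon cassettes by exact run counting, block cassettes by
    approximate prefix matching (<= ``max_cassette_edits`` edits).
    """
    pos = _locate_flank_end(read, template.upstream_flank)
    if pos is None:
        return None
    pos += 3 * _count_unit_run(read, pos, template.repeat_unit)
    observed: list[tuple[str, int]] = []
    for cassette in template.cassettes:
        if cassette.is_variable:
            run = _count_unit_run(read, pos, cassette.unit)
            observed.append((cassette.name, run))
            pos += 3 * run
        else:
            window = read[pos : pos + len(cassette.sequence)]
            if len(window) < len(cassette.sequence):
                return None  # read too short to judge this cassette
            d = edlib.align(cassette.sequence, window, mode="NW", task="distance")[
                "editDistance"
            ]
            if d <= max_cassette_edits:
                observed.append((cassette.name, cassette.codon_count))
                pos += len(cassette.sequence)
            else:
                observed.append((cassette.name, 0))
    if pos + 3 > len(read):
        return None  # no post-cassette anchor; trailing counts unreliable
    return tuple(observed)


def detect_structure(
    reads,
    template: LocusTemplate,
    params: AlleleCallParams = AlleleCallParams(),
    report_frac: float = 0.3,
) -> TractStructure:
    """Detect the modal post-tract cassette structure from reads.

    ``reads`` is an iterable of (read_id, sequence) pairs.  Structures
    observed in at least ``report_frac`` of parseable reads are reported;
    more than one such structure flags two structural alleles for
    per-allele re-laddering instead of an arbitrary choice.
    """
    tally: Counter = Counter()
    n_parsed = 0
    for _, seq in reads:
        parsed = _parse_read_structure(seq.upper(), template)
        if parsed is not None:
            tally[parsed] += 1
            n_parsed += 1
    if n_parsed < params.min_reads:
        raise AlleleCallError(
            f"insufficient parseable reads for structure detection: {n_parsed}"
        )
    frequent = [
        (sig, count / n_parsed)
        for sig, count in tally.most_common()
        if count / n_parsed >= report_frac
    ]
    if not frequent:
        frequent = [max(((s, c / n_parsed) for s, c in tally.items()), key=lambda x: x[1])]
    modal_sig = frequent[0][0]
    modal = dict(modal_sig)
    template_counts = template.cassette_codon_counts()
    atypical = modal != template_counts
    interruption = next(
        (
            count > 0
            for name, count in modal.items()
            if "interruption" in name
        ),
        False,
    )
    return TractStructure(
        locus_id=template.locus_id,
        interruption_present=interruption,
        cassette_codon_counts=modal,
        atypical=atypical,
        alternatives=tuple(frequent) if len(frequent) > 1 else (),
    )


def resize_if_atypical(
    reads,
    template: LocusTemplate,
    structure: TractStructure,
    hist: RepeatHistogram,
    params: SizingParams = SizingParams(),
) -> tuple[RepeatHistogram, list[ReadAssignment] | None]:
    """Re-size reads against a ladder matching an atypical structure.

    A canonical structure is a no-op returning the input histogram.
    ``reads`` must be re-iterable (a list or a factory-produced iterable).
    """
    if not structure.atypical:
        return hist, None
    new_template = apply_structure(template, structure)
    new_ladder = build_ladder(new_template)
    new_hist, assignments = size_reads(
        reads, new_ladder, params, sample_id=hist.sample_id
    )
    return new_hist, assignments
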