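"""Per-sample somatic-instability statistics.

All statistics are functions of the repeat-length histogram R_i and the
progenitor allele lengths N (normal allele) and M (unexpanded mutant
allele), with the supports fixed by their definitions:

* normal-allele RoSE  = (R_{N+1} + R_{N+2} + R_{N+3}) / R_N
* mutant-allele RoSE  = sum_{i=M+1}^{i_max} R_i / R_M
* MSLG (repeat units) = sum_{i=M}^{i_max} (R_i * i) / sum_{i=M}^{i_max} R_i  -  M

MSLG is the mean uninterrupted repeat length over reads at or above M,
minus M — the average somatic length gain of the mutant allele, not the
increment per mutation event.  Reads with N+3 < i < M fall in neither
support; they are tallied as ``intermediate_reads`` for QC but never enter
any statistic.  Contractions of the mutant allele (i < M) are likewise
outside every support.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sizing import RepeatHistogram


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator has no reads."""


def rose_normal(hist: RepeatHistogram, N: int) -> float:
    """Ratio of somatic expansions of the normal allele."""
    r_n = hist.r(N)
    if r_n == 0:
        raise UndefinedStatisticError(f"no reads at normal allele length N={N}")
    return (hist.r(N + 1) + hist.r(N + 2) + hist.r(N + 3)) / r_n


def rose_mutant(hist: RepeatHistogram, M: int) -> float:
    """Ratio of somatic expansions of the mutant allele."""
    r_m = hist.r(M)
    if r_m == 0:
        raise UndefinedStatisticError(f"no reads at progenitor allele length M={M}")
    return sum(hist.r(i) for i in range(M + 1, hist.i_max + 1)) / r_m


def mslg(hist: RepeatHistogram, M: int) -> float:
    """Mean somatic length gain of the mutant allele, in repeat units."""
    total = sum(hist.r(i) for i in range(M, hist.i_max + 1))
    if total == 0:
        raise UndefinedStatisticError(f"no reads at or above M={M}")
    weighted = sum(hist.r(i) * i for i in range(M, hist.i_max + 1))
    return weighted / total - M


def normalize_histogram(hist: RepeatHistogram, scale: float = 1000.0) -> dict[int, float]:
    """Scale counts so they sum to ``scale`` (real values, no rounding)."""
    if hist.n_assigned == 0:
        raise UndefinedStatisticError("cannot normalize an empty histogram")
    factor = scale / hist.n_assigned
    return {i: r * factor for i, r in hist.counts.items()}


def gain_distribution(hist: RepeatHistogram, M: int) -> dict[int, float]:
    """Fraction of mutant-range reads at each length gain g = i - M >= 0."""
    total = sum(hist.r(i) for i in range(M, hist.i_max + 1))
    if total == 0:
        raise UndefinedStatisticError(f"no reads at or above M={M}")
    return {
        i - M: hist.r(i) / total
        for i in range(M, hist.i_max + 1)
        if hist.r(i) > 0
    }


def intermediate_reads(hist: RepeatHistogram, N: int, M: int) -> int:
    """Reads with N+3 < i < M: outside every statistic's support (QC only)."""
    return sum(hist.r(i) for i in range(N + 4, M))


@dataclass(frozen=True)
class InstabilityStats:
    """Bundle of per-sample instability statistics."""

    sample_id: str
    locus_id: str
    N: int
    M: int
    rose_normal: float
    rose_mutant: float
    mslg: float
    n_mutant_reads: int
    n_normal_reads: int
    n_intermediate_reads: int
    n_assigned: int
    n_unassigned: int
    normalized_hist: dict[int, float]


def compute_stats(hist: RepeatHistogram, N: int, M: int) -> InstabilityStats:
    """Compute all per-sample statistics for a histogram and allele call."""
    return InstabilityStats(
        sample_id=hist.sample_id,
        locus_id=hist.locus_id,
        N=N,
        M=M,
        rose_normal=rose_normal(hist, N),
        rose_mutant=rose_mutant(hist, M),
        mslg=mslg(hist, M),
        n_mutant_reads=sum(hist.r(i) for i in range(M, hist.i_max + 1)),
        n_normal_reads=sum(hist.r(i) for i in range(N, N + 4)),
        n_intermediate_reads=intermediate_reads(hist, N, M),
        n_assigned=hist.n_assigned,
        n_unassigned=hist.n_unassigned,
        normalized_hist=normalize_histogram(hist),
    )
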