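"""Shared fixtures: a small test locus, its ladder, and an independent
prefix-edit-distance oracle built on Bio.Align (not edlib)."""

from __future__ import annotations

import numpy as np
import pytest
from Bio import Align
from Bio.Seq import reverse_complement

from repeatladder import Cassette, LocusTemplate, build_ladder, htt_exon1_template

UP = "ACGTACGTTAGCCTGAGGTT"
DOWN = "TGCACCTTGGAGTCAATCGA"


@pytest.fixture(scope="session")
def template():
    """Small HTT-exon-1-like locus with synthetic flanks, i in [1, 60]."""
    return LocusTemplate(
        locus_id="TEST",
        upstream_flank=UP,
        downstream_flank=DOWN,
        repeat_unit="CAG",
        cassettes=(
            Cassette("caa_interruption", "CAACAG", 1),
            Cassette("ccg_tract", "CCG", 5),
        ),
        i_min=1,
        i_max=60,
    )


@pytest.fixture(scope="session")
def ladder(template):
    return build_ladder(template)


@pytest.fixture(scope="session")
def full_ladder():
    """Full [1, 113] ladder of the default HTT-exon-1-like template."""
    return build_ladder(htt_exon1_template())


@pytest.fixture(scope="session")
def plain_template():
    """Pure repeat tract with no cassettes."""
    return LocusTemplate(
        locus_id="PLAIN",
        upstream_flank=UP,
        downstream_flank=DOWN,
        repeat_unit="CAG",
        cassettes=(),
        i_min=1,
        i_max=60,
    )


def _prefix_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    # the unaligned reference suffix (gaps in the read row) costs nothing
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_ALIGNER = _prefix_aligner()


def oracle_distance(read: str, ref: str) -> int:
    """Unit-cost edit distance of ``read`` against a prefix of ``ref``."""
    return int(-_ALIGNER.score(ref, read))


def oracle_classify(read: str, ladder, margin: int = 1):
    """Exhaustive minimal-edit-distance classification over the full ladder.

    Returns (best_i, best_d, second_d, orientation); best_i is None on a
    tie within ``margin``.  Mirrors the assignment policy but computes
    every distance with the Bio.Align oracle.
    """
    scored = []
    for orientation, seq in (("forward", read), ("reverse", reverse_complement(read))):
        for i, ref in ladder.entries:
            scored.append((oracle_distance(seq, ref), i, orientation))
    scored.sort(key=lambda x: x[0])
    best_d, best_i, orientation = scored[0]
    second_d = next((d for d, i, _ in scored[1:] if i != best_i), None)
    if second_d is not None and second_d - best_d < margin:
        return None, best_d, second_d, orientation
    return best_i, best_d, second_d, orientation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


def mutate(rng, seq: str, n_subs: int) -> str:
    """Introduce exactly n distinct random substitutions."""
    seq = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(0, 3)]
    return "".join(seq)
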