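"""Progenitor-allele calling and tract-structure detection."""

import numpy as np
import pytest

from repeatladder import (
    AlleleCall,
    AlleleCallError,
    AlleleCallParams,
    RepeatHistogram,
    TractStructure,
    apply_structure,
    build_ladder,
    call_progenitor_lengths,
    detect_structure,
    resize_if_atypical,
)
from repeatladder.alleles import _parse_read_structure


def make_hist(counts, i_max=113):
    return RepeatHistogram(
        locus_id="L",
        sample_id="ref",
        counts=dict(counts),
        n_assigned=sum(counts.values()),
        n_unassigned=0,
        i_min=1,
        i_max=i_max,
    )


def stutter_hist(rng, n_allele, m_allele, n_reads=2000, shoulder=0.15):
    """Two sharp modes with +-1/+-2 stutter shoulders below ``shoulder``."""
    counts = {}
    for center, share in ((n_allele, 0.5), (m_allele, 0.5)):
        peak = int(n_reads * share * 0.7)
        counts[center] = counts.get(center, 0) + peak
        for off in (-2, -1, 1, 2):
            frac = rng.uniform(0.02, shoulder) / (abs(off))
            counts[center + off] = counts.get(center + off, 0) + int(peak * frac)
    return make_hist(counts)


class TestCallProgenitorLengths:
    def test_two_sharp_modes_with_shoulders(self, rng):
        hist = stutter_hist(rng, 17, 44)
        call = call_progenitor_lengths(hist)
        assert (call.N, call.M) == (17, 44)

    def test_recovery_across_seeds(self):
        for seed in range(25):
            gen = np.random.default_rng(seed)
            n_allele = int(gen.integers(10, 26))
            m_allele = int(gen.integers(36, 61))
            hist = stutter_hist(gen, n_allele, m_allele, shoulder=0.2)
            call = call_progenitor_lengths(hist)
            assert (call.N, call.M) == (n_allele, m_allele)

    def test_single_mode_is_an_explicit_error(self):
        hist = make_hist({20: 900, 21: 100, 19: 80})
        with pytest.raises(AlleleCallError, match="single-mode"):
            call_progenitor_lengths(hist)

    def test_equal_height_modes_smaller_is_n(self):
        hist = make_hist({20: 500, 40: 500})
        call = call_progenitor_lengths(hist)
        assert (call.N, call.M) == (20, 40)

    def test_insufficient_reads_rejected(self):
        hist = make_hist({20: 50, 40: 50})
        with pytest.raises(AlleleCallError, match="insufficient"):
            call_progenitor_lengths(hist)

    def test_close_modes_rejected_by_separation(self):
        hist = make_hist({20: 500, 23: 480})
        with pytest.raises(AlleleCallError, match="single-mode"):
            call_progenitor_lengths(hist, AlleleCallParams(min_separation=5))

    def test_degenerate_call_rejected(self):
        with pytest.raises(AlleleCallError, match="degenerate"):
            AlleleCall(N=40, M=40, source_sample_id="x")


class TestDetectStructure:
    def _reads(self, template, i_values, n_per=80):
        return [
            (f"r{i}_{k}", template.reference_sequence(i))
            for i in i_values
            for k in range(n_per)
        ]

    def test_canonical_reads_self_consistent(self, template):
        structure = detect_structure(self._reads(template, (17, 44), 120), template)
        assert not structure.atypical
        assert structure.interruption_present
        assert structure.cassette_codon_counts == template.cassette_codon_counts()

    def test_interruption_deletion_detected(self, template):
        no_int = TractStructure(
            locus_id="TEST",
            interruption_present=False,
            cassette_codon_counts={"caa_interruption": 0},
            atypical=True,
        )
        atypical_template = apply_structure(template, no_int)
        reads = self._reads(atypical_template, (17, 44), 120)
        structure = detect_structure(reads, template)
        assert structure.atypical
        assert not structure.interruption_present

    def test_balanced_mixture_reports_both_structures(self, template):
        short_ccg = apply_structure(
            template,
            TractStructure(
                locus_id="TEST",
                interruption_present=True,
                cassette_codon_counts={"ccg_tract": 3},
                atypical=True,
            ),
        )
        reads = self._reads(template, (30,), 150) + self._reads(short_ccg, (30,), 150)
        structure = detect_structure(reads, template)
        assert structure.conflicting
        freqs = [f for _, f in structure.alternatives]
        assert all(abs(f - 0.5) < 0.1 for f in freqs)

    def test_parse_tolerates_one_cassette_mismatch(self, template):
        read = template.reference_sequence(20)
        up = len(template.upstream_flank)
        pos = up + 60 + 2  # inside the CAACAG cassette
        corrupted = read[:pos] + ("T" if read[pos] != "T" else "G") + read[pos + 1:]
        parsed = _parse_read_structure(corrupted, template)
        assert dict(parsed)["caa_interruption"] == 2

    def test_insufficient_reads_rejected(self, template):
        with pytest.raises(AlleleCallError, match="insufficient"):
            detect_structure(self._reads(template, (20,), 10), template)


class TestResizeIfAtypical:
    @pytest.fixture()
    def atypical_setup(self, template):
        structure = TractStructure(
            locus_id="TEST",
            interruption_present=False,
            cassette_codon_counts={"caa_interruption": 0, "ccg_tract": 8},
            atypical=True,
        )
        atypical_template = apply_structure(template, structure)
        reads = [
            (f"r{i}_{k}", atypical_template.reference_sequence(i))
            for i in (17, 44)
            for k in range(150)
        ]
        return structure, atypical_template, reads

    def test_resize_recovers_true_modes(self, template, ladder, atypical_setup):
        structure, _, reads = atypical_setup
        from repeatladder import size_reads

        hist_canonical, _ = size_reads(reads, ladder)
        # canonical sizing cannot put the modes at the true lengths
        assert set(hist_canonical.counts) != {17, 44}
        detected = detect_structure(reads, template)
        assert detected.cassette_codon_counts == structure.cassette_codon_counts
        hist_fixed, _ = resize_if_atypical(reads, template, detected, hist_canonical)
        assert hist_fixed.counts == {17: 150, 44: 150}
        assert hist_fixed.n_unassigned <= hist_canonical.n_unassigned

    def test_canonical_structure_is_noop(self, template, ladder):
        reads = [(f"r{k}", template.reference_sequence(25)) for k in range(20)]
        from repeatladder import size_reads

        hist, _ = size_reads(reads, ladder)
        canonical = TractStructure(
            locus_id="TEST",
            interruption_present=True,
            cassette_codon_counts=template.cassette_codon_counts(),
            atypical=False,
        )
        same, assignments = resize_if_atypical(reads, template, canonical, hist)
        assert same is hist and assignments is None

    def test_resize_deterministic(self, template, ladder, atypical_setup):
        structure, _, reads = atypical_setup
        from repeatladder import size_reads

        hist, _ = size_reads(reads, ladder)
        h1, _ = resize_if_atypical(reads, template, structure, hist)
        h2, _ = resize_if_atypical(reads, template, structure, hist)
        assert h1.counts == h2.counts
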