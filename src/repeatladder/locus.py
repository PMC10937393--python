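"""Amplicon locus models and reference ladders for repeat sizing.

A sizing locus (e.g. *HTT* exon 1 or *ATXN3* exon 10) is described by a
:class:`LocusTemplate`: fixed primer-proximal flanks, a variable tract of a
single trinucleotide repeat unit, and an ordered set of fixed "cassettes"
between the variable tract and the downstream flank (for canonical *HTT*
exon 1: the CAA-CAG interruption, a CCG-CCA spacer, the CCG polyproline
tract and a short CCT run).

From a template we build a *ladder*: the family of otherwise-identical
reference amplicons that differ only in the number of uninterrupted repeat
units in the variable tract.  Reads are sized by unique best alignment
against the ladder; ladder indices therefore count only the uninterrupted
tract — interruption codons live in cassettes and are never counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

#: Longest tract reliably resolvable from a 400-nt single-end amplicon read.
MAX_REPEAT_UNITS = 113


class LocusConfigError(ValueError):
    """Raised when a locus template violates its invariants."""


@dataclass(frozen=True)
class Cassette:
    """A fixed sequence element between the variable tract and the flank.

    ``unit`` is repeated ``count`` times.  A single-codon unit (len 3)
    marks a cassette whose codon count may vary between donors (e.g. the
    CCG tract); multi-codon units are treated as present/absent blocks.
    """

    name: str
    unit: str
    count: int

    def __post_init__(self) -> None:
        if not self.unit or len(self.unit) % 3 != 0:
            raise LocusConfigError(
                f"cassette {self.name!r}: unit length must be a positive multiple of 3"
            )
        if not set(self.unit) <= DNA_ALPHABET:
            raise LocusConfigError(f"cassette {self.name!r}: unit must be over ACGT")
        if self.count < 0:
            raise LocusConfigError(f"cassette {self.name!r}: count must be >= 0")

    @property
    def sequence(self) -> str:
        return self.unit * self.count

    @property
    def codon_count(self) -> int:
        return (len(self.unit) // 3) * self.count

    @property
    def is_variable(self) -> bool:
        return len(self.unit) == 3


@dataclass(frozen=True)
class LocusTemplate:
    """Declarative description of one amplicon locus."""

    locus_id: str
    upstream_flank: str
    downstream_flank: str
    repeat_unit: str = "CAG"
    cassettes: tuple[Cassette, ...] = ()
    i_min: int = 1
    i_max: int = MAX_REPEAT_UNITS

    def __post_init__(self) -> None:
        if isinstance(self.cassettes, list):
            object.__setattr__(self, "cassettes", tuple(self.cassettes))
        for field_name in ("upstream_flank", "downstream_flank"):
            seq = getattr(self, field_name)
            if not seq:
                raise LocusConfigError(f"{field_name} must be non-empty")
            if not set(seq) <= DNA_ALPHABET:
                raise LocusConfigError(f"{field_name} must be over ACGT")
        if len(self.repeat_unit) != 3 or not set(self.repeat_unit) <= DNA_ALPHABET:
            raise LocusConfigError("repeat_unit must be a 3-nt ACGT string")
        if not (1 <= self.i_min <= self.i_max <= MAX_REPEAT_UNITS):
            raise LocusConfigError(
                f"require 1 <= i_min <= i_max <= {MAX_REPEAT_UNITS}, "
                f"got i_min={self.i_min}, i_max={self.i_max}"
            )

    @property
    def post_repeat_sequence(self) -> str:
        """Concatenated cassette sequence between the tract and downstream flank."""
        return "".join(c.sequence for c in self.cassettes)

    def reference_sequence(self, i: int) -> str:
        """Full amplicon sequence for an uninterrupted tract of ``i`` units."""
        if i < 0:
            raise ValueError("repeat count must be non-negative")
        return (
            self.upstream_flank
            + self.repeat_unit * i
            + self.post_repeat_sequence
            + self.downstream_flank
        )

    def cassette_codon_counts(self) -> dict[str, int]:
        return {c.name: c.codon_count for c in self.cassettes}


@dataclass(frozen=True)
class LadderReference:
    """Ordered family of reference amplicons indexed by uninterrupted repeat count."""

    template: LocusTemplate
    entries: tuple[tuple[int, str], ...]

    @property
    def locus_id(self) -> str:
        return self.template.locus_id

    @property
    def i_min(self) -> int:
        return self.entries[0][0]

    @property
    def i_max(self) -> int:
        return self.entries[-1][0]

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, i: int) -> str:
        return dict(self.entries)[i]


def build_ladder(template: LocusTemplate) -> LadderReference:
    """Build the reference ladder for ``template``.

    One reference per i in [i_min, i_max]; consecutive references differ by
    exactly one repeat unit (3 nt).  Deterministic.
    """
    entries = tuple(
        (i, template.reference_sequence(i))
        for i in range(template.i_min, template.i_max + 1)
    )
    return LadderReference(template=template, entries=entries)


def ladder_record_id(locus_id: str, repeat_unit: str, i: int) -> str:
    return f"{locus_id}_{repeat_unit}{i:03d}"


def parse_ladder_record_id(record_id: str) -> tuple[str, int]:
    """Invert :func:`ladder_record_id`: return (locus_id, i)."""
    stem, _, tail = record_id.rpartition("_")
    if not stem or len(tail) < 4:
        raise ValueError(f"not a ladder record id: {record_id!r}")
    return stem, int(tail[3:])


def write_ladder_fasta(ladder: LadderReference, destination) -> None:
    """Write the ladder as multi-FASTA; IDs encode locus and repeat count."""
    unit = ladder.template.repeat_unit
    records = [
        SeqRecord(
            Seq(seq),
            id=ladder_record_id(ladder.locus_id, unit, i),
            description=f"uninterrupted_{unit}_units={i}",
        )
        for i, seq in ladder.entries
    ]
    SeqIO.write(records, str(destination), "fasta")


def apply_structure(template: LocusTemplate, structure) -> LocusTemplate:
    """Return a template matching a detected tract structure.

    ``structure`` carries the locus it was detected on and a map of cassette
    name -> modal codon count (see ``alleles.TractStructure``).  Single-codon
    cassettes are resized; multi-codon cassettes may only be kept whole or
    dropped.  The input template is not modified.
    """
    if structure.locus_id != template.locus_id:
        raise LocusConfigError(
            f"structure detected on {structure.locus_id!r} cannot be applied "
            f"to template {template.locus_id!r}"
        )
    new_cassettes: list[Cassette] = []
    for cassette in template.cassettes:
        codons = structure.cassette_codon_counts.get(cassette.name, cassette.codon_count)
        if codons == cassette.codon_count:
            new_cassettes.append(cassette)
        elif cassette.is_variable:
            new_cassettes.append(replace(cassette, count=codons))
        elif codons == 0:
            continue  # block cassette absent in this donor
        else:
            raise LocusConfigError(
                f"cassette {cassette.name!r} is a fixed block; codon count can "
                f"only be 0 or {cassette.codon_count}, got {codons}"
            )
    return replace(template, cassettes=tuple(new_cassettes))


# ---------------------------------------------------------------------------
# Template configuration I/O (YAML)

def _resolve_sequence(value, base_dir: Path) -> str:
    """A flank is either an inline string or {fasta: path, id: record_id}."""
    if isinstance(value, str):
        return value.upper()
    if isinstance(value, Mapping) and "fasta" in value:
        path = base_dir / value["fasta"]
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        record_id = value.get("id")
        if record_id is None:
            if len(records) != 1:
                raise LocusConfigError(
                    f"{path}: multi-record FASTA requires an explicit 'id'"
                )
            return next(iter(records.values())).upper()
        return records[record_id].upper()
    raise LocusConfigError(f"cannot interpret sequence spec: {value!r}")


def template_from_dict(data: Mapping, base_dir: Path | str = ".") -> LocusTemplate:
    base = Path(base_dir)
    cassettes = tuple(
        Cassette(name=c["name"], unit=c["unit"].upper(), count=int(c["count"]))
        for c in data.get("cassettes", [])
    )
    return LocusTemplate(
        locus_id=data["locus_id"],
        upstream_flank=_resolve_sequence(data["upstream_flank"], base),
        downstream_flank=_resolve_sequence(data["downstream_flank"], base),
        repeat_unit=data.get("repeat_unit", "CAG").upper(),
        cassettes=cassettes,
        i_min=int(data.get("i_min", 1)),
        i_max=int(data.get("i_max", MAX_REPEAT_UNITS)),
    )


def load_template(path) -> LocusTemplate:
    path = Path(path)
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return template_from_dict(data, base_dir=path.parent)


def template_to_dict(template: LocusTemplate) -> dict:
    return {
        "locus_id": template.locus_id,
        "upstream_flank": template.upstream_flank,
        "downstream_flank": template.downstream_flank,
        "repeat_unit": template.repeat_unit,
        "cassettes": [
            {"name": c.name, "unit": c.unit, "count": c.count}
            for c in template.cassettes
        ],
        "i_min": template.i_min,
        "i_max": template.i_max,
    }


def save_template(template: LocusTemplate, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(template_to_dict(template), handle, sort_keys=False)


# ---------------------------------------------------------------------------
# Default templates.
#
# The cassette *structure* below is the canonical exon architecture; the
# flank sequences are synthetic placeholders of realistic length and GC
# content, not the clinical amplicon primer regions, and are meant to be
# overridden from a user template file for real data.

_HTT_UP_SYNTH = "ATGGCGACCCTGGAAAAGCTGATGAAGGCCTTCGAGTCCCTCAAGTCC"
_HTT_DOWN_SYNTH = "GATCCGTACTGAGTCTGAACTTGGCATCAAGTGACCGTTTCACCTGGATCA"
_ATXN3_UP_SYNTH = "GGACAGAGTTCACATCCATGTGAAAGGCCAGCCACCAGTTCAGG"
_ATXN3_DOWN_SYNTH = "TTCGGAAGTAGACCTGTCAAGTCCATCGGAAACTTGTGCCTTAG"


def htt_exon1_template(i_min: int = 1, i_max: int = MAX_REPEAT_UNITS) -> LocusTemplate:
    """Canonical *HTT* exon 1 structure: (CAG)i CAACAG CCGCCA (CCG)7 (CCT)2.

    Flanks are synthetic placeholders; real analyses should load a template
    with the amplicon's true primer-proximal sequences.
    """
    return LocusTemplate(
        locus_id="HTT_ex1",
        upstream_flank=_HTT_UP_SYNTH,
        downstream_flank=_HTT_DOWN_SYNTH,
        repeat_unit="CAG",
        cassettes=(
            Cassette("caa_interruption", "CAACAG", 1),
            Cassette("ccg_spacer", "CCGCCA", 1),
            Cassette("ccg_tract", "CCG", 7),
            Cassette("cct_tract", "CCT", 2),
        ),
        i_min=i_min,
        i_max=i_max,
    )


def atxn3_exon10_template(i_min: int = 1, i_max: int = MAX_REPEAT_UNITS) -> LocusTemplate:
    """*ATXN3* exon 10 pure CAG tract (synthetic placeholder flanks)."""
    return LocusTemplate(
        locus_id="ATXN3_ex10",
        upstream_flank=_ATXN3_UP_SYNTH,
        downstream_flank=_ATXN3_DOWN_SYNTH,
        repeat_unit="CAG",
        cassettes=(),
        i_min=i_min,
        i_max=i_max,
    )
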