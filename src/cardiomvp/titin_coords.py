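"""Transcript/protein coordinate arithmetic and point-mutation annotation.

Cloning work on giant genes like titin (*TTN*) is described in terms of
transcript fragments — "from bp X to bp Y of accession Z, corresponding to
aa A-aa B".  Both coordinate systems here are 1-based and inclusive, so a
fragment is internally consistent when

    bp_end - bp_start + 1 == 3 * (aa_end - aa_start + 1).

Published fragment tables are not always consistent (typos survive review);
this module checks the 3:1 rule exactly, reports the discrepancy in bp, and
never silently corrects an endpoint.  Accessions are opaque labels — no
sequence is fetched, and the reading frame is anchored by the stated aa_start.

Codon-level point substitutions are annotated with the standard nuclear
codon table and the conventional ``<ref><position><alt>`` protein notation
(e.g. ``D30994N``).
"""

from __future__ import annotations

import dataclasses
import re

__all__ = [
    "TranscriptFragment",
    "MutationCall",
    "FragmentReport",
    "CODON_TABLE",
    "AA_LETTERS",
    "REFERENCE_FRAGMENTS",
    "translate_codon",
    "aa_length_from_bp",
    "infer_aa_end",
    "validate_fragment",
    "apply_point_substitution",
    "format_protein_change",
    "parse_protein_change",
]

_BASES = "TCAG"
# Standard nuclear genetic code in TCAG order; '*' marks stop codons.
_AA_BY_CODON_INDEX = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA_BY_CODON_INDEX[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY*")

_NOTATION_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


class CoordinateInconsistencyError(ValueError):
    """A bp range whose length is not a whole number of codons."""

    def __init__(self, bp_length: int):
        self.bp_length = bp_length
        self.remainder = bp_length % 3
        super().__init__(
            f"bp length {bp_length} is not divisible by 3 (remainder {self.remainder})"
        )


@dataclasses.dataclass(frozen=True)
class TranscriptFragment:
    """A named transcript bp range with its stated protein aa range."""

    name: str
    accession: str
    bp_start: int
    bp_end: int
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if self.bp_end < self.bp_start:
            raise ValueError("bp_end must be >= bp_start")
        if self.aa_end < self.aa_start:
            raise ValueError("aa_end must be >= aa_start")

    @property
    def bp_length(self) -> int:
        return self.bp_end - self.bp_start + 1

    @property
    def aa_length(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclasses.dataclass(frozen=True)
class FragmentReport:
    """Outcome of the 3 bp : 1 aa consistency check."""

    name: str
    bp_length: int
    aa_length: int
    discrepancy_bp: int  # bp_length - 3 * aa_length
    consistent: bool


@dataclasses.dataclass(frozen=True)
class MutationCall:
    """A codon-level point substitution in protein notation."""

    ref_aa: str
    position: int
    alt_aa: str
    ref_codon: str | None = None
    alt_codon: str | None = None

    def __post_init__(self) -> None:
        if self.ref_aa not in AA_LETTERS or self.alt_aa not in AA_LETTERS:
            raise ValueError("amino acids must be single-letter codes")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        for codon, aa in ((self.ref_codon, self.ref_aa), (self.alt_codon, self.alt_aa)):
            if codon is not None and translate_codon(codon) != aa:
                raise ValueError(f"codon {codon} does not encode {aa}")
        if self.ref_codon is not None and self.alt_codon is not None:
            diff = sum(a != b for a, b in zip(self.ref_codon, self.alt_codon))
            if diff != 1:
                raise ValueError("point substitution codons must differ at exactly one base")

    @property
    def notation(self) -> str:
        return format_protein_change(self.ref_aa, self.position, self.alt_aa)

    @property
    def is_stop_gain(self) -> bool:
        return self.alt_aa == "*"


# Bundled reference coordinates for human titin Ig-domain fragments
# (NM_133378) and full-length MURF1 (NM_032588) as published for these
# co-IP constructs.  Two of the printed ranges are internally inconsistent
# under the 3:1 rule; they are kept verbatim so the validator can surface
# exactly that.
REFERENCE_FRAGMENTS: tuple[TranscriptFragment, ...] = (
    TranscriptFragment("A156", "NM_133378", 89426, 89711, 29735, 29829),
    TranscriptFragment("A160-161", "NM_133378", 90626, 91202, 30134, 30326),
    TranscriptFragment("A168", "NM_133378", 93006, 93287, 30928, 31021),
    TranscriptFragment("A169", "NM_133378", 93288, 93581, 31022, 31119),
    TranscriptFragment("A168-170", "NM_133378", 93006, 93908, 30928, 31228),
    TranscriptFragment("MURF1", "NM_032588", 137, 1198, 1, 354),
)


def translate_codon(codon: str) -> str:
    """Standard-table translation of a single codon to a one-letter code."""
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    return CODON_TABLE[codon]


def aa_length_from_bp(bp_start: int, bp_end: int) -> int:
    """Amino-acid count encoded by an inclusive bp range (exact integer)."""
    if bp_end < bp_start:
        raise ValueError("bp_end must be >= bp_start")
    length = bp_end - bp_start + 1
    if length % 3:
        raise CoordinateInconsistencyError(length)
    return length // 3


def infer_aa_end(bp_start: int, bp_end: int, aa_start: int) -> int:
    """Protein end coordinate implied by the bp range and its aa start."""
    return aa_start + aa_length_from_bp(bp_start, bp_end) - 1


def validate_fragment(frag: TranscriptFragment) -> FragmentReport:
    """Check the 3 bp : 1 aa rule; never corrects, only reports."""
    discrepancy = frag.bp_length - 3 * frag.aa_length
    return FragmentReport(
        name=frag.name,
        bp_length=frag.bp_length,
        aa_length=frag.aa_length,
        discrepancy_bp=discrepancy,
        consistent=discrepancy == 0,
    )


def apply_point_substitution(
    codon: str, codon_position: int, new_base: str
) -> tuple[str, str, str]:
    """Substitute one base of a codon; returns (new codon, ref aa, alt aa).

    ``codon_position`` is 1-3.  Substitutions creating a stop codon are
    returned normally ('*'), not raised — a nonsense change is a valid call.
    """
    codon = codon.upper().replace("U", "T")
    new_base = new_base.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon_position not in (1, 2, 3):
        raise ValueError("codon_position must be 1, 2 or 3")
    if new_base not in _BASES:
        raise ValueError(f"invalid base {new_base!r}")
    new_codon = codon[: codon_position - 1] + new_base + codon[codon_position:]
    return new_codon, CODON_TABLE[codon], CODON_TABLE[new_codon]


def format_protein_change(ref_aa: str, position: int, alt_aa: str) -> str:
    """``D30994N``-style notation for a protein point substitution."""
    if ref_aa not in AA_LETTERS or alt_aa not in AA_LETTERS:
        raise ValueError("amino acids must be valid single-letter codes")
    if position < 1:
        raise ValueError("position must be >= 1")
    return f"{ref_aa}{position}{alt_aa}"


def parse_protein_change(notation: str) -> tuple[str, int, str]:
    """Inverse of :func:`format_protein_change`."""
    m = _NOTATION_RE.match(notation)
    if not m or m.group(1) not in AA_LETTERS or m.group(3) not in AA_LETTERS:
        raise ValueError(f"cannot parse protein-change notation {notation!r}")
    return m.group(1), int(m.group(2)), m.group(3)
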