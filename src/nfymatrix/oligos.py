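"""Oligonucleotides and the crystal-structure position numbering.

Competition EMSA oligos are short DNA duplexes given as their top strand.
Positions are referred to by the numbering of the human HSP70 CCAAT
co-crystal oligo, in which the CCAAT pentamer occupies indices N8-N12;
flanking positions run from N5 (-3 relative to CCAAT) to N16 (+4).  Each
:class:`Oligo` carries a ``numbering_offset`` mapping a crystal index N to
its 1-based position in the sequence: ``position = N - numbering_offset``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

__all__ = [
    "CAB2_PROBE",
    "FT_PROBE",
    "CCAAT",
    "CCAAT_START_INDEX",
    "Oligo",
    "CcaatLocation",
    "CcaatNotFoundError",
    "locate_ccaat",
    "base_at",
    "read_oligo_registry",
    "write_oligo_registry",
]

DNA_ALPHABET = frozenset("ACGT")
CCAAT = "CCAAT"
#: crystal index of the first CCAAT base
CCAAT_START_INDEX = 8

#: CAB2 promoter (-65) CCAAT probe, 31-mer top strand
CAB2_PROBE = "CTTAAAATCCAATGAATGAACAGATAAAGAT"
#: FT -5.3 kb enhancer CCAAT probe, 31-mer top strand
FT_PROBE = "GCACTCATCCAATCCTTTATGGAATCTTCTT"


class CcaatNotFoundError(ValueError):
    """The sequence contains no CCAAT pentamer on the top strand."""


class CcaatLocation(NamedTuple):
    start: int  # 1-based position of the first C
    count: int  # number of CCAAT occurrences


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("oligo sequence must be non-empty")
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise ValueError(
            f"oligo sequence must be uppercase over A/C/G/T, found {sorted(bad)}"
        )


def locate_ccaat(sequence: str) -> CcaatLocation:
    """Locate the first exact CCAAT on the top strand of ``sequence``.

    Returns the 1-based start of the first occurrence together with the
    total occurrence count.  Raises :class:`CcaatNotFoundError` when the
    pentamer is absent.
    """
    _validate_sequence(sequence)
    first = sequence.find(CCAAT)
    if first < 0:
        raise CcaatNotFoundError(f"no CCAAT in sequence {sequence!r}")
    count = 0
    pos = first
    while pos >= 0:
        count += 1
        pos = sequence.find(CCAAT, pos + 1)
    return CcaatLocation(start=first + 1, count=count)


@dataclass(frozen=True)
class Oligo:
    """A named competition-EMSA oligo (top strand) with crystal numbering.

    ``numbering_offset`` maps crystal index N to the 1-based sequence
    position ``N - numbering_offset``.  For the CAB2 probe the CCAAT starts
    at sequence position 9, so the offset is -1 (N8 -> position 9).
    """

    id: str
    sequence: str
    role: str = "competitor"  # "probe" | "competitor"
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if self.role not in ("probe", "competitor"):
            raise ValueError(f"role must be 'probe' or 'competitor', got {self.role!r}")

    @classmethod
    def from_ccaat_anchor(cls, id: str, sequence: str, role: str = "competitor") -> "Oligo":
        """Build an oligo whose numbering is anchored on its unique CCAAT.

        The offset is chosen so the first CCAAT base sits at crystal index 8.
        """
        loc = locate_ccaat(sequence)
        return cls(id=id, sequence=sequence, role=role,
                   numbering_offset=CCAAT_START_INDEX - loc.start)

    def position_of(self, crystal_index: int) -> int:
        """1-based sequence position of crystal index N."""
        return crystal_index - self.numbering_offset

    def __len__(self) -> int:
        return len(self.sequence)


def base_at(oligo: Oligo, crystal_index: int) -> str:
    """Base of ``oligo`` at crystal index N (1-based crystal numbering)."""
    pos = oligo.position_of(crystal_index)
    if not 1 <= pos <= len(oligo.sequence):
        raise IndexError(
            f"crystal index {crystal_index} maps to position {pos}, outside "
            f"1..{len(oligo.sequence)} of oligo {oligo.id!r}"
        )
    return oligo.sequence[pos - 1]


def read_oligo_registry(path) -> dict[str, Oligo]:
    """Read an oligo registry TSV (columns: id, sequence, role, numbering_offset)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str, "role": str})
    oligos: dict[str, Oligo] = {}
    for row in df.itertuples(index=False):
        oligos[row.id] = Oligo(
            id=row.id,
            sequence=row.sequence,
            role=row.role,
            numbering_offset=int(row.numbering_offset),
        )
    return oligos


def write_oligo_registry(oligos, path) -> None:
    rows = [
        {
            "id": o.id,
            "sequence": o.sequence,
            "role": o.role,
            "numbering_offset": o.numbering_offset,
        }
        for o in (oligos.values() if isinstance(oligos, dict) else oligos)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
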