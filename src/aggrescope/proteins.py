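"""Bookkeeping for the poison/antidote protein architecture.

The two proteins of the driver are encoded on largely overlapping coding
sequences: the antidote carries an extra N-terminal stretch (encoded by its
own first exon) and shares its entire remaining C-terminal sequence with
the poison.  A short amino-acid motif (IGNAFRG, 7 residues) is tandemly
repeated near the C-terminus; matching repeat counts between a poison and
an antidote are required for their co-assembly, and repeat-insertion
mutants change the count.
"""

from __future__ import annotations

import math

__all__ = [
    "REPEAT_UNIT",
    "shared_residue_count",
    "repeat_unit_count",
]

REPEAT_UNIT = "IGNAFRG"  # the 7-residue C-terminal repeat motif


def shared_residue_count(antidote_length: int, nterminal_extension: int) -> int:
    """Residues the poison shares with the antidote.

    The poison is the antidote minus its antidote-specific N-terminal
    extension, so the shared count is the difference of the two lengths
    (e.g. a 337-residue antidote with a 45-residue extension shares 292
    residues with the poison).
    """
    if nterminal_extension < 0 or antidote_length <= nterminal_extension:
        raise ValueError("extension must be >= 0 and shorter than the antidote")
    return antidote_length - nterminal_extension


def repeat_unit_count(
    base_units: float = 1.5,
    inserted_codons: int = 0,
    unit_length: int = len(REPEAT_UNIT),
) -> int:
    """Whole repeat units present after inserting codons into the repeat region.

    The wild-type allele carries ~1.5 units of the 7-residue motif;
    inserting 18 codons brings the region to four complete units
    (floor((1.5*7 + 18)/7) = 4).
    """
    if base_units < 0 or inserted_codons < 0 or unit_length <= 0:
        raise ValueError("repeat geometry must be non-negative with unit_length > 0")
    total_residues = base_units * unit_length + inserted_codons
    return math.floor(total_residues / unit_length)
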