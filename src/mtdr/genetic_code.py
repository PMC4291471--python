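"""Standard genetic-code constants shared across the package.

Derived from Biopython's standard (table 1) codon table so the 61 sense
codons, the stop codons, and the synonymous families never have to be
typed by hand.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The three stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons, sorted alphabetically (deterministic ordering is
#: relied on by the simulator and output tables).
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: codon -> one-letter amino acid.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: amino acid -> tuple of synonymous codons (sorted).
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: Codons that are their amino acid's only codon (ATG/Met, TGG/Trp).
SINGLE_CODON_FAMILY: frozenset[str] = frozenset(
    codons[0] for codons in SYNONYMOUS_FAMILIES.values() if len(codons) == 1
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (used for codon<->anticodon)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iter_codons(sequence: str) -> list[str]:
    """Split an in-frame nucleotide sequence into consecutive codons."""
    if len(sequence) % 3:
        raise ValueError(f"sequence length {len(sequence)} is not a multiple of 3")
    return [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
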