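"""Genetic-code constants shared by the codon-evolution machinery.

Universal (translation table 1) code only; the table is a package-level
constant, not a per-call option.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
NUCLEOTIDES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], []).append(_codon)
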