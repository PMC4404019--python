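"""Standard genetic code with synonymous-family bookkeeping.

Codons are represented in the RNA alphabet (``AUG``) everywhere in this
package; FASTA input is DNA and is transliterated on ingestion.  The three
stop codons are grouped as a synonymous family under the label ``TER`` so
that termination usage can be analysed alongside the amino-acid families.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

RNA_BASES = "ACGU"

#: The 64 codons in lexicographic (A<C<G<U) order; fixed axis order for all
#: per-codon vectors and 64x64 pair matrices in this package.
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Label of the translation-termination (stop) family UAA/UAG/UGA.
TER = "TER"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus synonymous family sizes.

    Attributes
    ----------
    codon_to_aa:
        Maps each of the 64 RNA codons to a 1-letter amino acid, or ``TER``
        for stop codons.
    family_size:
        Number of synonymous codons per amino acid (the ``n_i`` of the RSCU
        statistic); Met and Trp are 1, stop (TER) is 3 in the standard code.
    families:
        Amino acid -> sorted tuple of its synonymous codons.
    """

    codon_to_aa: dict[str, str]
    family_size: dict[str, int]
    families: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("a genetic code must map exactly 64 codons")
        if sum(self.family_size.values()) != 64:
            raise ValueError("family sizes must sum to 64")

    @classmethod
    def standard(cls) -> "GeneticCode":
        """The standard genetic code (NCBI translation table 1)."""
        table = CodonTable.unambiguous_rna_by_id[1]
        codon_to_aa = {}
        for codon in CODONS:
            if codon in table.stop_codons:
                codon_to_aa[codon] = TER
            else:
                codon_to_aa[codon] = table.forward_table[codon]
        families: dict[str, list[str]] = {}
        for codon, aa in codon_to_aa.items():
            families.setdefault(aa, []).append(codon)
        frozen = {aa: tuple(sorted(cods)) for aa, cods in families.items()}
        sizes = {aa: len(cods) for aa, cods in frozen.items()}
        return cls(codon_to_aa, sizes, frozen)

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def aa_name(self, aa: str) -> str:
        """3-letter display name (``Ala``, ``Met``, ``TER``)."""
        return TER if aa == TER else seq3(aa)

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[TER]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """The 61 non-stop codons, in the global CODONS order."""
        return tuple(c for c in CODONS if self.codon_to_aa[c] != TER)


#: Shared default instance.
STANDARD_CODE = GeneticCode.standard()
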