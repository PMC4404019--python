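"""Relative synonymous codon usage (RSCU) over groups of ORFs.

RSCU for codon j of amino acid i is x_ij * n_i / sum_j x_ij, where x_ij is
the codon count pooled over the whole group and n_i the synonymous family
size.  RSCU is 1 for every codon under uniform synonymous usage and equals
n_i when one codon is used exclusively; single-codon families (Met, Trp)
are always exactly 1.

Group RSCU is computed on pooled (concatenated) counts, not averaged per
gene, matching the dataset-level convention of CodonW.  Stop codons form a
3-codon TER family included like any other; the start codon is counted (it
only affects Met, whose RSCU is forced to 1 anyway).  A family with zero
total has undefined (NaN) RSCU — never 0 — so ratio maps stay honest on
small groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genetic_code import CODONS, GeneticCode, STANDARD_CODE
from .sequences import OrfSet, codons_of

MOST_COMMON = "most common"
INTERMEDIATE = "intermediate"
LESS_FREQUENT = "less frequent"

#: RSCU below this is classed "less frequent"; display cutoff only.
LESS_FREQUENT_CUTOFF = 0.5

#: RSCU ratios within this band count as "similar" between two groups.
SIMILARITY_BAND = (0.9, 1.1)


def count_codons(orfs: OrfSet, member_ids: Iterable[str] | None = None) -> pd.Series:
    """Pooled per-codon counts over a group of ORFs (all 64 codons).

    ``member_ids`` has set semantics: duplicated ids count once.
    """
    if member_ids is None:
        members = list(orfs)
    else:
        wanted = set(member_ids)
        members = [rec for rec in orfs if rec.orf_id in wanted]
    if not members:
        raise ValueError("empty member set")
    counts = dict.fromkeys(CODONS, 0)
    for rec in members:
        for codon in codons_of(rec):
            counts[codon] += 1
    return pd.Series(counts, name="count")


@dataclass
class RscuTable:
    """Per-codon counts and RSCU values for one group of ORFs."""

    group_label: str
    counts: pd.Series
    rscu: pd.Series
    code: GeneticCode
    total_codons: int

    def classes(self) -> pd.Series:
        return preference_classes(self)

    def to_frame(self) -> pd.DataFrame:
        """Long table: amino_acid, codon, count, rscu, class."""
        classes = self.classes()
        rows = []
        for aa in sorted(self.code.families, key=self.code.aa_name):
            for codon in self.code.families[aa]:
                rows.append((self.code.aa_name(aa), codon,
                             int(self.counts[codon]),
                             self.rscu[codon], classes[codon]))
        return pd.DataFrame(rows, columns=["amino_acid", "codon", "count", "rscu", "class"])

    def to_tsv(self, path: "Path | str") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def rscu_table(
    counts: pd.Series,
    code: GeneticCode = STANDARD_CODE,
    group_label: str = "",
) -> RscuTable:
    """Compute RSCU from pooled per-codon counts."""
    missing = set(CODONS) - set(counts.index)
    if missing:
        raise ValueError(f"counts must cover all 64 codons; missing {sorted(missing)[:3]}")
    rscu = pd.Series(np.nan, index=list(CODONS), name="rscu")
    for aa, family in code.families.items():
        total = counts[list(family)].sum()
        if total > 0:
            n_i = code.family_size[aa]
            rscu[list(family)] = counts[list(family)] * n_i / total
    return RscuTable(group_label, counts.reindex(list(CODONS)).astype(int),
                     rscu, code, int(counts.sum()))


def preference_classes(table: RscuTable) -> pd.Series:
    """Per-codon usage class within its synonymous family.

    The family argmax (all of them, on ties) is "most common"; codons with
    RSCU < 0.5 are "less frequent"; the rest are "intermediate".  Families
    with undefined RSCU get None.
    """
    classes = pd.Series([None] * 64, index=list(CODONS), dtype=object)
    for aa, family in table.code.families.items():
        values = table.rscu[list(family)]
        if values.isna().any():
            continue
        top = values.max()
        for codon in family:
            if values[codon] == top:
                classes[codon] = MOST_COMMON
            elif values[codon] < LESS_FREQUENT_CUTOFF:
                classes[codon] = LESS_FREQUENT
            else:
                classes[codon] = INTERMEDIATE
    return classes


@dataclass
class RatioMap:
    """Per-codon RSCU ratios between two groups with a similarity flag.

    ``similar`` is true iff the ratio lies in [0.9, 1.1]; undefined ratios
    (either RSCU undefined, or denominator 0) are NaN and never similar.
    """

    numerator_label: str
    denominator_label: str
    ratio: pd.Series
    similar: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"codon": list(CODONS),
                             "ratio": self.ratio.values,
                             "similar": self.similar.values})

    def to_tsv(self, path: "Path | str") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def ratio_map(
    a: RscuTable,
    b: RscuTable,
    band: tuple[float, float] = SIMILARITY_BAND,
) -> RatioMap:
    """Codon-wise RSCU ratio a/b with the similarity band flag."""
    if a.code is not b.code and a.code.codon_to_aa != b.code.codon_to_aa:
        raise ValueError("ratio_map requires tables on the same genetic code")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = a.rscu.to_numpy() / b.rscu.to_numpy()
    ratio = pd.Series(np.where(np.isfinite(raw), raw, np.nan), index=list(CODONS))
    similar = (ratio >= band[0]) & (ratio <= band[1])
    return RatioMap(a.group_label, b.group_label, ratio, similar.fillna(False))
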