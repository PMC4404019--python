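"""RPKM computation and expression-level grouping of ORFs.

The four culture conditions are glucose/succinate at 18 h (exponential) and
72 h (stationary): G18, S18, G72, S72.  ORFs are stratified by RPKM either
per condition (EC), by the highest value across conditions (HV) or by the
average (AV); ribosomal ORFs form a separate reference group (R).

Bin edges realise the printed integer ranges 1-30 / 31-70 / 71-100 /
101-999 / >=1000 as half-open real intervals [1,31), [31,71), [71,101),
[101,1000), [1000,inf) so that non-integer RPKM values are assignable.
ORFs whose statistic falls below 1 RPKM are left unassigned rather than
forced into the lowest bin.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed condition order; also the tie-break order for argmax/argmin labels.
CONDITIONS: tuple[str, ...] = ("G18", "S18", "G72", "S72")

SCHEMES = ("EC", "HV", "AV")

BIN_EDGES = (1.0, 31.0, 71.0, 101.0, 1000.0, math.inf)
BIN_LABELS = ("1-30", "31-70", "71-100", "101-999", "≥1000")
RIBOSOMAL_BIN = "R"

SUMMARY_EDGES = (1.0, 31.0, 101.0, math.inf)
SUMMARY_LABELS = ("1-30", "31-100", ">100")

FOLD_EDGES = (1.0, 2.0, 5.0, 10.0, 50.0, math.inf)
FOLD_LABELS = ("1-2", "2.1-5", "5.1-10", "10.1-50", ">50")


def compute_rpkm(reads: float, library_size: float, length: float) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = 10^9 * C / (N * L) with C the reads mapped to the ORF, N the total
    mapped reads in the library and L the ORF length in nt.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if length <= 0:
        raise ValueError("length must be positive")
    return 1.0e9 * reads / (library_size * length)


class ExpressionMatrix:
    """Per-ORF RPKM across the four named conditions.

    Wraps a DataFrame indexed by orf_id with columns G18, S18, G72, S72.
    """

    def __init__(self, rpkm: pd.DataFrame):
        missing = [c for c in CONDITIONS if c not in rpkm.columns]
        if missing:
            raise ValueError(f"missing condition columns: {missing}")
        df = rpkm.loc[:, list(CONDITIONS)].astype(float)
        if df.index.has_duplicates:
            raise ValueError("duplicate orf_id values")
        if df.isna().any().any():
            raise ValueError("missing RPKM values")
        if (df.to_numpy() < 0).any():
            raise ValueError("RPKM values must be >= 0")
        df.index.name = "orf_id"
        self.rpkm = df

    def __len__(self) -> int:
        return len(self.rpkm)

    @property
    def orf_ids(self) -> list[str]:
        return list(self.rpkm.index)

    def restrict(self, ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [i for i in self.orf_ids if i in set(ids)]
        return ExpressionMatrix(self.rpkm.loc[keep])

    def statistic(self, scheme: str, condition: str | None = None) -> pd.Series:
        """The per-ORF value each grouping scheme bins on."""
        if scheme == "EC":
            if condition not in CONDITIONS:
                raise ValueError(f"EC grouping needs a condition from {CONDITIONS}")
            return self.rpkm[condition]
        if scheme == "HV":
            return self.rpkm.max(axis=1)
        if scheme == "AV":
            return self.rpkm.mean(axis=1)
        raise ValueError(f"unknown grouping scheme {scheme!r}")

    @classmethod
    def from_counts(
        cls,
        reads: pd.DataFrame,
        library_sizes: Mapping[str, float],
        lengths: Mapping[str, float],
    ) -> "ExpressionMatrix":
        """Build RPKM from raw mapped-read counts.

        ``reads`` is indexed by orf_id with the four condition columns;
        ``library_sizes`` gives total mapped reads per condition and
        ``lengths`` the ORF length in nt.
        """
        L = pd.Series({oid: float(lengths[oid]) for oid in reads.index})
        data = {
            cond: 1.0e9 * reads[cond].astype(float) / (float(library_sizes[cond]) * L)
            for cond in CONDITIONS
        }
        return cls(pd.DataFrame(data, index=reads.index))

    @classmethod
    def from_tsv(cls, path: "Path | str") -> "ExpressionMatrix":
        """Read an expression TSV.

        Either columns ``orf_id, rpkm_G18, rpkm_S18, rpkm_G72, rpkm_S72``, or
        raw counts ``reads_*`` plus ``length_nt`` preceded by a comment header
        line ``#library_sizes G18=<N> S18=<N> G72=<N> S72=<N>``.
        """
        sizes: dict[str, float] = {}
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#library_sizes"):
            for tok in first.split()[1:]:
                cond, val = tok.split("=")
                sizes[cond] = float(val)
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("orf_id")
        if all(f"rpkm_{c}" in df.columns for c in CONDITIONS):
            rpkm = df[[f"rpkm_{c}" for c in CONDITIONS]]
            rpkm.columns = list(CONDITIONS)
            return cls(rpkm)
        if all(f"reads_{c}" in df.columns for c in CONDITIONS):
            if not sizes:
                raise ValueError("reads_* columns need a #library_sizes header")
            if "length_nt" not in df.columns:
                raise ValueError("reads_* columns need a length_nt column")
            reads = df[[f"reads_{c}" for c in CONDITIONS]]
            reads.columns = list(CONDITIONS)
            return cls.from_counts(reads, sizes, df["length_nt"])
        raise ValueError("expected rpkm_* or reads_* condition columns")

    def to_tsv(self, path: "Path | str") -> None:
        out = self.rpkm.copy()
        out.columns = [f"rpkm_{c}" for c in CONDITIONS]
        out.to_csv(path, sep="\t", index_label="orf_id")


def _bin_of(value: float) -> str | None:
    if value < BIN_EDGES[0]:
        return None
    for lo, hi, label in zip(BIN_EDGES[:-1], BIN_EDGES[1:], BIN_LABELS):
        if lo <= value < hi:
            return label
    return None  # unreachable


def assign_bins(
    matrix: ExpressionMatrix,
    scheme: str = "HV",
    ribosomal_ids: Iterable[str] = (),
    condition: str | None = None,
) -> pd.DataFrame:
    """Assign every ORF to an expression bin under one grouping scheme.

    Returns a DataFrame indexed by orf_id with columns ``scheme``,
    ``statistic`` and ``bin``.  Ribosomal ORFs go to bin "R" regardless of
    expression; ORFs with statistic < 1 RPKM get bin ``None`` (unassigned).
    """
    ribo = set(ribosomal_ids)
    unknown = ribo - set(matrix.orf_ids)
    if unknown:
        raise ValueError(f"ribosomal ids not in matrix: {sorted(unknown)[:5]}")
    stat = matrix.statistic(scheme, condition)
    label = scheme if scheme != "EC" else f"EC({condition})"
    rows = []
    for oid, value in stat.items():
        if oid in ribo:
            bin_ = RIBOSOMAL_BIN
        else:
            bin_ = _bin_of(float(value))
            if bin_ is None:
                logger.debug("ORF %s unassigned (%s statistic %.3g < 1)", oid, label, value)
        rows.append((oid, label, float(value), bin_))
    out = pd.DataFrame(rows, columns=["orf_id", "scheme", "statistic", "bin"])
    return out.set_index("orf_id")


def group_members(assignments: pd.DataFrame) -> dict[str, list[str]]:
    """Bin label -> ordered member ids (unassigned ORFs dropped)."""
    groups: dict[str, list[str]] = {}
    for oid, row in assignments.iterrows():
        if row["bin"] is not None:
            groups.setdefault(row["bin"], []).append(oid)
    return groups


def summary_bins(
    matrix: ExpressionMatrix,
    basis: str = "highest",
    denominator: str = "assigned",
) -> pd.DataFrame | pd.Series:
    """Percentages of ORFs in the coarse bins 1-30 / 31-100 / >100 RPKM.

    ``basis`` is "highest" (max across conditions, one Series) or
    "per-condition" (a DataFrame with one row per condition).  With
    ``denominator="assigned"`` percentages are over ORFs at >=1 RPKM (and sum
    to 100); "all" divides by every ORF in the matrix instead.
    """
    if len(matrix) == 0:
        raise ValueError("empty expression matrix")
    if denominator not in ("assigned", "all"):
        raise ValueError("denominator must be 'assigned' or 'all'")

    def _one(values: pd.Series) -> pd.Series:
        v = values.to_numpy(dtype=float)
        counts = np.histogram(v[v >= SUMMARY_EDGES[0]], bins=SUMMARY_EDGES)[0]
        denom = counts.sum() if denominator == "assigned" else len(v)
        pct = 100.0 * counts / denom if denom else np.zeros(3)
        return pd.Series(pct, index=list(SUMMARY_LABELS))

    if basis == "highest":
        return _one(matrix.statistic("HV"))
    if basis == "per-condition":
        return pd.DataFrame({c: _one(matrix.rpkm[c]) for c in CONDITIONS}).T
    raise ValueError("basis must be 'highest' or 'per-condition'")


def fold_changes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Max/min RPKM ratio per ORF with the conditions where they occur.

    Columns: ``ratio`` (NaN when any condition value is 0, flagged undefined),
    ``max_condition``, ``min_condition`` and the display ``label``
    ``[max/min]``.  Ties take the first condition in G18,S18,G72,S72 order.
    """
    values = matrix.rpkm.to_numpy(dtype=float)
    imax = values.argmax(axis=1)
    imin = values.argmin(axis=1)
    vmax = values[np.arange(len(values)), imax]
    vmin = values[np.arange(len(values)), imin]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vmin > 0, vmax / vmin, np.nan)
    maxc = [CONDITIONS[i] for i in imax]
    minc = [CONDITIONS[i] for i in imin]
    return pd.DataFrame(
        {
            "ratio": ratio,
            "max_condition": maxc,
            "min_condition": minc,
            "label": [f"[{a}/{b}]" for a, b in zip(maxc, minc)],
        },
        index=matrix.rpkm.index,
    )


def fold_change_bins(ratios: pd.Series) -> pd.Series:
    """Percentages of ORFs per fold-change bin 1-2 / 2.1-5 / 5.1-10 / 10.1-50 / >50.

    Bins are upper-inclusive: [1,2], (2,5], (5,10], (10,50], (50,inf),
    matching the printed decimal labels.  NaN ratios are excluded.
    """
    r = ratios.dropna()
    if (r < 1).any():
        raise ValueError("fold-change ratios must be >= 1")
    cut = pd.cut(r, bins=list(FOLD_EDGES), labels=list(FOLD_LABELS),
                 right=True, include_lowest=True)
    counts = cut.value_counts().reindex(list(FOLD_LABELS)).fillna(0)
    return 100.0 * counts / len(r) if len(r) else counts.astype(float)


def normalized_display(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Each ORF's four values divided by its minimum across conditions.

    Rows with any zero value are undefined and dropped (logged); the argmin
    condition maps to exactly 1 in every kept row.
    """
    df = matrix.rpkm
    bad = (df <= 0).any(axis=1)
    if bad.any():
        logger.warning("dropping %d ORFs with zero RPKM from normalized display",
                       int(bad.sum()))
    kept = df.loc[~bad]
    return kept.div(kept.min(axis=1), axis=0)
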