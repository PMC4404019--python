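"""3' codon-context (codon-pair) bias via contingency-table adjusted residuals.

Adjacent in-frame codon pairs within each ORF are tabulated into a 64x64
contingency table (5' codon = row, 3' codon = column).  Under independence
of neighbours the expected count is e_pq = row_p * col_q / N; the adjusted
residual

    r_pq = (o_pq - e_pq) / sqrt(e_pq * (1 - p_p) * (1 - q_q))

(p_p, q_q the marginal proportions) is approximately standard normal, so
|r| > 3 flags a biased pair: positive residuals are preferred ("good")
3' contexts, negative ones avoided ("bad") contexts.

Pairs never span two ORFs; the first codon participates only as a 5'
member and the terminal stop codon only as a 3' member.  Stop-containing
pairs are counted by default (switchable).  A plain Pearson residual mode
((o-e)/sqrt(e)) is available for sensitivity analysis, and a Bonferroni
threshold helper is provided, but the default significance rule is the
plain +/-3 band with no multiplicity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import CODON_INDEX, CODONS, STANDARD_CODE, TER
from .sequences import OrfSet, codons_of

logger = logging.getLogger(__name__)

#: Default significance band half-width on adjusted residuals.
BIAS_THRESHOLD = 3.0

PREFERRED = "preferred"
AVOIDED = "avoided"
NO_BIAS = "no-bias"

_STOP_IDX = np.array([CODON_INDEX[c] for c in STANDARD_CODE.stop_codons])


def pair_counts(
    orfs: OrfSet,
    member_ids: Iterable[str] | None = None,
    include_stop: bool = True,
) -> np.ndarray:
    """64x64 observed counts of adjacent codon pairs over a group of ORFs.

    Each ORF of k codons contributes exactly k-1 ordered pairs.  With
    ``include_stop=False`` pairs containing a stop codon are dropped.
    """
    if member_ids is None:
        members = list(orfs)
    else:
        wanted = set(member_ids)
        members = [rec for rec in orfs if rec.orf_id in wanted]
    if not members:
        raise ValueError("empty member set")
    observed = np.zeros((64, 64), dtype=np.int64)
    for rec in members:
        idx = np.array([CODON_INDEX[c] for c in codons_of(rec)], dtype=np.intp)
        np.add.at(observed, (idx[:-1], idx[1:]), 1)
    if not include_stop:
        observed[_STOP_IDX, :] = 0
        observed[:, _STOP_IDX] = 0
    return observed


def expected_counts(observed: np.ndarray) -> np.ndarray:
    """Expected counts under independence: e_pq = row_p * col_q / N."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty observed table")
    return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n


def adjusted_residuals(
    observed: np.ndarray,
    expected: np.ndarray | None = None,
    mode: str = "adjusted",
) -> np.ndarray:
    """Cell-wise residuals of the contingency table; NaN where e_pq = 0.

    ``mode="adjusted"`` divides by sqrt(e(1-p)(1-q)); ``mode="pearson"``
    divides by sqrt(e) only.
    """
    obs = np.asarray(observed, dtype=float)
    exp = expected_counts(obs) if expected is None else np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected shapes differ")
    n = obs.sum()
    p = obs.sum(axis=1) / n
    q = obs.sum(axis=0) / n
    if mode == "adjusted":
        denom_sq = exp * np.outer(1.0 - p, 1.0 - q)
    elif mode == "pearson":
        denom_sq = exp
    else:
        raise ValueError(f"unknown residual mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (obs - exp) / np.sqrt(denom_sq)
    r[exp == 0] = np.nan
    # a row or column covering everything makes 1-p or 1-q zero -> undefined
    r[~np.isfinite(r)] = np.nan
    return r


@dataclass
class PairContextTable:
    """Observed/expected/residual 64x64 matrices for one group of ORFs."""

    group_label: str
    observed: np.ndarray
    expected: np.ndarray
    residual: np.ndarray
    mode: str = "adjusted"

    @property
    def n_pairs(self) -> int:
        return int(self.observed.sum())

    @classmethod
    def build(
        cls,
        orfs: OrfSet,
        member_ids: Iterable[str] | None = None,
        group_label: str = "",
        include_stop: bool = True,
        mode: str = "adjusted",
    ) -> "PairContextTable":
        obs = pair_counts(orfs, member_ids, include_stop=include_stop)
        exp = expected_counts(obs)
        res = adjusted_residuals(obs, exp, mode=mode)
        return cls(group_label, obs, exp, res, mode)

    def to_frame(self) -> pd.DataFrame:
        """Long format: codon5, codon3, observed, expected, residual, call."""
        calls = bias_calls(self)
        return calls

    def to_tsv(self, path: "Path | str") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def bias_calls(table: PairContextTable, threshold: float = BIAS_THRESHOLD) -> pd.DataFrame:
    """Classify every defined cell as preferred / avoided / no-bias.

    Residuals strictly above +threshold are preferred, strictly below
    -threshold avoided; the closed band [-threshold, +threshold] is no-bias.
    """
    p_idx, q_idx = np.nonzero(~np.isnan(table.residual))
    res = table.residual[p_idx, q_idx]
    call = np.where(res > threshold, PREFERRED,
                    np.where(res < -threshold, AVOIDED, NO_BIAS))
    return pd.DataFrame({
        "codon5": [CODONS[i] for i in p_idx],
        "codon3": [CODONS[j] for j in q_idx],
        "observed": table.observed[p_idx, q_idx],
        "expected": table.expected[p_idx, q_idx],
        "residual": res,
        "call": call,
    })


def top_pairs(table: PairContextTable, k: int = 5, direction: str = PREFERRED) -> pd.DataFrame:
    """The k most preferred (largest residual) or avoided (smallest) pairs.

    Ties are broken lexicographically on (codon5, codon3).  If k exceeds the
    number of defined cells, all are returned (logged).
    """
    if direction not in (PREFERRED, AVOIDED):
        raise ValueError("direction must be 'preferred' or 'avoided'")
    cells = bias_calls(table, threshold=BIAS_THRESHOLD)
    if k > len(cells):
        logger.warning("top_pairs: k=%d exceeds %d defined cells", k, len(cells))
        k = len(cells)
    ascending = direction == AVOIDED
    ranked = cells.sort_values(
        ["residual", "codon5", "codon3"],
        ascending=[ascending, True, True],
    ).head(k)
    return ranked.reset_index(drop=True)


@dataclass
class DifferentialMap:
    """Cell-wise residual differences between two groups' context tables.

    ``similar`` is true where |residual_a - residual_b| <= band; cells
    undefined in either table stay NaN and are flagged not similar.
    """

    label_a: str
    label_b: str
    delta: np.ndarray
    similar: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        p_idx, q_idx = np.nonzero(~np.isnan(self.delta))
        return pd.DataFrame({
            "codon5": [CODONS[i] for i in p_idx],
            "codon3": [CODONS[j] for j in q_idx],
            "delta": self.delta[p_idx, q_idx],
            "similar": self.similar[p_idx, q_idx],
        })

    def to_tsv(self, path: "Path | str") -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def differential_map(
    a: PairContextTable,
    b: PairContextTable,
    band: float = BIAS_THRESHOLD,
) -> DifferentialMap:
    """Compare two context tables cell by cell on the residual scale."""
    if a.observed.shape != b.observed.shape:
        raise ValueError("tables must share the 64x64 grid")
    delta = a.residual - b.residual
    with np.errstate(invalid="ignore"):
        similar = np.abs(delta) <= band
    similar[np.isnan(delta)] = False
    return DifferentialMap(a.group_label, b.group_label, delta, similar)


def bonferroni_threshold(alpha: float = 0.05, n_cells: int = 64 * 64) -> float:
    """Two-sided normal threshold after Bonferroni correction over n_cells."""
    return float(stats.norm.isf(alpha / (2 * n_cells)))
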