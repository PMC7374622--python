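"""Pairwise comparison of sparse predictors.

Two predictors trained on different traits may re-use the same DNA regions.
SNPs from the row and column predictors less than 4,000 bp apart (strict)
are identified with one another — close enough that high-LD pairs tag the
same signal. Two statistics follow:

* count overlap — the percentage of row-predictor SNPs with at least one
  column match;
* sign-weighted variance overlap ``r~`` — each matched column SNP gets a
  weight of uniform magnitude 1 signed by the product of effect-size signs;
  the weights multiply the row SNP's variance ``2 beta^2 (1-f) f`` and the
  sum is normalized by the row predictor's total variance. ``r~`` can be
  negative, and can exceed 100% in magnitude when a row SNP has several
  matches (summed literally, never clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Predictor, PredictorSNP
from .variance import snp_variance

__all__ = [
    "ProximityMatch",
    "OverlapMatrix",
    "find_matches",
    "count_overlap_percent",
    "signed_variance_overlap",
    "overlap_matrices",
    "restrict_top",
]

DEFAULT_WINDOW = 4000


@dataclass
class ProximityMatch:
    """Per row-SNP index, the column-SNP indices within the window."""

    window: int
    matches: list[np.ndarray]

    @property
    def matched_mask(self) -> np.ndarray:
        return np.array([m.size > 0 for m in self.matches], dtype=bool)

    def multi_match_rows(self) -> list[int]:
        """Row indices with more than one column match (|r~| may exceed 100%)."""
        return [i for i, m in enumerate(self.matches) if m.size > 1]


def find_matches(
    row: Predictor, col: Predictor, window: int = DEFAULT_WINDOW
) -> ProximityMatch:
    """Column SNPs strictly closer than ``window`` bp to each row SNP.

    Matching is per-chromosome on positions; a row SNP may match several
    column SNPs.
    """
    if window < 0:
        raise ValidationError(f"window must be >= 0, got {window}")
    col_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = col.chromosomes
    positions = col.positions
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        order = np.argsort(positions[sel], kind="stable")
        col_by_chrom[chrom] = (positions[sel][order], sel[order])
    matches: list[np.ndarray] = []
    for s in row.snps:
        entry = col_by_chrom.get(s.chromosome)
        if entry is None:
            matches.append(np.empty(0, dtype=np.int64))
            continue
        cpos, cidx = entry
        # |pos_row - pos_col| < window  <=>  pos_col in (pos-window, pos+window)
        lo = np.searchsorted(cpos, s.position - window, side="right")
        hi = np.searchsorted(cpos, s.position + window, side="left")
        matches.append(cidx[lo:hi])
    return ProximityMatch(window=window, matches=matches)


def count_overlap_percent(
    row: Predictor, col: Predictor, window: int = DEFAULT_WINDOW
) -> float:
    """Percent of row-predictor SNPs with a column SNP within the window."""
    pm = find_matches(row, col, window)
    return 100.0 * pm.matched_mask.mean()


def _sign_pair(row_snp: PredictorSNP, col_snp: PredictorSNP) -> float:
    sign = np.sign(row_snp.beta * col_snp.beta)
    # opposite counted alleles flip the column effect's direction
    if (
        row_snp.counted_allele is not None
        and col_snp.counted_allele is not None
        and row_snp.counted_allele != col_snp.counted_allele
    ):
        sign = -sign
    return float(sign)


def signed_variance_overlap(
    row: Predictor, col: Predictor, window: int = DEFAULT_WINDOW
) -> float:
    """Sign-weighted variance overlap ``r~`` of two predictors, in percent.

    r~ = 100 * sum_i sum_{j in C_i} sgn(beta_i beta_j) * v_i / sum_i v_i,
    with ``v_i = 2 beta_i^2 (1-f_i) f_i`` the ROW SNP's variance and ``C_i``
    the column SNPs within the window. Only the signs of the column betas
    enter, so r~ is invariant under positive rescaling of the column
    predictor.
    """
    pm = find_matches(row, col, window)
    v = snp_variance(row.betas, row.mafs)
    signed = np.array(
        [
            v[i] * sum(_sign_pair(row.snps[i], col.snps[j]) for j in cols)
            for i, cols in enumerate(pm.matches)
        ]
    )
    return 100.0 * float(np.sum(signed) / np.sum(v))


@dataclass
class OverlapMatrix:
    """Phenotype x phenotype overlap matrices (generally asymmetric).

    ``count`` holds the percent of row SNPs matched by the column predictor
    (diagonal 100 by construction); ``signed_variance`` holds r~ in percent,
    normalized per row. Row labels name the row predictor.
    """

    count: pd.DataFrame
    signed_variance: pd.DataFrame


def overlap_matrices(
    predictors: list[Predictor], window: int = DEFAULT_WINDOW
) -> OverlapMatrix:
    """Both overlap matrices over all ordered pairs of predictors."""
    if len(predictors) < 2:
        raise ValidationError("need at least two predictors")
    names = [p.phenotype for p in predictors]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate phenotype names in {names}")
    n = len(predictors)
    counts = np.empty((n, n))
    signed = np.empty((n, n))
    for i, prow in enumerate(predictors):
        for j, pcol in enumerate(predictors):
            counts[i, j] = count_overlap_percent(prow, pcol, window)
            signed[i, j] = signed_variance_overlap(prow, pcol, window)
    return OverlapMatrix(
        count=pd.DataFrame(counts, index=names, columns=names),
        signed_variance=pd.DataFrame(signed, index=names, columns=names),
    )


def restrict_top(predictor: Predictor, n: int) -> Predictor:
    """Keep the ``n`` SNPs with the largest variance ``2 beta^2 (1-f) f``.

    Ties broken by (chromosome, position) ascending. Intended for trimming
    very large predictors before overlap analysis.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if n >= len(predictor):
        return predictor
    v = snp_variance(predictor.betas, predictor.mafs)
    order = sorted(
        range(len(predictor)),
        key=lambda i: (-v[i], predictor.snps[i].chromosome, predictor.snps[i].position),
    )
    keep = sorted(order[:n])  # preserve original SNP order
    return Predictor(predictor.phenotype, (predictor.snps[i] for i in keep))
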