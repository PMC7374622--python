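"""Variance accounted for by predictor SNPs.

Under Hardy-Weinberg equilibrium the minor-allele count ``x in {0,1,2}`` of
a SNP with minor allele frequency ``f`` has variance ``2(1-f)f``, so a SNP
with weight ``beta`` contributes ``2 beta^2 (1-f) f`` to the variance of
the additive score ``sum_i x_i beta_i``. Totals and subset fractions here
use the uncorrelated-SNP approximation throughout: covariance terms are
deliberately omitted (L1-penalized training leaves active sets with little
mutual correlation; an empirical correlation diagnostic lives in
:mod:`prs_architect.lasso`).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

from .errors import ValidationError
from .io import Predictor, VarianceTable

__all__ = [
    "snp_variance",
    "predictor_variance",
    "subset_variance_fraction",
    "small_maf_error",
]


def _check_maf(maf) -> np.ndarray:
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValidationError(f"maf must lie in (0, 0.5], got {maf}")
    return maf


def snp_variance(beta, maf):
    """Variance contribution ``2 beta^2 (1-f) f`` of a single SNP.

    Vectorized over array inputs; symmetric under ``beta -> -beta``.
    """
    maf = _check_maf(maf)
    beta = np.asarray(beta, dtype=float)
    out = 2.0 * beta**2 * (1.0 - maf) * maf
    return float(out) if out.ndim == 0 else out


def predictor_variance(predictor: Predictor) -> VarianceTable:
    """Per-SNP variance contributions and their total for a predictor.

    The total is the plain sum over the active set (uncorrelated
    approximation); entries align with predictor order.
    """
    contrib = snp_variance(predictor.betas, predictor.mafs)
    return VarianceTable(
        snp_ids=predictor.snp_ids,
        contributions=np.atleast_1d(contrib),
        total=float(np.sum(contrib)),
    )


def subset_variance_fraction(
    predictor: Predictor,
    subset: Iterable[str] | Callable[..., bool],
) -> float:
    """Fraction of predictor variance carried by a subset of its SNPs.

    ``subset`` is either an iterable of SNP ids (all of which must belong to
    the predictor) or a predicate called on each :class:`PredictorSNP`.
    Returns a value in [0, 1]; the empty subset gives 0 and the full active
    set gives 1.
    """
    table = predictor_variance(predictor)
    if callable(subset):
        mask = np.array([bool(subset(s)) for s in predictor.snps])
    else:
        wanted = set(subset)
        unknown = wanted - set(predictor.snp_ids)
        if unknown:
            raise ValidationError(
                f"subset contains ids not in predictor: {sorted(unknown)!r}"
            )
        mask = np.array([sid in wanted for sid in predictor.snp_ids])
    return float(table.contributions[mask].sum() / table.total)


def small_maf_error(beta, maf):
    """Relative error of the small-MAF approximation ``2 beta^2 f``.

    The exact contribution is ``2 beta^2 (1-f) f``; dropping the ``(1-f)``
    factor overstates it by a relative ``f / (1-f)``, which vanishes as
    ``f -> 0`` and reaches 1 at ``f = 0.5``.
    """
    maf = _check_maf(maf)
    out = maf / (1.0 - maf)
    return float(out) if out.ndim == 0 else out
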