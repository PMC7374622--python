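"""Accessibility of predictor SNPs from whole-exome sequencing data.

Exome sequencing only calls variants inside its capture targets, which sit
within gene bodies. A sparse predictor trained on array data can therefore
only be computed from exome data if its SNPs happen to be exome-callable.
This module matches predictor SNPs against an exome variant set (exact
chromosome+position) and crosses that with genic status at expansion ``k``
to produce a four-way breakdown, in SNP counts and in variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genic import DEFAULT_K, build_index, classify_snps
from .io import ExomeResource, GeneRecord, Predictor
from .variance import predictor_variance

__all__ = ["ExomeBreakdown", "match_exome", "genic_exonic_summary"]

CATEGORIES = (
    "genic_exonic",
    "nongenic_exonic",
    "genic_nonexonic",
    "nongenic_nonexonic",
)


def match_exome(predictor: Predictor, exome: ExomeResource) -> np.ndarray:
    """Boolean exome-callable flag per predictor SNP.

    A SNP is flagged iff its exact (chromosome, position) appears in the
    exome variant set; alleles are not compared (predictors and exome data
    typically come from different platforms with no shared allele coding).
    """
    return np.array(
        [exome.has_variant(s.chromosome, s.position) for s in predictor.snps],
        dtype=bool,
    )


@dataclass
class ExomeBreakdown:
    """Four-way genic x exonic breakdown of a predictor, counts and variance.

    Each quadruple sums to 1 exactly. ``genic_exonic`` in counts is the
    share of predictor SNPs both within expanded gene bodies and callable
    from exome data; the variance quadruple weights SNPs by
    ``2 beta^2 (1-f) f`` instead.
    """

    k: float
    count_fractions: dict[str, float]
    variance_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        row = {"k": self.k}
        row.update({f"count_{c}": self.count_fractions[c] for c in CATEGORIES})
        row.update({f"variance_{c}": self.variance_fractions[c] for c in CATEGORIES})
        return pd.DataFrame([row])


def genic_exonic_summary(
    predictor: Predictor,
    genes: list[GeneRecord],
    exome: ExomeResource,
    k: float = DEFAULT_K,
) -> ExomeBreakdown:
    """Cross-classify predictor SNPs by genic status (at ``k``) and exome access.

    The headline exome-accessibility statistics are the ``genic_exonic``
    entries: the count fraction answers "what share of the predictor's SNPs
    could exome sequencing see", the variance fraction "what share of the
    predictor's variance".
    """
    genic = np.array(
        [len(g) > 0 for g in classify_snps(predictor, build_index(genes, k))]
    )
    exonic = match_exome(predictor, exome)
    contrib = predictor_variance(predictor).contributions
    total = contrib.sum()
    n = len(predictor)
    masks = {
        "genic_exonic": genic & exonic,
        "nongenic_exonic": ~genic & exonic,
        "genic_nonexonic": genic & ~exonic,
        "nongenic_nonexonic": ~genic & ~exonic,
    }
    return ExomeBreakdown(
        k=float(k),
        count_fractions={c: float(m.sum() / n) for c, m in masks.items()},
        variance_fractions={c: float(contrib[m].sum() / total) for c, m in masks.items()},
    )
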