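"""Genic classification of predictor SNPs under expanded gene boundaries.

A SNP is *genic* at expansion ``k`` (kilo base pairs) if its position falls
within ``[start - 1000k, end + 1000k]`` of any protein-coding gene body,
inclusive at both expanded endpoints, clipped at position 1, and symmetric
regardless of strand. Where exactly genic regions end is itself uncertain,
which is why the whole analysis is run as a sweep over ``k``: both the genic
SNP-count fraction and the genic variance fraction are non-decreasing in
``k`` and the default grid is 0-30 kbp in 0.5 kbp steps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError
from .io import GeneRecord, Predictor
from .variance import predictor_variance

__all__ = [
    "ExpandedGeneIndex",
    "SweepResult",
    "GeneGroup",
    "GeneVarianceRanking",
    "build_index",
    "classify_snps",
    "snp_gene_distances",
    "sweep",
    "rank_genes",
    "random_baseline",
    "flag_genes",
]

DEFAULT_K_GRID = tuple(np.arange(0.0, 30.0 + 1e-9, 0.5))
DEFAULT_K = 30.0


def _expansion_bp(k: float) -> int:
    if k < 0:
        raise ValidationError(f"boundary expansion k must be >= 0, got {k}")
    return int(round(1000.0 * k))


@dataclass
class ExpandedGeneIndex:
    """Per-chromosome interval index of gene bodies expanded by ``k`` kbp."""

    k: float
    trees: dict[str, IntervalTree]

    def query(self, chromosome: str, position: int) -> set[str]:
        """Gene ids whose expanded interval contains the 1-based position."""
        tree = self.trees.get(chromosome)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(position)}


def build_index(genes: Iterable[GeneRecord], k: float) -> ExpandedGeneIndex:
    """Build a point-query index of gene bodies expanded by ``k`` kbp.

    Expansion is symmetric at both ends, ignores strand, and is clipped at
    position 1. Intervals are inclusive at the expanded endpoints.
    """
    pad = _expansion_bp(k)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(1, g.start - pad)
        hi = g.end + pad
        # intervaltree uses half-open ints; +1 makes [lo, hi] inclusive
        trees.setdefault(g.chromosome, IntervalTree()).addi(lo, hi + 1, g.gene_id)
    return ExpandedGeneIndex(k=float(k), trees=trees)


def classify_snps(
    predictor: Predictor, index: ExpandedGeneIndex
) -> list[set[str]]:
    """Per-SNP set of overlapping gene ids; genic iff the set is non-empty."""
    return [index.query(s.chromosome, s.position) for s in predictor.snps]


def snp_gene_distances(predictor: Predictor, genes: Sequence[GeneRecord]) -> np.ndarray:
    """Distance (bp) from each SNP to the nearest gene body on its chromosome.

    0 for SNPs inside a gene body; ``inf`` on chromosomes with no genes.
    A SNP is genic at expansion ``k`` iff its distance is <= 1000k, which
    turns the k-sweep into a single thresholding pass.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    starts = {c: np.array([g.start for g in gs]) for c, gs in by_chrom.items()}
    ends = {c: np.array([g.end for g in gs]) for c, gs in by_chrom.items()}
    out = np.empty(len(predictor), dtype=float)
    for i, s in enumerate(predictor.snps):
        if s.chromosome not in starts:
            out[i] = np.inf
            continue
        d = np.maximum.reduce(
            [
                starts[s.chromosome] - s.position,
                s.position - ends[s.chromosome],
                np.zeros_like(starts[s.chromosome]),
            ]
        )
        out[i] = d.min()
    return out


@dataclass
class SweepResult:
    """Genic count and variance fractions along a grid of expansions ``k``."""

    k: np.ndarray
    count_fraction: np.ndarray
    variance_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "count_fraction": self.count_fraction,
                "variance_fraction": self.variance_fraction,
            }
        )


def sweep(
    predictor: Predictor,
    genes: Sequence[GeneRecord],
    k_grid: Sequence[float] = DEFAULT_K_GRID,
) -> SweepResult:
    """Genic SNP-count fraction and variance fraction at each expansion k.

    Both series are non-decreasing in ``k`` by construction. Fractions are
    on [0, 1]; the CLI formats them as percentages.
    """
    k_grid = np.asarray(list(k_grid), dtype=float)
    if k_grid.size == 0 or np.any(np.diff(k_grid) < 0):
        raise ValidationError("k_grid must be non-empty and sorted ascending")
    if np.any(k_grid < 0):
        raise ValidationError("k values must be >= 0")
    dist = snp_gene_distances(predictor, genes)
    contrib = predictor_variance(predictor).contributions
    total = contrib.sum()
    n = len(predictor)
    count_frac = np.empty_like(k_grid)
    var_frac = np.empty_like(k_grid)
    for i, k in enumerate(k_grid):
        genic = dist <= _expansion_bp(k)
        count_frac[i] = genic.sum() / n
        var_frac[i] = contrib[genic].sum() / total
    return SweepResult(k=k_grid, count_fraction=count_frac, variance_fraction=var_frac)


@dataclass(frozen=True)
class GeneGroup:
    """Genes sharing the exact same set of contributing predictor SNPs.

    Expanded boundaries of nearby genes overlap, so several genes may carry
    exactly the same SNPs and hence the same variance fraction; such genes
    are reported as one group.
    """

    gene_ids: tuple[str, ...]
    snp_ids: frozenset[str]
    variance_fraction: float
    flagged: tuple[bool, ...] | None = None


@dataclass
class GeneVarianceRanking:
    """Top per-gene variance fractions at a fixed expansion ``k``.

    A SNP inside several expanded genes contributes its full variance to
    each, so gene fractions may double-count and need not sum to the overall
    genic fraction. ``top_n`` counts distinct variance values, not genes.
    """

    k: float
    top_n: int
    groups: list[GeneGroup]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, grp in enumerate(self.groups, start=1):
            for gid, flag in zip(
                grp.gene_ids,
                grp.flagged if grp.flagged is not None else [None] * len(grp.gene_ids),
            ):
                rows.append(
                    {
                        "rank": rank,
                        "gene_id": gid,
                        "variance_fraction": grp.variance_fraction,
                        "n_snps": len(grp.snp_ids),
                        "snp_ids": ";".join(sorted(grp.snp_ids)),
                        "flagged": flag,
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=["rank", "gene_id", "variance_fraction", "n_snps", "snp_ids", "flagged"],
        )
        if all(g.flagged is None for g in self.groups):
            df = df.drop(columns=["flagged"])
        return df


def rank_genes(
    predictor: Predictor,
    genes: Sequence[GeneRecord],
    k: float = DEFAULT_K,
    top_n: int = 15,
) -> GeneVarianceRanking:
    """Rank genes by the predictor variance fraction their SNPs account for.

    Each gene's fraction is the subset variance fraction of the SNPs inside
    its expanded body. Genes with identical SNP sets form one group; groups
    are sorted by fraction descending with ties broken by the
    lexicographically smallest gene id; the ranking keeps the ``top_n``
    largest *distinct* fraction values, so more than ``top_n`` genes may be
    returned. Genes with no SNPs are omitted.
    """
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    index = build_index(genes, k)
    memberships = classify_snps(predictor, index)
    gene_snps: dict[str, set[str]] = {}
    for snp, gids in zip(predictor.snps, memberships):
        for gid in gids:
            gene_snps.setdefault(gid, set()).add(snp.snp_id)

    table = predictor_variance(predictor)
    var_by_id = dict(zip(table.snp_ids, table.contributions))

    by_set: dict[frozenset[str], list[str]] = {}
    for gid, sids in gene_snps.items():
        by_set.setdefault(frozenset(sids), []).append(gid)

    groups = [
        GeneGroup(
            gene_ids=tuple(sorted(gids)),
            snp_ids=sids,
            variance_fraction=float(
                sum(var_by_id[s] for s in sids) / table.total
            ),
        )
        for sids, gids in by_set.items()
    ]
    groups.sort(key=lambda g: (-g.variance_fraction, g.gene_ids[0]))
    distinct = []
    for g in groups:
        if g.variance_fraction not in distinct:
            distinct.append(g.variance_fraction)
    keep = set(distinct[:top_n])
    return GeneVarianceRanking(
        k=float(k), top_n=top_n, groups=[g for g in groups if g.variance_fraction in keep]
    )


def random_baseline(
    manifest: Predictor,
    size: int,
    genes: Sequence[GeneRecord],
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null genic count-fraction sweep for random SNP sets from an array manifest.

    Each replicate draws ``size`` SNPs uniformly without replacement from the
    manifest and recomputes the count-fraction sweep; returned frame carries
    the per-k mean and standard deviation over replicates. This is the
    baseline against which a trained predictor's genic enrichment is judged.
    """
    if size > len(manifest):
        raise ValidationError(
            f"sample size {size} exceeds manifest size {len(manifest)}"
        )
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    k_grid = np.asarray(list(k_grid), dtype=float)
    if np.any(np.diff(k_grid) < 0):
        raise ValidationError("k_grid must be sorted ascending")
    rng = np.random.default_rng(seed)
    dist = snp_gene_distances(manifest, genes)
    pads = np.array([_expansion_bp(k) for k in k_grid])
    fracs = np.empty((reps, k_grid.size))
    for r in range(reps):
        idx = rng.choice(len(manifest), size=size, replace=False)
        d = dist[idx]
        fracs[r] = (d[:, None] <= pads[None, :]).mean(axis=0)
    return pd.DataFrame(
        {
            "k": k_grid,
            "mean_count_fraction": fracs.mean(axis=0),
            "std_count_fraction": fracs.std(axis=0, ddof=0),
        }
    )


@dataclass
class FlagSummary:
    """How many flagged genes appear in a ranking and their summed fraction."""

    flagged_gene_count: int
    flagged_variance_fraction: float


def flag_genes(
    ranking: GeneVarianceRanking, flag_set: Iterable[str]
) -> tuple[GeneVarianceRanking, FlagSummary]:
    """Annotate a gene ranking against a set of flagged gene names/ids.

    Intended for screening top genes against externally curated problem
    lists (e.g. genes whose exome variant calls are known to be unreliable).
    Each flagged gene contributes its group's variance fraction to the
    summary total.
    """
    flags = set(flag_set)
    annotated = []
    count = 0
    summed = 0.0
    for grp in ranking.groups:
        marks = tuple(gid in flags for gid in grp.gene_ids)
        count += sum(marks)
        summed += grp.variance_fraction * sum(marks)
        annotated.append(replace(grp, flagged=marks))
    return (
        GeneVarianceRanking(k=ranking.k, top_n=ranking.top_n, groups=annotated),
        FlagSummary(flagged_gene_count=count, flagged_variance_fraction=summed),
    )
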