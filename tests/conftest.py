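"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use plain double loops (or direct
set arithmetic) so they share no code path with the indexed/vectorized
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from prs_architect import (
    Dist,
    GeneRecord,
    GenomeSpec,
    Predictor,
    PredictorSNP,
    PredictorSpec,
    generate_genome,
    generate_predictor,
)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_genic_membership(snp, genes, k: float) -> set[str]:
    """Gene ids covering a SNP at expansion k, by a plain double loop."""
    pad = int(round(1000 * k))
    hits = set()
    for g in genes:
        if g.chromosome != snp.chromosome:
            continue
        if max(1, g.start - pad) <= snp.position <= g.end + pad:
            hits.add(g.gene_id)
    return hits


def brute_proximity_matches(row, col, window: int) -> list[set[int]]:
    """Per row-SNP set of column indices within the strict window."""
    out = []
    for s in row.snps:
        hits = set()
        for j, c in enumerate(col.snps):
            if c.chromosome == s.chromosome and abs(c.position - s.position) < window:
                hits.add(j)
        out.append(hits)
    return out


def brute_bed_membership(pos: int, intervals) -> bool:
    """1-based position against BED half-open intervals, by direct scan."""
    return any(s + 1 <= pos <= e for s, e in intervals)


def brute_snp_variance(beta: float, maf: float) -> float:
    return 2.0 * beta * beta * (1.0 - maf) * maf


# ---------------------------------------------------------------------------
# random-instance builders
# ---------------------------------------------------------------------------

def random_predictor(rng: np.random.Generator, n: int = 50,
                     chroms=("chr1", "chr2"), span: int = 2_000_000,
                     phenotype: str = "random") -> Predictor:
    taken = set()
    snps = []
    while len(snps) < n:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(1, span))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        beta = float(rng.normal()) or 0.1
        snps.append(
            PredictorSNP(
                snp_id=f"r{len(snps)}",
                chromosome=chrom,
                position=pos,
                beta=beta,
                maf=float(rng.uniform(0.01, 0.5)),
            )
        )
    return Predictor(phenotype, snps)


def random_genes(rng: np.random.Generator, n: int = 20,
                 chroms=("chr1", "chr2"), span: int = 2_000_000) -> list[GeneRecord]:
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(1, span))
        length = int(rng.integers(500, 50_000))
        genes.append(
            GeneRecord(
                gene_id=f"G{i:04d}",
                gene_name=f"g{i}",
                chromosome=chrom,
                start=start,
                end=start + length,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 2-chromosome genome of 60 genes."""
    spec = GenomeSpec(n_chromosomes=2, genes_per_chromosome=30, seed=11)
    return generate_genome(spec)


@pytest.fixture(scope="session")
def planted_predictor(small_genome):
    """Predictor with an exactly planted genic count fraction of 0.55."""
    spec = PredictorSpec(n_snps=400, genic_count_fraction=0.55, seed=12)
    return generate_predictor(small_genome, spec, phenotype="planted")


@pytest.fixture(scope="session")
def sparse_base():
    """Widely spaced predictor (every SNP isolated) for pair planting."""
    rng = np.random.default_rng(21)
    return random_predictor(rng, n=200, span=50_000_000, phenotype="sparse")


@pytest.fixture
def two_snp_predictor():
    """The hand-computed two-SNP fixture: variances 0.5 and 0.18, total 0.68."""
    return Predictor(
        "hand",
        [
            PredictorSNP("A", "chr1", 1000, 1.0, 0.5),
            PredictorSNP("B", "chr1", 10000, 1.0, 0.1),
        ],
    )
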