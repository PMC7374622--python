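"""Synthetic genomes, predictors, exome resources, cohorts, and predictor pairs.

Every generator is deterministic given its seed and emits a
:class:`SyntheticTruth` ledger recording the planted structure (genic
status, variance fractions, causal effects, matched SNP pairs), so that the
downstream analyses have an exact ground truth to recover. Planted count
fractions are enforced exactly by stratified placement, not in expectation.

The genome model is deliberately simple: non-overlapping protein-coding
gene bodies separated by intergenic gaps, no linkage disequilibrium between
SNPs (the variance arithmetic elsewhere assumes largely uncorrelated SNPs),
and Hardy-Weinberg genotypes for cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .errors import GenerationError, ValidationError
from .io import GeneRecord, Predictor, PredictorSNP, write_genes
from .variance import snp_variance

__all__ = [
    "Dist",
    "GenomeSpec",
    "PredictorSpec",
    "SyntheticTruth",
    "generate_genome",
    "generate_predictor",
    "generate_exome",
    "generate_cohort",
    "generate_predictor_pair",
]


# ---------------------------------------------------------------------------
# sampling distributions (small declarative spec so configs stay plain JSON)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dist:
    """A named sampling distribution with keyword parameters.

    Supported: ``fixed(value)``, ``uniform(low, high)``,
    ``lognormal(median, sigma)`` (median in natural units),
    ``exponential(mean)``, ``laplace(loc, scale)``,
    ``uniform_signed(low, high)`` (magnitude uniform, random sign).
    """

    name: str
    params: dict = field(default_factory=dict)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.name == "fixed":
            return np.full(size, float(p["value"]))
        if self.name == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.name == "lognormal":
            return rng.lognormal(np.log(p["median"]), p["sigma"], size)
        if self.name == "exponential":
            return rng.exponential(p["mean"], size)
        if self.name == "laplace":
            return rng.laplace(p.get("loc", 0.0), p["scale"], size)
        if self.name == "uniform_signed":
            mag = rng.uniform(p["low"], p["high"], size)
            return mag * rng.choice([-1.0, 1.0], size)
        raise ValidationError(f"unknown distribution {self.name!r}")


# strict proximity window used when isolating planted predictor pairs
DEFAULT_WINDOW = 4000

DEFAULT_GENE_LENGTH = Dist("lognormal", {"median": 25_000, "sigma": 0.8})
DEFAULT_INTERGENIC_GAP = Dist("exponential", {"mean": 75_000})
DEFAULT_BETA = Dist("laplace", {"scale": 0.05})
DEFAULT_MAF = Dist("uniform", {"low": 0.01, "high": 0.5})


# ---------------------------------------------------------------------------
# specs and the truth ledger
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Layout of a synthetic genome of non-overlapping gene bodies."""

    n_chromosomes: int = 2
    genes_per_chromosome: int = 100
    gene_length: Dist = DEFAULT_GENE_LENGTH
    intergenic_gap: Dist = DEFAULT_INTERGENIC_GAP
    seed: int = 0


@dataclass
class PredictorSpec:
    """A sparse predictor with a planted genic SNP-count fraction at k=0."""

    n_snps: int = 1000
    genic_count_fraction: float = 0.55
    beta_distribution: Dist = DEFAULT_BETA
    maf_distribution: Dist = DEFAULT_MAF
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.genic_count_fraction <= 1.0):
            raise ValidationError("genic_count_fraction must lie in [0, 1]")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")


@dataclass
class SyntheticTruth:
    """Ledger of planted structure; every field is recomputable from the files."""

    genic_status: list[bool] | None = None
    genic_count_fraction: float | None = None
    genic_variance_fraction: float | None = None
    causal_snp_ids: list[str] | None = None
    causal_betas: list[float] | None = None
    heritability: float | None = None
    analytic_score_variance: float | None = None
    matched_pairs: list[dict] | None = None
    count_overlap_base_to_pair: float | None = None
    count_overlap_pair_to_base: float | None = None
    signed_variance_overlap_base_row: float | None = None
    signed_variance_overlap_pair_row: float | None = None
    captured_snp_ids: list[str] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: v for k, v in asdict(self).items() if v is not None},
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(
    spec: GenomeSpec, out_path=None
) -> list[GeneRecord]:
    """Lay out non-overlapping protein-coding genes separated by gaps.

    Walking each chromosome left to right: a gap is sampled, the gene starts
    one bp past the gap, extends for its sampled length, and the walk resumes
    at its end. All lengths are rounded to integers and must be >= 1.
    Deterministic given ``spec.seed``; optionally writes GFF3 to ``out_path``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[GeneRecord] = []
    counter = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = 0
        n = spec.genes_per_chromosome
        gaps = np.rint(spec.intergenic_gap.sample(n, rng)).astype(np.int64)
        lengths = np.rint(spec.gene_length.sample(n, rng)).astype(np.int64)
        if np.any(lengths < 1) or np.any(gaps < 0):
            raise ValidationError(
                "sampled gene lengths must be >= 1 and gaps >= 0; "
                "check the spec distributions"
            )
        for gap, length in zip(gaps, lengths):
            start = cursor + int(gap) + 1
            end = start + int(length) - 1
            counter += 1
            records.append(
                GeneRecord(
                    gene_id=f"GENE{counter:05d}",
                    gene_name=f"Gene{counter}",
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand="+" if counter % 2 else "-",
                )
            )
            cursor = end
    if out_path is not None:
        write_genes(records, out_path)
    return records


def _chromosome_extents(
    genes: Sequence[GeneRecord], margin: int
) -> dict[str, int]:
    extents: dict[str, int] = {}
    for g in genes:
        extents[g.chromosome] = max(extents.get(g.chromosome, 0), g.end)
    return {c: e + margin for c, e in extents.items()}


def _intergenic_intervals(
    genes: Sequence[GeneRecord], margin: int
) -> list[tuple[str, int, int]]:
    """1-based inclusive intervals outside every gene body."""
    extents = _chromosome_extents(genes, margin)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        cursor = 1
        for g in gs:
            if g.start > cursor:
                out.append((chrom, cursor, g.start - 1))
            cursor = max(cursor, g.end + 1)
        if extents[chrom] >= cursor:
            out.append((chrom, cursor, extents[chrom]))
    return out


def _sample_positions_in_intervals(
    intervals: list[tuple[str, int, int]],
    n: int,
    rng: np.random.Generator,
    taken: set[tuple[str, int]],
) -> list[tuple[str, int]]:
    if not intervals:
        raise GenerationError("no space available to place SNPs")
    lengths = np.array([hi - lo + 1 for _, lo, hi in intervals], dtype=float)
    probs = lengths / lengths.sum()
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise GenerationError("could not place SNPs at distinct positions")
        i = rng.choice(len(intervals), p=probs)
        chrom, lo, hi = intervals[i]
        pos = int(rng.integers(lo, hi + 1))
        if (chrom, pos) in taken:
            continue
        taken.add((chrom, pos))
        out.append((chrom, pos))
    return out


# ---------------------------------------------------------------------------
# predictor
# ---------------------------------------------------------------------------

def generate_predictor(
    genes: Sequence[GeneRecord],
    spec: PredictorSpec,
    phenotype: str = "synthetic",
    margin: int = 100_000,
) -> tuple[Predictor, SyntheticTruth]:
    """Plant a sparse predictor with an exact genic SNP-count fraction at k=0.

    Exactly ``round(genic_count_fraction * n_snps)`` SNPs land inside gene
    bodies (uniform over genes, then uniform within the body); the rest land
    uniformly in intergenic space, which extends ``margin`` bp past the last
    gene of each chromosome. Effect sizes and MAFs are drawn i.i.d. from the
    spec's distributions. The truth ledger records per-SNP genic status and
    the realized count and variance fractions.
    """
    rng = np.random.default_rng(spec.seed)
    n_genic = int(round(spec.genic_count_fraction * spec.n_snps))
    n_inter = spec.n_snps - n_genic
    genes = list(genes)
    if n_genic > 0 and not genes:
        raise GenerationError("genic SNPs requested but the genome has no genes")

    taken: set[tuple[str, int]] = set()
    genic_sites: list[tuple[str, int]] = []
    attempts = 0
    while len(genic_sites) < n_genic:
        attempts += 1
        if attempts > 200 * n_genic + 1000:
            raise GenerationError("could not place genic SNPs at distinct positions")
        g = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(g.start, g.end + 1))
        if (g.chromosome, pos) in taken:
            continue
        taken.add((g.chromosome, pos))
        genic_sites.append((g.chromosome, pos))

    inter_intervals = _intergenic_intervals(genes, margin) if genes else []
    if not genes:
        inter_intervals = [("chr1", 1, margin)]
    inter_sites = _sample_positions_in_intervals(inter_intervals, n_inter, rng, taken)

    sites = genic_sites + inter_sites
    genic_status = [True] * n_genic + [False] * n_inter
    order = rng.permutation(spec.n_snps)

    betas = spec.beta_distribution.sample(spec.n_snps, rng)
    while np.any(betas == 0.0):  # pragma: no cover - probability zero
        betas[betas == 0.0] = spec.beta_distribution.sample(
            int(np.sum(betas == 0.0)), rng
        )
    mafs = spec.maf_distribution.sample(spec.n_snps, rng)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValidationError("maf_distribution must produce values in (0, 0.5]")

    snps = []
    status = []
    for rank, idx in enumerate(order):
        chrom, pos = sites[idx]
        snps.append(
            PredictorSNP(
                snp_id=f"snp{rank + 1:06d}",
                chromosome=chrom,
                position=pos,
                beta=float(betas[rank]),
                maf=float(mafs[rank]),
            )
        )
        status.append(genic_status[idx])

    predictor = Predictor(phenotype, snps)
    contrib = snp_variance(predictor.betas, predictor.mafs)
    mask = np.array(status)
    truth = SyntheticTruth(
        genic_status=status,
        genic_count_fraction=float(mask.mean()),
        genic_variance_fraction=float(contrib[mask].sum() / contrib.sum()),
    )
    return predictor, truth


# ---------------------------------------------------------------------------
# exome
# ---------------------------------------------------------------------------

def generate_exome(
    genes: Sequence[GeneRecord],
    manifest: Predictor,
    capture_fraction: float,
    seed: int = 0,
) -> tuple["ExomeResource", SyntheticTruth]:
    """Emulate an exome variant set covering a fraction of genic manifest SNPs.

    Each manifest SNP inside a k=0 gene body is captured independently with
    probability ``capture_fraction``; the variant set is exactly the captured
    SNPs. Targets are 1-bp BED intervals at the captured positions (whole
    gene bodies when ``capture_fraction == 1``), so every variant lies inside
    a target and targets nest inside gene bodies.
    """
    from .genic import build_index, classify_snps
    from .io import ExomeResource

    if not (0.0 <= capture_fraction <= 1.0):
        raise ValidationError("capture_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    index = build_index(genes, 0.0)
    genic = [len(g) > 0 for g in classify_snps(manifest, index)]
    captured: list[PredictorSNP] = []
    for snp, is_genic in zip(manifest.snps, genic):
        if is_genic and rng.random() < capture_fraction:
            captured.append(snp)

    variants = {(s.chromosome, s.position) for s in captured}
    targets: dict[str, list[tuple[int, int]]] = {}
    if capture_fraction == 1.0:
        for g in genes:
            targets.setdefault(g.chromosome, []).append((g.start - 1, g.end))
    else:
        for s in captured:
            targets.setdefault(s.chromosome, []).append((s.position - 1, s.position))
    truth = SyntheticTruth(captured_snp_ids=[s.snp_id for s in captured])
    return ExomeResource(variants=variants, targets=targets), truth


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(
    causal: Predictor,
    n_individuals: int,
    heritability: float,
    binary: bool = False,
    prevalence: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Hardy-Weinberg genotypes and additive phenotypes for a causal predictor.

    Genotypes are minor-allele counts ``x ~ Binomial(2, f)`` drawn
    independently per SNP (no LD). The continuous phenotype is
    ``y = sum_i x_i beta_i + eps`` with Gaussian noise scaled so the genetic
    share of the phenotype variance equals ``heritability`` in expectation;
    ``heritability == 1`` gives exactly zero noise. In binary mode the
    continuous liability is thresholded at its empirical ``1 - prevalence``
    quantile into 0/1 case-control labels.
    """
    if not (0.0 < heritability <= 1.0):
        raise ValidationError("heritability must lie in (0, 1]")
    if binary:
        if prevalence is None or not (0.0 < prevalence < 1.0):
            raise ValidationError("binary mode needs prevalence in (0, 1)")
    rng = np.random.default_rng(seed)
    mafs = causal.mafs
    betas = causal.betas
    X = rng.binomial(2, mafs[None, :], size=(n_individuals, mafs.size)).astype(np.int8)
    g = X @ betas
    var_g = float(np.sum(snp_variance(betas, mafs)))
    if heritability == 1.0:
        eps = np.zeros(n_individuals)
    else:
        var_eps = var_g * (1.0 - heritability) / heritability
        eps = rng.normal(0.0, np.sqrt(var_eps), n_individuals)
    y = g + eps
    if binary:
        threshold = np.quantile(y, 1.0 - prevalence)
        y = (y > threshold).astype(float)
    truth = SyntheticTruth(
        causal_snp_ids=list(causal.snp_ids),
        causal_betas=[float(b) for b in betas],
        heritability=heritability,
        analytic_score_variance=var_g,
    )
    return X, y, truth


# ---------------------------------------------------------------------------
# predictor pairs with planted overlap
# ---------------------------------------------------------------------------

def generate_predictor_pair(
    base: Predictor,
    shared_fraction: float,
    sign_concordance: float,
    jitter_bp: int = 1000,
    seed: int = 0,
    phenotype: str | None = None,
    margin: int = 500_000,
) -> tuple[Predictor, SyntheticTruth]:
    """A second predictor with a planted overlap structure against ``base``.

    ``round(shared_fraction * len(base))`` SNPs of the new predictor are
    placed within ``jitter_bp`` (< 4,000) of distinct base SNPs, with
    ``round(sign_concordance * n_shared)`` of them sign-concordant; the
    remaining SNPs are placed at least 4,000 bp from every base SNP. The
    placement is verified so each new SNP proximity-matches exactly its
    partner (or nothing), making the ledger's predicted overlap statistics
    exact:

    * count overlap base->pair = 100 * n_shared / len(base) (and likewise
      pair->base, the pair having the same size as the base),
    * r~ with base as row = 100 * sum(sign_i * v_i) / total_v over the
      matched base SNPs, and analogously with the pair as row.
    """
    if not (0.0 <= shared_fraction <= 1.0 and 0.0 <= sign_concordance <= 1.0):
        raise ValidationError("shared_fraction and sign_concordance must lie in [0, 1]")
    if not (0 <= jitter_bp <= 3999):
        raise ValidationError("jitter_bp must lie in [0, 3999]")
    rng = np.random.default_rng(seed)
    n = len(base)
    n_shared = int(round(shared_fraction * n))
    base_pos = {c: base.positions[base.chromosomes == c] for c in set(base.chromosomes)}

    def near_base(chrom: str, pos: int) -> np.ndarray:
        arr = base_pos.get(chrom)
        if arr is None:
            return np.empty(0, dtype=np.int64)
        return arr[np.abs(arr - pos) < DEFAULT_WINDOW]

    # a partner within jitter of base SNP i matches only i provided no other
    # base SNP lies within window + jitter of i
    isolated = []
    for i, s in enumerate(base.snps):
        arr = base_pos[s.chromosome]
        if np.sum(np.abs(arr - s.position) < DEFAULT_WINDOW + jitter_bp) == 1:
            isolated.append(i)
    if len(isolated) < n_shared:
        raise GenerationError(
            f"only {len(isolated)} of {n} base SNPs are isolated enough to host "
            f"an unambiguous partner at jitter {jitter_bp} bp; "
            f"cannot plant {n_shared} shared SNPs"
        )
    shared_idx = rng.choice(np.array(isolated), size=n_shared, replace=False)
    concordant = np.zeros(n_shared, dtype=bool)
    concordant[: int(round(sign_concordance * n_shared))] = True
    concordant = concordant[rng.permutation(n_shared)]

    # uniqueness is per-predictor: a partner may sit exactly on its base SNP
    taken: set[tuple[str, int]] = set()
    new_snps: list[PredictorSNP] = []
    pairs: list[dict] = []
    for rank, (bi, conc) in enumerate(zip(shared_idx, concordant)):
        bsnp = base.snps[bi]
        placed = False
        for _ in range(500):
            jit = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            pos = max(1, bsnp.position + jit)
            if (bsnp.chromosome, pos) in taken:
                continue
            neighbors = near_base(bsnp.chromosome, pos)
            if neighbors.size == 1 and neighbors[0] == bsnp.position:
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"cannot isolate a partner for base SNP {bsnp.snp_id}: "
                "base SNPs are too densely spaced for the requested jitter"
            )
        taken.add((bsnp.chromosome, pos))
        mag = abs(float(DEFAULT_BETA.sample(1, rng)[0])) or 1e-6
        beta = mag if (bsnp.beta > 0) == conc else -mag
        new_snps.append(
            PredictorSNP(
                snp_id=f"pair{rank + 1:06d}",
                chromosome=bsnp.chromosome,
                position=pos,
                beta=beta,
                maf=float(DEFAULT_MAF.sample(1, rng)[0]),
            )
        )
        pairs.append(
            {
                "base_snp_id": bsnp.snp_id,
                "pair_snp_id": new_snps[-1].snp_id,
                "sign_concordant": bool(conc),
            }
        )

    extents = _chromosome_extents(base_snp_records(base), margin)
    n_far = n - n_shared
    placed_far = 0
    attempts = 0
    chrom_list = sorted(extents)
    while placed_far < n_far:
        attempts += 1
        if attempts > 500 * max(n_far, 1) + 1000:
            raise GenerationError(
                "cannot place SNPs >= 4000 bp from every base SNP; "
                "increase margin or reduce the base predictor's density"
            )
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        pos = int(rng.integers(1, extents[chrom] + 1))
        if (chrom, pos) in taken or near_base(chrom, pos).size:
            continue
        taken.add((chrom, pos))
        placed_far += 1
        new_snps.append(
            PredictorSNP(
                snp_id=f"pair{n_shared + placed_far:06d}",
                chromosome=chrom,
                position=pos,
                beta=float(DEFAULT_BETA.sample(1, rng)[0]) or 1e-6,
                maf=float(DEFAULT_MAF.sample(1, rng)[0]),
            )
        )

    pair_pred = Predictor(phenotype or f"{base.phenotype}_pair", new_snps)

    # ledger-predicted overlap statistics from the planted pairing
    base_v = snp_variance(base.betas, base.mafs)
    base_total = float(base_v.sum())
    pair_v = snp_variance(pair_pred.betas, pair_pred.mafs)
    pair_total = float(pair_v.sum())
    base_id_to_i = {sid: i for i, sid in enumerate(base.snp_ids)}
    pair_id_to_i = {sid: i for i, sid in enumerate(pair_pred.snp_ids)}
    r_base = sum(
        (1.0 if p["sign_concordant"] else -1.0) * base_v[base_id_to_i[p["base_snp_id"]]]
        for p in pairs
    )
    r_pair = sum(
        (1.0 if p["sign_concordant"] else -1.0) * pair_v[pair_id_to_i[p["pair_snp_id"]]]
        for p in pairs
    )
    truth = SyntheticTruth(
        matched_pairs=pairs,
        count_overlap_base_to_pair=100.0 * n_shared / n,
        count_overlap_pair_to_base=100.0 * n_shared / len(pair_pred),
        signed_variance_overlap_base_row=100.0 * r_base / base_total,
        signed_variance_overlap_pair_row=100.0 * r_pair / pair_total,
    )
    return pair_pred, truth


def base_snp_records(predictor: Predictor) -> list[GeneRecord]:
    """Degenerate 1-bp gene records at SNP sites (extent bookkeeping only)."""
    return [
        GeneRecord(
            gene_id=s.snp_id,
            gene_name=s.snp_id,
            chromosome=s.chromosome,
            start=s.position,
            end=s.position,
        )
        for s in predictor.snps
    ]
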