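"""Domain types, file readers/writers, and coordinate conventions.

Coordinate conventions
----------------------
All genomic positions are held internally 1-based, with gene intervals
1-based and inclusive at both ends (the GFF3 convention). BED files are
0-based half-open ``[start, end)``; they are converted at the boundary of
this module and nowhere else: a 1-based position ``p`` lies inside a BED
interval ``[s, e)`` iff ``s < p <= e``, equivalently ``s + 1 <= p <= e``
in 1-based inclusive terms.

Chromosome labels are opaque strings: ``"chr1"`` and ``"1"`` are distinct.
Readers accept ``normalize_chrom=True`` to strip a leading ``"chr"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "PredictorSNP",
    "Predictor",
    "GeneRecord",
    "ExomeResource",
    "VarianceTable",
    "bed_interval_contains",
    "bed_to_inclusive",
    "read_predictor",
    "write_predictor",
    "read_genes",
    "write_genes",
    "read_exome",
    "write_exome",
]

VALID_STRANDS = frozenset({"+", "-", "."})


# ---------------------------------------------------------------------------
# coordinate conversion — the only place 0/1-based arithmetic happens
# ---------------------------------------------------------------------------

def bed_interval_contains(pos: int, start: int, end: int) -> bool:
    """True iff 1-based position ``pos`` lies in BED interval ``[start, end)``."""
    return start < pos <= end


def bed_to_inclusive(start: int, end: int) -> tuple[int, int]:
    """Convert a BED half-open interval to a 1-based inclusive one."""
    return start + 1, end


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorSNP:
    """One weighted variant of a sparse polygenic predictor.

    ``beta`` is the effect size per copy of the counted (minor) allele and
    ``maf`` the minor allele frequency, restricted to ``(0, 0.5]``. Inputs
    coding an allele frequency above 0.5 are rejected rather than folded:
    the per-SNP variance ``2 beta^2 (1-f) f`` is symmetric in ``f <-> 1-f``,
    so silent folding would hide upstream data errors.
    """

    snp_id: str
    chromosome: str
    position: int
    beta: float
    maf: float
    counted_allele: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"SNP {self.snp_id!r}: position must be >= 1, got {self.position}"
            )
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(
                f"SNP {self.snp_id!r}: maf must lie in (0, 0.5], got {self.maf}"
            )
        if not np.isfinite(self.beta) or self.beta == 0.0:
            raise ValidationError(
                f"SNP {self.snp_id!r}: beta must be finite and nonzero, got {self.beta}"
            )


@dataclass(frozen=True)
class Predictor:
    """A named sparse predictor: an ordered active set of weighted SNPs.

    The (chromosome, position) pairs are unique within a predictor and the
    active set is non-empty; zero-weight SNPs are not representable (see
    :class:`PredictorSNP`).
    """

    phenotype: str
    snps: tuple[PredictorSNP, ...]

    def __init__(self, phenotype: str, snps: Iterable[PredictorSNP]):
        object.__setattr__(self, "phenotype", phenotype)
        object.__setattr__(self, "snps", tuple(snps))
        if not self.snps:
            raise ValidationError(f"predictor {phenotype!r}: active set is empty")
        seen: set[tuple[str, int]] = set()
        for s in self.snps:
            key = (s.chromosome, s.position)
            if key in seen:
                raise ValidationError(
                    f"predictor {phenotype!r}: duplicate site {key[0]}:{key[1]}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[PredictorSNP]:
        return iter(self.snps)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.snp_id for s in self.snps)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    @property
    def betas(self) -> np.ndarray:
        return np.array([s.beta for s in self.snps], dtype=float)

    @property
    def mafs(self) -> np.ndarray:
        return np.array([s.maf for s in self.snps], dtype=float)

    def subset(self, snp_ids: Iterable[str], phenotype: str | None = None) -> "Predictor":
        """New predictor restricted to ``snp_ids`` (original order kept)."""
        wanted = set(snp_ids)
        unknown = wanted - set(self.snp_ids)
        if unknown:
            raise ValidationError(f"unknown SNP ids: {sorted(unknown)!r}")
        return Predictor(
            phenotype or self.phenotype,
            (s for s in self.snps if s.snp_id in wanted),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chromosomes,
                "pos": self.positions,
                "beta": self.betas,
                "maf": self.mafs,
                "counted_allele": [s.counted_allele for s in self.snps],
            }
        )


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene body: 1-based inclusive interval on a chromosome."""

    gene_id: str
    gene_name: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id!r}: start must be >= 1")
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be one of {sorted(VALID_STRANDS)}"
            )


@dataclass
class ExomeResource:
    """Variant positions callable from exome sequencing plus target regions.

    ``variants`` holds exact (chromosome, 1-based position) sites.
    ``targets`` maps chromosome to a list of BED half-open ``[start, end)``
    intervals, stored as given in the BED file.
    """

    variants: set[tuple[str, int]]
    targets: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivals in self.targets.items():
            for start, end in ivals:
                if end <= start:
                    raise ValidationError(
                        f"target {chrom}:[{start},{end}): end must exceed start"
                    )
        stray = [v for v in self.variants if not self.contains_position(*v)]
        if stray and self.targets:
            warnings.warn(
                f"{len(stray)} exome variant(s) lie outside every target interval "
                f"(first: {stray[0]})",
                stacklevel=2,
            )

    def contains_position(self, chromosome: str, position: int) -> bool:
        """True iff the 1-based position falls inside some target interval."""
        return any(
            bed_interval_contains(position, s, e)
            for s, e in self.targets.get(chromosome, ())
        )

    def has_variant(self, chromosome: str, position: int) -> bool:
        return (chromosome, position) in self.variants


@dataclass(frozen=True)
class VarianceTable:
    """Per-SNP variance contributions of a predictor, in predictor order."""

    snp_ids: tuple[str, ...]
    contributions: np.ndarray
    total: float

    def __post_init__(self) -> None:
        contrib = np.asarray(self.contributions, dtype=float)
        object.__setattr__(self, "contributions", contrib)
        if np.any(contrib < 0):
            raise ValidationError("variance contributions must be non-negative")
        if not np.isclose(self.total, contrib.sum(), rtol=1e-12, atol=0.0):
            raise ValidationError("total does not equal the sum of contributions")

    @property
    def fractions(self) -> np.ndarray:
        """Per-SNP share of the total predictor variance (sums to 1)."""
        return self.contributions / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": list(self.snp_ids),
                "variance": self.contributions,
                "fraction": self.fractions,
            }
        )


# ---------------------------------------------------------------------------
# predictor TSV
# ---------------------------------------------------------------------------

_PREDICTOR_COLUMNS = ("snp_id", "chrom", "pos", "beta", "maf")


def _strip_chr(label: str) -> str:
    return label[3:] if label.startswith("chr") else label


def read_predictor(
    path, phenotype: str | None = None, normalize_chrom: bool = False
) -> Predictor:
    """Read a predictor weight table from a tab-separated file.

    The file must carry a header with columns ``snp_id``, ``chrom``, ``pos``,
    ``beta``, ``maf`` (and optionally ``counted_allele``). Row order is
    preserved. The phenotype name defaults to the file stem.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "snp_id": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse predictor TSV: {exc}") from exc
    missing = [c for c in _PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if phenotype is None:
        import os

        phenotype = os.path.splitext(os.path.basename(str(path)))[0]
    has_allele = "counted_allele" in df.columns
    snps = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        chrom = _strip_chr(row.chrom) if normalize_chrom else row.chrom
        allele = None
        if has_allele and isinstance(row.counted_allele, str):
            allele = row.counted_allele
        try:
            snps.append(
                PredictorSNP(
                    snp_id=str(row.snp_id),
                    chromosome=chrom,
                    position=int(row.pos),
                    beta=float(row.beta),
                    maf=float(row.maf),
                    counted_allele=allele,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {row_number}: {exc}") from exc
    return Predictor(phenotype, snps)


def write_predictor(predictor: Predictor, path) -> None:
    """Write a predictor as the tab-separated table read_predictor expects."""
    df = predictor.to_frame()
    if df["counted_allele"].isna().all():
        df = df.drop(columns=["counted_allele"])
    # %.17g round-trips doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene annotation (GFF3)
# ---------------------------------------------------------------------------

def read_genes(path, normalize_chrom: bool = False) -> list[GeneRecord]:
    """Load protein-coding gene records from a GFF3 annotation.

    Only features of type ``gene`` whose ``gene_type``/``biotype`` attribute
    is ``protein_coding`` are retained; coordinates are kept 1-based
    inclusive as written in the file.
    """
    _prescan_gff3(path)

    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = _first_attr(feat, "gene_type", "biotype", "gene_biotype")
        if biotype != "protein_coding":
            continue
        gene_id = _first_attr(feat, "gene_id", "ID") or feat.id
        gene_name = _first_attr(feat, "gene_name", "Name") or gene_id
        chrom = _strip_chr(feat.seqid) if normalize_chrom else feat.seqid
        records.append(
            GeneRecord(
                gene_id=gene_id,
                gene_name=gene_name,
                chromosome=chrom,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in VALID_STRANDS else ".",
                biotype=biotype,
            )
        )
    return records


def _first_attr(feat, *keys: str) -> str | None:
    for key in keys:
        if key in feat.attributes:
            values = feat.attributes[key]
            if values:
                return values[0]
    return None


def _prescan_gff3(path) -> None:
    """Cheap structural check so format errors carry a line number."""
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}, line {line_number}: expected 9 tab-separated "
                    f"fields, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(
                    f"{path}, line {line_number}: non-integer coordinates"
                ) from None
            if fields[2] == "gene" and start > end:
                raise ValidationError(
                    f"{path}, line {line_number}: gene start {start} > end {end}"
                )


def write_genes(genes: Sequence[GeneRecord], path) -> None:
    """Serialize gene records as a minimal GFF3 annotation."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};gene_id={g.gene_id};"
                f"gene_name={g.gene_name};gene_type={g.biotype}"
            )
            fh.write(
                f"{g.chromosome}\tprs_architect\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# exome resources (variant TSV + target BED)
# ---------------------------------------------------------------------------

def read_exome(variant_path, target_path, normalize_chrom: bool = False) -> ExomeResource:
    """Read an exome variant table (TSV: chrom, pos; 1-based) and target BED."""
    try:
        vdf = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"{variant_path}: cannot parse variant TSV: {exc}") from exc
    for col in ("chrom", "pos"):
        if col not in vdf.columns:
            raise FormatError(f"{variant_path}: missing required column {col!r}")
    fix = _strip_chr if normalize_chrom else (lambda c: c)
    variants = {(fix(c), int(p)) for c, p in zip(vdf["chrom"], vdf["pos"])}

    targets: dict[str, list[tuple[int, int]]] = {}
    with open(target_path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{target_path}, line {line_number}: BED needs >= 3 columns"
                )
            chrom = fix(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{target_path}, line {line_number}: non-integer coordinates"
                ) from None
            if end <= start:
                raise ValidationError(
                    f"{target_path}, line {line_number}: end {end} <= start {start}"
                )
            targets.setdefault(chrom, []).append((start, end))
    return ExomeResource(variants=variants, targets=targets)


def write_exome(exome: ExomeResource, variant_path, target_path) -> None:
    with open(variant_path, "w") as fh:
        fh.write("chrom\tpos\n")
        for chrom, pos in sorted(exome.variants):
            fh.write(f"{chrom}\t{pos}\n")
    with open(target_path, "w") as fh:
        for chrom in sorted(exome.targets):
            for start, end in sorted(exome.targets[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\n")
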