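"""Collapse qualifying variants to per-sample gene carriage and count
pathway carriers per cohort.

The unit of counting throughout is the *carrier sample*, never the
variant: a sample carries a gene if it has at least one qualifying
variant there (dominant collapsing, het or hom alike), and carries a
pathway if it carries at least one member gene.  This keeps the 2x2
tables downstream on independent sampling units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geneset_io import GeneSetCollection
from .variant_io import MISSING, QualifyingFilter, VariantRecord, is_qualifying

__all__ = [
    "CohortSpec",
    "CarrierMatrix",
    "PathwayCount",
    "read_manifest",
    "build_carrier_matrix",
    "pathway_carrier_counts",
    "one_per_family",
]


@dataclass(frozen=True)
class CohortSpec:
    cohort_id: str
    role: str  # "case" or "comparison"
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in ("case", "comparison"):
            raise ValueError(f"role must be case/comparison, got {self.role!r}")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample ids in cohort {self.cohort_id}")
        if not self.sample_ids:
            raise ValueError(f"cohort {self.cohort_id} has zero samples")

    def __len__(self) -> int:
        return len(self.sample_ids)


def validate_cohorts(cohorts: Sequence[CohortSpec]) -> None:
    """Exactly one case cohort; sample ids unique across cohorts."""
    roles = [c.role for c in cohorts]
    if roles.count("case") != 1:
        raise ValueError(
            f"exactly one cohort must have role=case, found {roles.count('case')}"
        )
    seen: set[str] = set()
    for c in cohorts:
        overlap = seen & set(c.sample_ids)
        if overlap:
            raise ValueError(
                f"sample ids shared across cohorts: {sorted(overlap)[:5]}"
            )
        seen |= set(c.sample_ids)


class CarrierMatrix:
    """Samples x genes binary carriage matrix.

    Entry (s, g) is 1 iff sample ``s`` carries at least one qualifying
    variant in gene ``g``.  Backed by a boolean ndarray with ordered
    sample and gene labels.
    """

    def __init__(
        self,
        samples: Sequence[str],
        genes: Sequence[str],
        carriage: np.ndarray,
    ) -> None:
        carriage = np.asarray(carriage)
        if carriage.dtype != bool:
            if not np.isin(carriage, (0, 1)).all():
                raise ValueError("carriage entries must be 0/1")
            carriage = carriage.astype(bool)
        if carriage.shape != (len(samples), len(genes)):
            raise ValueError(
                f"carriage shape {carriage.shape} != "
                f"({len(samples)}, {len(genes)})"
            )
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene symbols")
        self.samples = tuple(samples)
        self.genes = tuple(str(g).upper() for g in genes)
        self.carriage = carriage
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.carriage.shape

    def dose(self, sample: str, gene: str) -> int:
        return int(self.carriage[self._sample_index[sample],
                                 self._gene_index[gene.upper()]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.carriage.astype(np.int8),
            index=list(self.samples),
            columns=list(self.genes),
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CarrierMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            [str(s) for s in df.index],
            [str(g) for g in df.columns],
            df.to_numpy(),
        )

    def equivalent_to(self, other: "CarrierMatrix") -> bool:
        """Equality up to representation of carrier-free genes.

        A gene column that is all-zero may be stored or omitted without
        changing any downstream count; this compares the two matrices
        treating absent columns as all-zero.
        """
        if self.samples != other.samples:
            return False
        for gene in set(self.genes) | set(other.genes):
            a = (
                self.carriage[:, self._gene_index[gene]]
                if gene in self._gene_index
                else np.zeros(len(self.samples), dtype=bool)
            )
            b = (
                other.carriage[:, other._gene_index[gene]]
                if gene in other._gene_index
                else np.zeros(len(other.samples), dtype=bool)
            )
            if not np.array_equal(a, b):
                return False
        return True

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CarrierMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.genes == other.genes
            and np.array_equal(self.carriage, other.carriage)
        )


@dataclass(frozen=True)
class PathwayCount:
    set_id: str
    cohort_id: str
    n_carriers: int
    n_noncarriers: int

    @property
    def n_total(self) -> int:
        return self.n_carriers + self.n_noncarriers


def read_manifest(path: str | Path) -> tuple[list[CohortSpec], pd.DataFrame]:
    """Read a cohort manifest TSV (sample_id, cohort_id, role[, family_id]).

    Returns the cohort specs (in file order of first appearance) and the
    raw frame for family-aware subsampling.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample_id", "cohort_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    cohorts: list[CohortSpec] = []
    for cid in df["cohort_id"].drop_duplicates():
        sub = df[df["cohort_id"] == cid]
        roles = sub["role"].unique()
        if len(roles) != 1:
            raise ValueError(f"{path}: cohort {cid} has mixed roles {list(roles)}")
        cohorts.append(CohortSpec(cid, roles[0], tuple(sub["sample_id"])))
    validate_cohorts(cohorts)
    return cohorts, df


def one_per_family(
    manifest: pd.DataFrame, seed: int, prefer_role: str = "case"
) -> pd.DataFrame:
    """Keep one sample per family_id (probands/cases preferred, else a
    seeded random pick); rows without a family_id are kept as-is."""
    if "family_id" not in manifest.columns:
        return manifest
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    no_family = manifest["family_id"].isna() | (manifest["family_id"] == "")
    keep.extend(manifest.index[no_family])
    for _, fam in manifest[~no_family].groupby("family_id", sort=True):
        preferred = fam[fam["role"] == prefer_role]
        pool = preferred if len(preferred) else fam
        keep.append(int(rng.choice(pool.index.to_numpy())))
    return manifest.loc[sorted(keep)].reset_index(drop=True)


def build_carrier_matrix(
    variants: Iterable[VariantRecord],
    qfilter: QualifyingFilter,
    samples: Sequence[str],
    max_missing_fraction: float | None = None,
) -> CarrierMatrix:
    """Collapse a variant stream to per-sample, per-gene carrier status.

    A sample carries a gene iff it has allele dose >= 1 for at least one
    qualifying variant there; missing genotypes never create carriage.
    With ``max_missing_fraction`` set, samples whose fraction of missing
    genotype calls across qualifying variants exceeds it are dropped
    (strict mode); the default keeps every sample.
    """
    samples = list(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    gene_order: list[str] = []
    gene_index: dict[str, int] = {}
    cols: list[np.ndarray] = []
    n_missing = np.zeros(len(samples), dtype=np.int64)
    n_qualifying = 0

    for v in variants:
        unknown = set(v.genotypes) - sample_index.keys()
        if unknown:
            raise ValueError(
                f"genotypes name samples absent from the sample list: "
                f"{sorted(unknown)[:5]}"
            )
        if not is_qualifying(v, qfilter):
            continue
        n_qualifying += 1
        gene = v.gene.upper()
        if gene not in gene_index:
            gene_index[gene] = len(gene_order)
            gene_order.append(gene)
            cols.append(np.zeros(len(samples), dtype=bool))
        col = cols[gene_index[gene]]
        for s, dose in v.genotypes.items():
            i = sample_index[s]
            if dose == MISSING:
                n_missing[i] += 1
            elif dose >= 1:
                col[i] = True

    if n_qualifying == 0:
        warnings.warn("no qualifying variants; carrier matrix is all-zero")
        return CarrierMatrix(samples, [], np.zeros((len(samples), 0), dtype=bool))

    carriage = np.column_stack(cols) if cols else np.zeros((len(samples), 0), bool)
    if max_missing_fraction is not None and n_qualifying > 0:
        frac = n_missing / n_qualifying
        keep = frac <= max_missing_fraction
        samples = [s for s, k in zip(samples, keep) if k]
        carriage = carriage[keep]
    return CarrierMatrix(samples, gene_order, carriage)


def pathway_carrier_counts(
    matrix: CarrierMatrix,
    collection: GeneSetCollection,
    cohorts: Sequence[CohortSpec],
) -> list[PathwayCount]:
    """Count pathway-carrier samples per (pathway, cohort).

    A sample is a pathway carrier iff it carries >= 1 member gene;
    member genes absent from the matrix contribute nothing.
    """
    flags = pathway_carrier_flags(matrix, collection)
    out: list[PathwayCount] = []
    sidx = {s: i for i, s in enumerate(matrix.samples)}
    for cohort in cohorts:
        missing = [s for s in cohort.sample_ids if s not in sidx]
        if missing:
            raise ValueError(
                f"cohort {cohort.cohort_id} samples absent from matrix: "
                f"{missing[:5]}"
            )
        rows = np.fromiter(
            (sidx[s] for s in cohort.sample_ids), dtype=np.int64,
            count=len(cohort.sample_ids),
        )
        sub = flags[rows]  # cohort samples x sets
        carriers = sub.sum(axis=0)
        n = len(cohort.sample_ids)
        for j, gs in enumerate(collection.sets):
            out.append(
                PathwayCount(gs.set_id, cohort.cohort_id,
                             int(carriers[j]), n - int(carriers[j]))
            )
    return out


def pathway_carrier_flags(
    matrix: CarrierMatrix, collection: GeneSetCollection
) -> np.ndarray:
    """Boolean samples x pathways matrix of pathway carriage."""
    gidx = {g: i for i, g in enumerate(matrix.genes)}
    membership = np.zeros((len(matrix.genes), len(collection)), dtype=bool)
    for j, gs in enumerate(collection.sets):
        for g in gs.genes:
            i = gidx.get(g)
            if i is not None:
                membership[i, j] = True
    if matrix.carriage.size == 0 or membership.size == 0:
        return np.zeros((len(matrix.samples), len(collection)), dtype=bool)
    # float32 matmul is far faster than boolean any() loops at this size
    hits = matrix.carriage.astype(np.float32) @ membership.astype(np.float32)
    return hits > 0.5
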