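"""Synthetic multi-cohort generator with planted pathway effects.

Emulates the statistical structure the burden analysis assumes: one
case cohort (default n=39) and several comparison cohorts (defaults
86, 310, 1,296, 2,990 and 385 samples), each sample carrying rare
qualifying variants independently per gene at a baseline Bernoulli
rate, with the case cohort's rate multiplied by a configurable relative
risk inside *planted* pathways.  Output is available both as an
in-memory carrier matrix and as a fully formed annotated VCF (flat
INFO tags GENE/CSQ_CLASS/POP_AC/POP_AN) plus cohort manifest, GMT and
truth table, so every upstream module is exercisable without any
external download.

Genes are independent within a sample (no linkage disequilibrium) and
samples are unrelated — exactly the exchangeability the 2x2 framework
and the label-permutation null assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import CarrierMatrix, CohortSpec, validate_cohorts
from .geneset_io import GeneSet, GeneSetCollection

__all__ = [
    "GeneSetSpec",
    "SyntheticCohortConfig",
    "generate_cohorts",
    "emit_vcf",
    "DEFAULT_COHORT_SIZES",
]

# Study-scale defaults: one case cohort and five clinical comparison
# cohorts (obesity, myopathy, autism-ADHD, rare disease, immune
# dysregulation sized 86/310/1296/2990/385).
DEFAULT_COHORT_SIZES: dict[str, int] = {
    "misc": 39,
    "obesity": 86,
    "myopathy": 310,
    "autism_adhd": 1296,
    "rare_disease": 2990,
    "immune_dysreg": 385,
}

_QUALIFYING_TERMS = (
    "stop_gained",
    "start_lost",
    "frameshift_insertion",
    "frameshift_deletion",
    "splice_donor_variant",
)
_DECOY_TERMS = ("missense_variant", "synonymous_variant", "intron_variant")


@dataclass(frozen=True)
class GeneSetSpec:
    """Shape of the generated pathway collection: ``n_sets`` sets with
    sizes drawn uniformly from [min_size, max_size] over the gene
    universe."""

    n_sets: int = 200
    min_size: int = 10
    max_size: int = 100

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("invalid gene-set spec")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_SIZES)
    )
    case_cohort: str = "misc"
    n_genes: int = 2000
    baseline_rate: float = 0.002
    planted_effects: tuple[tuple[str, float], ...] = ()
    geneset_spec: GeneSetSpec = field(default_factory=GeneSetSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case_cohort not in self.cohort_sizes:
            raise ValueError(f"case cohort {self.case_cohort!r} not in cohort_sizes")
        if any(n < 1 for n in self.cohort_sizes.values()):
            raise ValueError("all cohort sizes must be >= 1")
        if not 0 < self.baseline_rate < 1:
            raise ValueError("baseline_rate must be in (0, 1)")
        for set_id, rr in self.planted_effects:
            if rr <= 0:
                raise ValueError(f"relative risk for {set_id} must be > 0")
            if self.baseline_rate * rr > 1:
                raise ValueError(
                    f"effective rate {self.baseline_rate * rr} > 1 for {set_id}"
                )
        object.__setattr__(
            self, "planted_effects", tuple(self.planted_effects)
        )


def _gene_symbols(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]


def _make_genesets(cfg: SyntheticCohortConfig,
                   rng: np.random.Generator) -> GeneSetCollection:
    genes = np.array(_gene_symbols(cfg.n_genes))
    spec = cfg.geneset_spec
    width = max(4, len(str(spec.n_sets)))
    sets = []
    for i in range(1, spec.n_sets + 1):
        size = int(rng.integers(spec.min_size,
                                min(spec.max_size, cfg.n_genes) + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(
            GeneSet(f"SET{i:0{width}d}", f"synthetic pathway {i}",
                    frozenset(members))
        )
    return GeneSetCollection(
        tuple(sets), provenance=f"synthetic(seed={cfg.seed})"
    )


def generate_cohorts(
    cfg: SyntheticCohortConfig,
) -> tuple[CarrierMatrix, list[CohortSpec], GeneSetCollection, pd.DataFrame]:
    """Draw per-(sample, gene) carriage and return the full scenario.

    Case samples carry genes of a planted pathway at
    ``baseline_rate * relative_risk`` (genes in several planted sets take
    the maximum); every other (sample, gene) pair uses the baseline.
    The truth table lists each planted (set_id, relative_risk, n_genes).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    collection = _make_genesets(cfg, rng)
    genes = _gene_symbols(cfg.n_genes)
    gidx = {g: i for i, g in enumerate(genes)}

    cohorts: list[CohortSpec] = []
    sample_ids: list[str] = []
    case_mask_parts: list[np.ndarray] = []
    for cid, n in cfg.cohort_sizes.items():
        role = "case" if cid == cfg.case_cohort else "comparison"
        ids = tuple(f"{cid}_{i:05d}" for i in range(1, n + 1))
        cohorts.append(CohortSpec(cid, role, ids))
        sample_ids.extend(ids)
        case_mask_parts.append(np.full(n, role == "case"))
    validate_cohorts(cohorts)
    case_mask = np.concatenate(case_mask_parts)

    # per-gene case rate = baseline * max RR over planted sets with that gene
    gene_rr = np.ones(cfg.n_genes)
    truth_rows = []
    for set_id, rr in cfg.planted_effects:
        gs = collection[set_id]
        for g in gs.genes:
            i = gidx[g]
            gene_rr[i] = max(gene_rr[i], rr)
        truth_rows.append(
            {"set_id": set_id, "relative_risk": rr, "n_genes": len(gs)}
        )
    case_rate = np.minimum(cfg.baseline_rate * gene_rr, 1.0)

    u = rng.random((len(sample_ids), cfg.n_genes))
    rates = np.where(case_mask[:, None], case_rate[None, :],
                     cfg.baseline_rate)
    carriage = u < rates
    matrix = CarrierMatrix(sample_ids, genes, carriage)
    truth = pd.DataFrame(truth_rows,
                         columns=["set_id", "relative_risk", "n_genes"])
    return matrix, cohorts, collection, truth


def emit_vcf(
    matrix: CarrierMatrix,
    cfg: SyntheticCohortConfig,
    out_dir: str | Path,
    cohorts: Sequence[CohortSpec] | None = None,
    collection: GeneSetCollection | None = None,
    truth: pd.DataFrame | None = None,
    decoy_fraction: float = 0.0,
) -> dict[str, Path]:
    """Realize a carrier matrix as an annotated VCF plus side files.

    Each gene with at least one carrier becomes one synthetic locus with
    a heterozygous qualifying variant (consequence drawn among the five
    qualifying classes, POP_AC uniform in 0..10 at POP_AN=280,000);
    carriers are 0/1, everyone else 0/0.  ``decoy_fraction`` injects
    that proportion of additional non-qualifying records (wrong
    consequence class or common allele) with arbitrary genotypes, which
    the qualifying filter must remove.  Re-reading the file and
    rebuilding the carrier matrix reproduces ``matrix`` exactly
    (restricted to genes that have carriers).

    Returns a dict of written paths (vcf, manifest, gmt, truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xEC]))
    paths: dict[str, Path] = {}

    vcf_path = out / "cohorts.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=pathburden-synthetic(seed={cfg.seed})",
        "##contig=<ID=chr1>",
        '##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="Consequence term">',
        '##INFO=<ID=POP_AC,Number=A,Type=Integer,Description="Reference population ALT allele count">',
        '##INFO=<ID=POP_AN,Number=A,Type=Integer,Description="Reference population allele number">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    records: list[tuple[int, str]] = []
    pos = 1000
    for j, gene in enumerate(matrix.genes):
        carriers = matrix.carriage[:, j]
        if not carriers.any():
            continue
        term = _QUALIFYING_TERMS[int(rng.integers(len(_QUALIFYING_TERMS)))]
        ref, alt = _alleles_for(term, rng)
        ac = int(rng.integers(0, 11))
        gts = "\t".join("0/1" if c else "0/0" for c in carriers)
        info = f"GENE={gene};CSQ_CLASS={term};POP_AC={ac};POP_AN=280000"
        records.append(
            (pos, f"chr1\t{pos}\t{gene}_q\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}")
        )
        pos += 1000

    if decoy_fraction > 0:
        n_decoys = int(round(decoy_fraction * max(len(records), 1)))
        for k in range(n_decoys):
            gene = matrix.genes[int(rng.integers(len(matrix.genes)))] \
                if matrix.genes else "GENE0001"
            if rng.random() < 0.5:
                term = _DECOY_TERMS[int(rng.integers(len(_DECOY_TERMS)))]
                ac = int(rng.integers(0, 11))
            else:  # qualifying class but too common
                term = _QUALIFYING_TERMS[int(rng.integers(len(_QUALIFYING_TERMS)))]
                ac = int(rng.integers(11, 5000))
            ref, alt = _alleles_for(term, rng)
            gts = "\t".join(
                "0/1" if rng.random() < 0.05 else "0/0" for _ in matrix.samples
            )
            info = f"GENE={gene};CSQ_CLASS={term};POP_AC={ac};POP_AN=280000"
            records.append(
                (pos, f"chr1\t{pos}\tdecoy_{k}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t{gts}")
            )
            pos += 1000
    records.sort(key=lambda r: r[0])
    vcf_path.write_text("\n".join(lines + [r[1] for r in records]) + "\n")
    paths["vcf"] = vcf_path

    if cohorts is not None:
        mpath = out / "manifest.tsv"
        rows = ["sample_id\tcohort_id\trole"]
        for c in cohorts:
            rows.extend(f"{s}\t{c.cohort_id}\t{c.role}" for s in c.sample_ids)
        mpath.write_text("\n".join(rows) + "\n")
        paths["manifest"] = mpath
    if collection is not None:
        gpath = out / "pathways.gmt"
        glines = [
            "\t".join([gs.set_id, gs.name, *sorted(gs.genes)])
            for gs in collection.sets
        ]
        gpath.write_text("\n".join(glines) + "\n")
        paths["gmt"] = gpath
    if truth is not None:
        tpath = out / "truth.tsv"
        truth.to_csv(tpath, sep="\t", index=False)
        paths["truth"] = tpath
    return paths


def _alleles_for(term: str, rng: np.random.Generator) -> tuple[str, str]:
    """REF/ALT pair consistent with the consequence term's indel class."""
    bases = "ACGT"
    b = lambda: bases[int(rng.integers(4))]
    if term == "frameshift_insertion":
        ref = b()
        return ref, ref + b() + b()
    if term == "frameshift_deletion":
        anchor = b()
        return anchor + b() + b(), anchor
    ref = b()
    alt = b()
    while alt == ref:
        alt = b()
    return ref, alt
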