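"""End-to-end orchestration: filter -> collapse -> count -> Fisher per
comparison -> Monte Carlo vs pooled -> adjust -> consensus -> report.

One :class:`RunConfig` drives the whole analysis.  A single qualifying
filter is applied to every cohort — per-cohort overrides are refused at
validation time, because differential filtering between case and
comparison cohorts is exactly the selection bias the shared-parameter
design exists to prevent.  All outputs are deterministic given
(config, seed), including across worker counts: per-pathway Monte Carlo
generators are keyed by pathway id, not by scheduling order.
"""

from __future__ import annotations

import concurrent.futures
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    CarrierMatrix,
    CohortSpec,
    pathway_carrier_flags,
    read_manifest,
    build_carrier_matrix,
    one_per_family,
    validate_cohorts,
)
from .enrichment import (
    EnrichmentResult,
    FisherResult,
    adjust_pvalues,
    call_consensus,
    fisher_greater_pvalues,
    fisher_enrichment,
    odds_ratio_label,
)
from .geneset_io import GeneSetCollection, read_gmt
from .montecarlo import MCConfig, MCResult, mc_pathway_test, mc_standard_error
from .variant_io import QualifyingFilter, read_vcf

logger = logging.getLogger("pathburden")

__all__ = ["RunConfig", "RunResult", "run_pipeline", "summarize_run", "load_config"]


@dataclass
class RunConfig:
    manifest: Path
    gmt: Path
    vcfs: tuple[Path, ...] = ()
    carrier_matrix: Path | None = None
    annotation_dialect: str = "info_tags"
    qualifying_filter: QualifyingFilter = field(default_factory=QualifyingFilter)
    mc: MCConfig = field(default_factory=MCConfig)
    alternative: str = "greater"
    alpha: float = 0.05
    multiplicity: str = "benjamini_hochberg"
    require_all_comparisons: bool = True
    out_dir: Path = Path("pathburden_results")
    threads: int = 1
    max_missing_fraction: float | None = None
    family_aware: bool = False

    def validate(self) -> None:
        if bool(self.vcfs) == (self.carrier_matrix is not None):
            raise ValueError("provide either vcfs or carrier_matrix, not both")
        for p in (self.manifest, self.gmt, *self.vcfs):
            if not Path(p).exists():
                raise FileNotFoundError(str(p))
        if self.carrier_matrix is not None and not Path(self.carrier_matrix).exists():
            raise FileNotFoundError(str(self.carrier_matrix))
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")


_FORBIDDEN_KEYS = ("cohort_filters", "per_cohort_filters", "filter_overrides")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration.

    Any per-cohort filter override key is rejected outright: the design
    requires one shared qualifying filter across all cohorts.
    """
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    for key in _FORBIDDEN_KEYS:
        if key in raw:
            raise ValueError(
                f"{key!r} is not allowed: the qualifying filter must be "
                "identical for every cohort (selection-bias guard)"
            )
    qf_raw = raw.pop("qualifying_filter", {})
    if isinstance(qf_raw, dict):
        for key in _FORBIDDEN_KEYS:
            if key in qf_raw:
                raise ValueError(f"{key!r} is not allowed inside qualifying_filter")
        allowed = qf_raw.get("allowed_consequences")
        qfilter = QualifyingFilter(
            allowed_consequences=frozenset(allowed)
            if allowed
            else QualifyingFilter().allowed_consequences,
            max_pop_allele_count=int(qf_raw.get("max_pop_allele_count", 10)),
            reference_allele_number=int(
                qf_raw.get("reference_allele_number", 280_000)
            ),
        )
    else:
        raise ValueError("qualifying_filter must be a mapping")
    mc_raw = raw.pop("mc", {})
    mc = MCConfig(
        iterations=int(mc_raw.get("iterations", 100_000)),
        seed=int(mc_raw.get("seed", raw.get("seed", 0))),
        adaptive_alpha=mc_raw.get("adaptive_alpha"),
    )
    raw.pop("seed", None)
    cfg = RunConfig(
        manifest=Path(raw.pop("manifest")),
        gmt=Path(raw.pop("gmt")),
        vcfs=tuple(Path(p) for p in raw.pop("vcfs", [])),
        carrier_matrix=(
            Path(raw["carrier_matrix"]) if raw.get("carrier_matrix") else None
        ),
        annotation_dialect=raw.pop("annotation_dialect", "info_tags"),
        qualifying_filter=qfilter,
        mc=mc,
        alternative=raw.pop("alternative", "greater"),
        alpha=float(raw.pop("alpha", 0.05)),
        multiplicity=raw.pop("multiplicity", "benjamini_hochberg"),
        require_all_comparisons=bool(raw.pop("require_all_comparisons", True)),
        out_dir=Path(raw.pop("out_dir", "pathburden_results")),
        threads=int(raw.pop("threads", 1)),
        max_missing_fraction=raw.pop("max_missing_fraction", None),
        family_aware=bool(raw.pop("family_aware", False)),
    )
    cfg.validate()
    return cfg


@dataclass
class RunResult:
    results: list[EnrichmentResult]
    enrichment_frame: pd.DataFrame   # one row per (pathway, comparison)
    summary_frame: pd.DataFrame      # one row per pathway
    stage_counts: dict[str, int]
    manifest: dict[str, Any]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyse(
    matrix: CarrierMatrix,
    collection: GeneSetCollection,
    cohorts: Sequence[CohortSpec],
    *,
    mc: MCConfig,
    alternative: str = "greater",
    alpha: float = 0.05,
    multiplicity: str = "benjamini_hochberg",
    require_all_comparisons: bool = True,
    threads: int = 1,
) -> list[EnrichmentResult]:
    """Core analysis on an in-memory carrier matrix.

    Fisher's exact test of the case cohort against each comparison
    cohort for every pathway, Monte Carlo permutation against the pooled
    comparisons, multiplicity adjustment across pathways (within each
    comparison, and across pathways for the Monte Carlo p), then the
    consensus call.
    """
    validate_cohorts(cohorts)
    case = next(c for c in cohorts if c.role == "case")
    comparisons = [c for c in cohorts if c.role == "comparison"]
    if not comparisons:
        raise ValueError("at least one comparison cohort is required")

    flags = pathway_carrier_flags(matrix, collection)  # samples x sets
    sidx = {s: i for i, s in enumerate(matrix.samples)}

    def rows_of(c: CohortSpec) -> np.ndarray:
        missing = [s for s in c.sample_ids if s not in sidx]
        if missing:
            raise ValueError(
                f"cohort {c.cohort_id} samples absent from matrix: {missing[:5]}"
            )
        return np.fromiter((sidx[s] for s in c.sample_ids), np.int64,
                           count=len(c.sample_ids))

    case_flags = flags[rows_of(case)]
    case_carriers = case_flags.sum(axis=0).astype(np.int64)
    n_case = len(case)

    set_ids = list(collection.set_ids)
    n_sets = len(set_ids)

    # Fisher per comparison cohort (vectorized across pathways)
    fisher: dict[str, dict[str, FisherResult]] = {s: {} for s in set_ids}
    adjusted: dict[str, dict[str, float]] = {s: {} for s in set_ids}
    for comp in comparisons:
        comp_flags = flags[rows_of(comp)]
        comp_carriers = comp_flags.sum(axis=0).astype(np.int64)
        n_comp = len(comp)
        if alternative == "greater":
            pvals = fisher_greater_pvalues(case_carriers, n_case,
                                           comp_carriers, n_comp)
        else:
            pvals = np.array([
                fisher_enrichment(
                    int(a), n_case - int(a), int(c), n_comp - int(c),
                    alternative=alternative,
                )[0]
                for a, c in zip(case_carriers, comp_carriers)
            ])
        adj = adjust_pvalues(pvals, multiplicity)
        for j, sid in enumerate(set_ids):
            a, c = int(case_carriers[j]), int(comp_carriers[j])
            _, odds = fisher_enrichment(a, n_case - a, c, n_comp - c,
                                        alternative="greater")
            fisher[sid][comp.cohort_id] = FisherResult(
                set_id=sid,
                comparison_cohort_id=comp.cohort_id,
                table=(a, n_case - a, c, n_comp - c),
                p_value=float(pvals[j]),
                odds_ratio=odds,
                alternative=alternative,
            )
            adjusted[sid][comp.cohort_id] = float(adj[j])

    # Monte Carlo vs pooled comparisons, per pathway
    pooled_rows = np.concatenate([rows_of(c) for c in comparisons])
    pooled_flags = flags[pooled_rows]

    def one_mc(j: int) -> MCResult:
        return mc_pathway_test(
            case_flags[:, j].astype(np.int8),
            pooled_flags[:, j].astype(np.int8),
            mc,
            set_id=set_ids[j],
        )

    if threads > 1:
        with concurrent.futures.ThreadPoolExecutor(max_workers=threads) as ex:
            mc_results = list(ex.map(one_mc, range(n_sets)))
    else:
        mc_results = [one_mc(j) for j in range(n_sets)]

    mc_adj = adjust_pvalues([r.empirical_p for r in mc_results], multiplicity)

    out: list[EnrichmentResult] = []
    for j, sid in enumerate(set_ids):
        res = EnrichmentResult(
            set_id=sid,
            fisher=fisher[sid],
            mc_p=mc_results[j].empirical_p,
            mc_iterations=mc_results[j].iterations_used,
            adjusted_p=adjusted[sid],
            mc_adjusted_p=float(mc_adj[j]),
            consensus=False,
        )
        res.consensus = call_consensus(
            res, alpha=alpha, require_all_comparisons=require_all_comparisons,
            primary_comparison=comparisons[0].cohort_id,
        )
        out.append(res)
    return out


def _frames(results: list[EnrichmentResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for r in results:
        for cid, f in r.fisher.items():
            a, b, c, d = f.table
            rows.append({
                "set_id": r.set_id, "comparison": cid,
                "case_carriers": a, "case_noncarriers": b,
                "comparison_carriers": c, "comparison_noncarriers": d,
                "p_value": f.p_value,
                "odds_ratio": odds_ratio_label(f.odds_ratio),
                "adjusted_p": r.adjusted_p[cid],
            })
    enrich = pd.DataFrame(rows)
    summary = pd.DataFrame([
        {
            "set_id": r.set_id,
            "mc_p": r.mc_p,
            "mc_adjusted_p": r.mc_adjusted_p,
            "mc_iterations": r.mc_iterations,
            "max_fisher_p": max(f.p_value for f in r.fisher.values()),
            "consensus": int(r.consensus),
        }
        for r in results
    ])
    return enrich, summary


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Run the full analysis from files and write the results bundle."""
    cfg.validate()
    cohorts, manifest_df = read_manifest(cfg.manifest)
    if cfg.family_aware:
        manifest_df = one_per_family(manifest_df, seed=cfg.mc.seed)
        cohorts, _ = _cohorts_from_frame(manifest_df)
    collection = read_gmt(cfg.gmt)
    stage_counts: dict[str, int] = {}

    all_samples = [s for c in cohorts for s in c.sample_ids]
    if cfg.carrier_matrix is not None:
        matrix = CarrierMatrix.from_tsv(cfg.carrier_matrix)
        stage_counts["variants_read"] = -1
        stage_counts["qualifying_variants"] = -1
    else:
        records = []
        n_read = 0
        vcf_samples: set[str] = set()
        for path in cfg.vcfs:
            for v in read_vcf(path, cfg.annotation_dialect):
                n_read += 1
                vcf_samples.update(v.genotypes)
                records.append(v)
        orphans = sorted(set(all_samples) - vcf_samples)
        if orphans:
            raise ValueError(
                f"manifest samples absent from all VCFs: {orphans[:10]}"
            )
        stage_counts["variants_read"] = n_read
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            matrix = build_carrier_matrix(
                records, cfg.qualifying_filter, all_samples,
                max_missing_fraction=cfg.max_missing_fraction,
            )
        stage_counts["qualifying_genes"] = len(matrix.genes)
    missing = sorted(set(all_samples) - set(matrix.samples))
    if missing and cfg.max_missing_fraction is None:
        raise ValueError(f"samples missing from carrier matrix: {missing[:10]}")

    results = analyse(
        matrix, collection, cohorts,
        mc=cfg.mc, alternative=cfg.alternative, alpha=cfg.alpha,
        multiplicity=cfg.multiplicity,
        require_all_comparisons=cfg.require_all_comparisons,
        threads=cfg.threads,
    )
    for c in cohorts:
        stage_counts[f"n_{c.cohort_id}"] = len(c)
    stage_counts["n_pathways"] = len(collection)
    stage_counts["n_consensus"] = sum(r.consensus for r in results)

    enrich, summary = _frames(results)
    manifest = {
        "pathburden_version": __version__,
        "seed": cfg.mc.seed,
        "mc_iterations": cfg.mc.iterations,
        "alpha": cfg.alpha,
        "multiplicity": cfg.multiplicity,
        "alternative": cfg.alternative,
        "qualifying_filter": {
            "allowed_consequences": sorted(
                cfg.qualifying_filter.allowed_consequences
            ),
            "max_pop_allele_count": cfg.qualifying_filter.max_pop_allele_count,
            "reference_allele_number": cfg.qualifying_filter.reference_allele_number,
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in (cfg.manifest, cfg.gmt, *cfg.vcfs)
        },
        "stage_counts": stage_counts,
        "library_versions": _library_versions(),
    }
    _write_bundle(cfg, enrich, summary, manifest)
    return RunResult(results, enrich, summary, stage_counts, manifest)


def _cohorts_from_frame(df: pd.DataFrame) -> tuple[list[CohortSpec], pd.DataFrame]:
    cohorts = []
    for cid in df["cohort_id"].drop_duplicates():
        sub = df[df["cohort_id"] == cid]
        cohorts.append(CohortSpec(cid, sub["role"].iloc[0], tuple(sub["sample_id"])))
    validate_cohorts(cohorts)
    return cohorts, df


def _library_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _provenance_header(manifest: Mapping[str, Any]) -> str:
    qf = manifest["qualifying_filter"]
    return "\n".join([
        f"# pathburden {manifest['pathburden_version']}",
        f"# seed={manifest['seed']} mc_iterations={manifest['mc_iterations']} "
        f"alpha={manifest['alpha']} multiplicity={manifest['multiplicity']} "
        f"alternative={manifest['alternative']}",
        f"# filter: AC<={qf['max_pop_allele_count']}/"
        f"{qf['reference_allele_number']} "
        f"classes={','.join(qf['allowed_consequences'])}",
    ]) + "\n"


def _write_bundle(cfg: RunConfig, enrich: pd.DataFrame,
                  summary: pd.DataFrame, manifest: dict[str, Any]) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _provenance_header(manifest)
    for name, df in (("enrichment", enrich), ("summary", summary)):
        with open(out / f"{name}.tsv", "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        df.to_json(out / f"{name}.json", orient="records", indent=2)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def summarize_run(result: RunResult, top_n: int = 10) -> tuple[str, dict[str, Any]]:
    """Human-readable report: stage counts, top pathways, QC flags.

    Flags any pathway whose pooled Fisher p and Monte Carlo p disagree by
    more than 4 Monte Carlo standard errors — an internal consistency
    alarm, since the permutation null and the hypergeometric null are
    the same distribution.
    """
    lines = ["pathburden run summary", "=" * 22, "", "Stage counts:"]
    for k, v in result.stage_counts.items():
        lines.append(f"  {k}: {v}")
    qc_flags: list[str] = []
    for r in result.results:
        if r.mc_iterations == 0:
            continue
        # pooled Fisher table from the per-comparison tables
        a = next(iter(r.fisher.values())).table[0]
        n_case = a + next(iter(r.fisher.values())).table[1]
        c = sum(f.table[2] for f in r.fisher.values())
        n_pool = sum(f.table[2] + f.table[3] for f in r.fisher.values())
        pooled_p = float(fisher_greater_pvalues(
            np.array([a]), n_case, np.array([c]), n_pool)[0])
        se = mc_standard_error(r.mc_p, r.mc_iterations)
        if abs(pooled_p - r.mc_p) > 4.0 * max(se, 1e-12):
            qc_flags.append(r.set_id)
    summary = result.summary_frame.sort_values(
        ["mc_p", "set_id"]).head(top_n)
    if len(result.results) == 0:
        lines.append("\nNo pathways tested — no qualifying variants.")
    else:
        lines.append(f"\nTop {len(summary)} pathways by Monte Carlo p:")
        for _, row in summary.iterrows():
            lines.append(
                f"  {row.set_id}  mc_p={row.mc_p:.3g} "
                f"mc_adj={row.mc_adjusted_p:.3g} "
                f"consensus={'yes' if row.consensus else 'no'}"
            )
    if qc_flags:
        lines.append(f"\nQC ALERT — Fisher/Monte-Carlo disagreement: {qc_flags}")
    else:
        lines.append("\nQC: Fisher and Monte Carlo agree within 4 SE everywhere.")
    report = {
        "stage_counts": result.stage_counts,
        "top_pathways": summary.to_dict(orient="records"),
        "qc_flags": qc_flags,
    }
    return "\n".join(lines) + "\n", report
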