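"""End-to-end orchestration: simulate/read -> normalize -> differential
expression -> biomarker evaluation -> (optional) function prediction.

One global seed deterministically derives per-stage seeds by hashing the
stage name, so re-running with the same config and seed reproduces every
emitted table bit-identically while stages stay stochastically isolated.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, biomarker, diffexpr, funcpred, normalization, synthetic

logger = logging.getLogger("lncq")


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 from the global seed."""
    return (zlib.crc32(f"{global_seed}:{stage}".encode()) ^ global_seed) % (2**31)


def load_default_comparisons(design: str) -> list[diffexpr.ComparisonSpec]:
    """Comparison lists shipped with the package (one per cohort design)."""
    text = (
        resources.files("lncq").joinpath(f"configs/{design}_comparisons.yaml").read_text()
    )
    return parse_comparisons(yaml.safe_load(text)["comparisons"])


def parse_comparisons(entries: list[dict]) -> list[diffexpr.ComparisonSpec]:
    return [
        diffexpr.ComparisonSpec(
            name=e["name"],
            group_a=e["group_a"],
            group_b=e["group_b"],
            covariates=e.get("covariates", []),
            significance=e.get("significance", "adjusted_p"),
            alpha=e.get("alpha", 0.05),
            positive_label=e.get("positive_label", "a"),
        )
        for e in entries
    ]


@dataclass
class RunConfig:
    cohort: dict
    normalization: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    biomarker: dict = field(default_factory=dict)
    function_prediction: dict = field(default_factory=dict)
    outdir: str = "lncq_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            cohort=raw.get("cohort", {"source": "synthetic", "design": "replication"}),
            normalization=raw.get("normalization", {}),
            comparisons=raw.get("comparisons", []),
            biomarker=raw.get("biomarker", {}),
            function_prediction=raw.get("function_prediction", {}),
            outdir=raw.get("outdir", "lncq_out"),
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class RunArtifacts:
    outdir: Path
    paths: dict[str, str]
    config: dict
    seed: int
    complete: bool = False

    def require_complete(self) -> None:
        if not self.complete:
            raise ValueError("run artifacts are incomplete")
        missing = [p for p in self.paths.values() if not Path(p).exists()]
        if missing:
            raise ValueError(f"declared artifacts missing on disk: {missing}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _cohort_inputs(config: RunConfig, seed: int):
    c = config.cohort
    if c.get("source", "synthetic") == "synthetic":
        design_name = c.get("design", "replication")
        if design_name == "replication":
            design = synthetic.replication_design()
            roles = synthetic.replication_feature_roles()
            effects = synthetic.replication_effects(noise_sd=c.get("noise_sd", 0.8))
            duplicates = c.get("duplicates", True)
            refs = synthetic.REPLICATION_REFERENCES
        elif design_name == "discovery":
            design = synthetic.discovery_design()
            roles = synthetic.discovery_feature_roles()
            effects = synthetic.discovery_effects(noise_sd=c.get("noise_sd", 0.8))
            duplicates = c.get("duplicates", False)
            refs = synthetic.DISCOVERY_REFERENCES
        else:
            raise ValueError(f"unknown synthetic design {design_name!r}")
        meta = synthetic.generate_cohort_metadata(design, stage_seed(seed, "cohort"))
        ct = synthetic.generate_ct_matrix(
            meta, effects, roles, stage_seed(seed, "ct"), duplicates=duplicates
        )
        return meta, ct, refs, design_name
    meta = pd.read_csv(c["metadata"], sep="\t", index_col=0)
    ct = normalization.read_ct_table(c["ct"], c["roles"])
    refs = config.normalization.get("reference_features")
    if refs is None:
        raise ValueError("reference_features required for file-based cohorts")
    return meta, ct, refs, None


def run_pipeline(config: RunConfig) -> RunArtifacts:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    paths: dict[str, str] = {}
    t0 = time.time()

    # --- cohort ---------------------------------------------------------
    try:
        meta, ct, refs, design_name = _cohort_inputs(config, seed)
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    normalization.write_ct_table(ct, outdir / "ct.tsv", outdir / "roles.tsv")
    paths.update(
        metadata=str(outdir / "metadata.tsv"),
        ct=str(outdir / "ct.tsv"),
        roles=str(outdir / "roles.tsv"),
    )
    logger.info("cohort: %d samples, %d features", meta.shape[0], ct.ct.shape[0])

    # --- normalization --------------------------------------------------
    try:
        rules = normalization.QCRules(**config.normalization.get("qc", {}))
        ct_f, qc_report = normalization.qc_filter(ct, rules)
        refs = config.normalization.get("reference_features", refs)
        dct = normalization.delta_ct(ct_f, refs)
        exprs = normalization.normalize_expression(dct)
    except Exception as exc:
        raise StageError("normalization", exc) from exc
    meta = meta.loc[[s for s in meta.index if s in set(exprs.expr.columns)]]
    exprs.expr.to_csv(outdir / "expression.tsv", sep="\t")
    (outdir / "qc_report.json").write_text(qc_report.to_json())
    paths.update(
        expression=str(outdir / "expression.tsv"),
        qc_report=str(outdir / "qc_report.json"),
    )

    # --- differential expression ---------------------------------------
    try:
        if config.comparisons:
            comparisons = parse_comparisons(config.comparisons)
        else:
            comparisons = load_default_comparisons(design_name or "replication")
        de_frames = []
        for comp in comparisons:
            de_frames.append(
                diffexpr.run_comparison(exprs.log2_expr, meta, comp)
            )
        de_table = pd.concat(de_frames)
    except Exception as exc:
        raise StageError("diffexpr", exc) from exc
    de_table.to_csv(outdir / "de_table.tsv", sep="\t")
    paths["de_table"] = str(outdir / "de_table.tsv")
    pca_res = diffexpr.pca(exprs.log2_expr.dropna(axis=0))
    pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    pca_res.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    paths.update(
        pca_scores=str(outdir / "pca_scores.tsv"),
        pca_loadings=str(outdir / "pca_loadings.tsv"),
    )

    # --- biomarker evaluation ------------------------------------------
    try:
        bm = config.biomarker
        reports = biomarker.evaluate_panels(
            exprs.expr,
            meta,
            comparisons,
            de_table,
            cutoff=bm.get("cutoff", 0.5),
            feature_scale=bm.get("feature_scale", "linear"),
            variance_floor_eps=bm.get("variance_floor", 1e-9),
        )
        bm_frame = biomarker.reports_to_frame(reports)
    except Exception as exc:
        raise StageError("biomarker", exc) from exc
    bm_frame.to_csv(outdir / "biomarker_report.tsv", sep="\t", index=False)
    paths["biomarker_report"] = str(outdir / "biomarker_report.tsv")

    # --- function prediction (optional) ---------------------------------
    fp = config.function_prediction
    if fp.get("enabled", False):
        try:
            gmt = fp.get("gene_sets")
            if gmt is not None and not Path(gmt).exists():
                raise FileNotFoundError(f"gene set file not found: {gmt}")
            net_seed = stage_seed(seed, "network")
            spec = synthetic.NetworkFixtureSpec(
                **{**fp.get("network", {}), "seed": net_seed}
            )
            lnc_expr, gene_expr, targets, ppi = synthetic.generate_network_fixture(spec)
            network = funcpred.build_meta_network(
                lnc_expr, gene_expr, targets, ppi,
                sim_threshold=fp.get("sim_threshold", 0.5),
            )
            if gmt is not None:
                sets = funcpred.GeneSetCollection.read_gmt(gmt)
            else:
                planted = (
                    list(spec.planted_module[1]) if spec.planted_module else None
                )
                sets = synthetic.generate_gene_sets(
                    list(gene_expr.index),
                    n_sets=fp.get("n_sets", 30),
                    set_size_range=tuple(fp.get("set_size_range", (5, 20))),
                    planted_set=planted,
                    seed=stage_seed(seed, "gene_sets"),
                )
            seeds = fp.get("seed_lncs") or network.nodes_of_type("lncRNA")[:1]
            enrich = funcpred.predict_functions(
                network, seeds, sets,
                restart=fp.get("restart", 0.5),
                n_perm=fp.get("n_perm", 1000),
                seed=stage_seed(seed, "gsea"),
                min_size=fp.get("min_size", 5),
                max_size=fp.get("max_size", 500),
            )
        except Exception as exc:
            raise StageError("function_prediction", exc) from exc
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        paths["enrichment"] = str(outdir / "enrichment.tsv")

    logger.info("pipeline finished in %.1fs", time.time() - t0)
    summary = {
        "version": __version__,
        "seed": seed,
        "n_samples": int(meta.shape[0]),
        "n_features": int(exprs.expr.shape[0]),
        "n_excluded_by_qc": len(qc_report.excluded),
        "comparisons": [c.name for c in comparisons],
        "n_significant": {
            c.name: int(de_table.loc[de_table["comparison"] == c.name, "significant"].sum())
            for c in comparisons
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    paths["summary"] = str(outdir / "summary.json")

    artifacts = RunArtifacts(
        outdir=outdir,
        paths=paths,
        config={
            "cohort": config.cohort,
            "normalization": config.normalization,
            "biomarker": config.biomarker,
            "function_prediction": config.function_prediction,
        },
        seed=seed,
        complete=True,
    )
    (outdir / "config_echo.json").write_text(json.dumps(artifacts.config, indent=2))
    return artifacts


def render_summary(artifacts: RunArtifacts) -> str:
    """Markdown report: significant features per comparison, top weighted
    accuracy per comparison, enriched terms per lncRNA."""
    artifacts.require_complete()
    de = pd.read_csv(artifacts.paths["de_table"], sep="\t", index_col=0)
    bm = pd.read_csv(artifacts.paths["biomarker_report"], sep="\t")
    lines = ["# Pipeline summary", ""]
    lines.append("## Significant features per comparison")
    for comp, sub in de.groupby("comparison"):
        sig = sub[sub["significant"]]
        if sig.empty:
            lines.append(f"- **{comp}**: no significant feature")
        else:
            feats = ", ".join(
                f"{f} (log2FC={r.log2fc:.2f}, p_adj={r.p_adj:.4f})"
                for f, r in sig.iterrows()
            )
            lines.append(f"- **{comp}**: {feats}")
    lines.append("")
    lines.append("## Best weighted accuracy per comparison")
    lines.append("")
    lines.append("| comparison | best variant | WA |")
    lines.append("|---|---|---|")
    for comp, sub in bm.groupby("comparison"):
        best = sub.loc[sub["weighted_accuracy"].idxmax()]
        lines.append(
            f"| {comp} | {best['variant']} | {best['weighted_accuracy']:.2f} |"
        )
    if "enrichment" in artifacts.paths:
        enr = pd.read_csv(artifacts.paths["enrichment"], sep="\t")
        lines.append("")
        lines.append("## Enriched terms per lncRNA (FDR < 0.1)")
        for lnc, sub in enr.groupby("lncRNA"):
            sig = sub[sub["significant"] == True]  # noqa: E712
            if sig.empty:
                lines.append(f"- **{lnc}**: none")
            else:
                terms = ", ".join(
                    f"{r['set']} (NES={r['NES']:.2f}, FDR={r['FDR']:.3f})"
                    for _, r in sig.iterrows()
                )
                lines.append(f"- **{lnc}**: {terms}")
    return "\n".join(lines) + "\n"
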