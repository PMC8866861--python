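"""End-to-end orchestration of the analysis stages.

``run_all`` wires normalize -> differential (both arms) -> decompose ->
fold filter -> enrichment (salt-specific and osmotic study sets) ->
phenotype/metabolite statistics, writing every artifact plus a RunReport
JSON whose parameter echo and checksums suffice to reproduce the run.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .design import ExpressionSet
from .differential import Decomposition, DifferentialResult, call_arm, decompose, fc_filter
from .enrichment import EnrichmentRun, enrich
from .groupstats import anova_lsd, fold_summary
from .io import (
    RunConfig,
    ordered_matrix,
    sha256_of,
    write_decomposition,
    write_differential,
    write_enrichment,
    write_expression,
)
from .ontology import AnnotationMap, OntologyGraph, propagate
from .preprocess import fold_changes, quantile_normalize, signed_log_scale, zscore_genes


@dataclass
class PipelineResult:
    normalized: ExpressionSet
    differential: dict[str, DifferentialResult]
    decomposition: Decomposition
    enrichment: dict[str, EnrichmentRun]
    report: dict


def normalize(es: ExpressionSet) -> ExpressionSet:
    return signed_log_scale(zscore_genes(quantile_normalize(es)))


def run_all(
    es: ExpressionSet,
    ontology: OntologyGraph | None,
    annotations: dict[str, set[str]] | None,
    config: RunConfig,
    outdir,
    phenotype: pd.DataFrame | None = None,
    metabolites: pd.DataFrame | None = None,
) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arms = [a for a in es.design["arm"].unique() if a != "control"]
    if len(arms) != 2:
        raise ValueError(f"expected exactly 2 treatment arms, found {arms}")
    nacl_arm, sorb_arm = arms

    fc = fold_changes(es)
    normalized = normalize(es)
    write_expression(normalized, outdir / "normalized.tsv")

    differential = {}
    for arm in (nacl_arm, sorb_arm):
        res = call_arm(
            normalized,
            arm,
            fc=fc,
            alpha=config.alpha,
            use_adjusted=config.use_adjusted,
            exact_limit=config.exact_limit,
        )
        write_differential(res, outdir / f"differential_{arm}.tsv")
        differential[arm] = res

    dec = decompose(differential[nacl_arm], differential[sorb_arm])
    dec = fc_filter(
        dec, fc, nacl_arm=nacl_arm, sorbitol_arm=sorb_arm, threshold=config.fold_threshold
    )
    write_decomposition(dec, outdir / "decomposition")
    for name, genes in dec.sets().items():
        ordered_matrix(normalized, genes, outdir / f"heatmap_{name}.tsv")

    enrichment: dict[str, EnrichmentRun] = {}
    if ontology is not None and annotations is not None:
        amap = propagate(ontology, annotations, on_unknown="skip")
        studies = {
            "salt_specific": dec.go_input["salt_specific_up"]
            | dec.go_input["salt_specific_down"],
            "osmotic": dec.go_input["osmotic_up"] | dec.go_input["osmotic_down"],
        }
        for name, study in studies.items():
            run = enrich(ontology, amap, study, cutoff=config.elim_cutoff)
            enrichment[name] = run
            write_enrichment(run.reported(config.min_genes), outdir / f"enrichment_{name}.tsv")

    if phenotype is not None:
        pheno = phenotype.copy()
        pheno["survival_pct"] = 100.0 * pheno["survivors"] / pheno["sown"]
        groups = {
            cond: sub["survival_pct"].to_numpy()
            for cond, sub in pheno.groupby("condition", sort=False)
        }
        anova = anova_lsd(groups, alpha=config.lsd_alpha)
        anova.summary.to_csv(outdir / "phenotype_survival_anova.csv", index=False)
    if metabolites is not None:
        folds = fold_summary(metabolites)
        folds.to_csv(outdir / "metabolite_folds.csv", index=False)

    report = {
        "version": __version__,
        "parameters": config.to_dict(),
        "seed": config.seed,
        "gene_counts": {
            "input": es.n_genes,
            "significant_" + nacl_arm: len(differential[nacl_arm].significant),
            "significant_" + sorb_arm: len(differential[sorb_arm].significant),
            "salt_specific": len(dec.salt_specific),
            "osmotic": len(dec.osmotic),
            "sorbitol_only": len(dec.sorbitol_only),
            "go_input": {k: len(v) for k, v in dec.go_input.items()},
        },
        "checksums": {
            p.name: sha256_of(p) for p in sorted(outdir.rglob("*")) if p.is_file()
        },
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return PipelineResult(
        normalized=normalized,
        differential=differential,
        decomposition=dec,
        enrichment=enrichment,
        report=report,
    )
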