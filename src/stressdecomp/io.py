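"""File formats and run configuration.

Matrices travel as TSV (gene rows, sample columns, header row) with a
sidecar ``<name>.stage.json`` recording the processing stage, so a
misordered pipeline fails loudly on re-ingestion. Design, phenotype and
metabolite tables are CSV; annotations are a two-column TSV; ontologies
are OBO; reports and truth are JSON.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import ExpressionSet, StudyDesign
from .differential import Decomposition, DifferentialResult
from .errors import ConfigError, DataValidationError
from .synthetic import PlantedTerm, PlantedTruth, SyntheticBundle
from .ontology import write_obo

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotations",
    "write_annotations",
    "read_gaf",
    "write_bundle",
    "write_differential",
    "write_decomposition",
    "write_enrichment",
    "ordered_matrix",
    "RunConfig",
]


def _stage_sidecar(matrix_path: Path) -> Path:
    return matrix_path.with_suffix(matrix_path.suffix + ".stage.json")


def write_expression(es: ExpressionSet, matrix_path, design_path=None) -> None:
    matrix_path = Path(matrix_path)
    frame = es.frame()
    frame.index.name = "gene"
    frame.to_csv(matrix_path, sep="\t", float_format="%.17g")
    _stage_sidecar(matrix_path).write_text(json.dumps({"stage": es.stage}))
    if design_path is not None:
        es.design.to_csv(design_path, index=False)


def read_expression(matrix_path, design_path, missing: str = "reject") -> ExpressionSet:
    """Read a matrix TSV plus design CSV into a validated ExpressionSet.

    ``missing``: ``"reject"`` (default) errors on any NaN; ``"drop-gene"``
    removes rows containing NaNs.
    """
    if missing not in ("reject", "drop-gene"):
        raise ConfigError(f"unknown missing-value policy {missing!r}")
    matrix_path = Path(matrix_path)
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    design = pd.read_csv(design_path, dtype={"dose": str})
    required = {"sample", "arm", "dose", "replicate"}
    if not required.issubset(design.columns):
        raise DataValidationError(
            f"design is missing columns {sorted(required - set(design.columns))}"
        )
    missing_samples = [s for s in frame.columns if s not in set(design["sample"])]
    if missing_samples:
        raise DataValidationError(
            f"samples absent from design: {missing_samples}"
        )
    design = design.set_index("sample").loc[list(frame.columns)].reset_index()
    if frame.isna().any().any():
        if missing == "reject":
            raise DataValidationError("matrix contains missing values")
        frame = frame.dropna(axis=0)
    sidecar = _stage_sidecar(matrix_path)
    stage = "raw"
    if sidecar.exists():
        stage = json.loads(sidecar.read_text())["stage"]
    values = frame.to_numpy(dtype=float)
    if stage == "raw" and not (values > 0).all():
        raise DataValidationError("raw intensities must be strictly positive")
    return ExpressionSet(
        genes=[str(g) for g in frame.index],
        design=design,
        values=values,
        stage=stage,
    )


def write_annotations(direct: Mapping[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_annotations(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataValidationError(f"annotation line {lineno} is not 2-column")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def read_gaf(path) -> dict[str, set[str]]:
    """Minimal GAF 2.x reader: columns 2 (gene) and 5 (term); NOT rows dropped."""
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            if "NOT" in parts[3].split("|"):
                continue
            out.setdefault(parts[1], set()).add(parts[4])
    return out


def _truth_to_json(truth: PlantedTruth) -> dict:
    return {
        "classes": truth.classes.to_dict(),
        "effects": {g: row.to_dict() for g, row in truth.effects.iterrows()},
        "baseline": truth.baseline.to_dict(),
        "noise_sd": truth.noise_sd,
        "planted_terms": {
            t: {"genes": list(p.genes), "fraction": p.fraction}
            for t, p in truth.planted_terms.items()
        },
    }


def read_truth(path) -> PlantedTruth:
    data = json.loads(Path(path).read_text())
    classes = pd.Series(data["classes"], name="class")
    classes.index.name = "gene"
    effects = pd.DataFrame.from_dict(data["effects"], orient="index").loc[classes.index]
    return PlantedTruth(
        classes=classes,
        effects=effects,
        baseline=pd.Series(data["baseline"]).loc[classes.index],
        noise_sd=data["noise_sd"],
        planted_terms={
            t: PlantedTerm(term=t, genes=tuple(v["genes"]), fraction=v["fraction"])
            for t, v in data["planted_terms"].items()
        },
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every bundle component; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.csv",
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "phenotype": outdir / "phenotype.csv",
        "metabolites": outdir / "metabolites.csv",
        "truth": outdir / "truth.json",
    }
    write_expression(bundle.expression, paths["expression"], paths["design"])
    write_obo(bundle.ontology, paths["ontology"])
    write_annotations(bundle.annotations, paths["annotations"])
    bundle.phenotype.to_csv(paths["phenotype"], index=False)
    bundle.metabolites.to_csv(paths["metabolites"], index=False)
    paths["truth"].write_text(
        json.dumps(_truth_to_json(bundle.truth), indent=1, sort_keys=True)
    )
    return paths


def write_differential(res: DifferentialResult, path) -> None:
    res.table.to_csv(path, sep="\t", float_format="%.17g")


def write_decomposition(dec: Decomposition, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    sets = dict(dec.sets())
    sets["sorbitol_only"] = dec.sorbitol_only
    sets["discordant"] = dec.discordant
    for name, genes in sets.items():
        path = outdir / f"{name}.txt"
        path.write_text("".join(f"{g}\n" for g in sorted(genes)))
        paths[name] = path
    for name, genes in dec.go_input.items():
        path = outdir / f"{name}.go_input.txt"
        path.write_text("".join(f"{g}\n" for g in sorted(genes)))
        paths[f"{name}.go_input"] = path
    return paths


#: Display headers matching the published enrichment-table layout.
ENRICHMENT_COLUMNS = {
    "name": "Description",
    "K": "Number in background",
    "k": "Number in gene set",
    "expected": "Expected",
    "p_classic": "Fisher classic",
    "p_elim": "Fisher weighted",
}


def write_enrichment(table: pd.DataFrame, path) -> None:
    out = table.rename(columns=ENRICHMENT_COLUMNS)
    out.index.name = "GO term"
    out.to_csv(path, sep="\t", float_format="%.6g")


def ordered_matrix(es: ExpressionSet, genes, path=None) -> pd.DataFrame:
    """Gene-set x all-samples matrix export for external heatmapping.

    Rows are the requested genes (sorted), columns follow design order.
    """
    genes = sorted(set(genes) & set(es.genes))
    frame = es.frame().loc[genes]
    if path is not None:
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format="%.17g")
    return frame


@dataclasses.dataclass
class RunConfig:
    """Validated analysis parameters; unknown keys are rejected."""

    alpha: float = 0.01
    lsd_alpha: float = 0.05
    fold_threshold: float = 2.0
    elim_cutoff: float = 0.01
    min_genes: int = 10
    exact_limit: int = 20
    seed: int = 0
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        def _number(name, typ):
            value = getattr(self, name)
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"{name} must be a number, got {value!r}")
            value = typ(value)
            setattr(self, name, value)
            return value

        for name in ("alpha", "lsd_alpha", "elim_cutoff"):
            if not 0.0 < _number(name, float) < 1.0:
                raise ConfigError(f"{name}={getattr(self, name)} outside (0, 1)")
        if not _number("fold_threshold", float) > 1.0:
            raise ConfigError("fold_threshold must exceed 1")
        if _number("min_genes", int) < 0:
            raise ConfigError("min_genes must be non-negative")
        # C(25,12) ~ 5.2M labelings is the largest enumeration we allow
        if not 2 <= _number("exact_limit", int) <= 25:
            raise ConfigError("exact_limit must lie in [2, 25]")
        _number("seed", int)
        if not isinstance(self.use_adjusted, bool):
            raise ConfigError("use_adjusted must be boolean")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
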