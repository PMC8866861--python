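"""Synthetic data generators with planted ground truth.

Everything downstream of ingestion can be exercised without external data:
expression matrices following the two-arm dose-series layout, a random
single-rooted ontology DAG with planted enriched terms, per-plate survival
and mass phenotypes, and metabolite concentration tables.

Determinism: every generator derives its stream as
``np.random.default_rng([seed, STREAM_ID])`` with a fixed per-generator
stream id, so the same seed reproduces every component bit-identically
while the components stay independent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CONTROL_ARM, DEFAULT_DESIGN, ExpressionSet, StudyDesign, condition_label
from .errors import DataValidationError, InvalidDesignError
from .ontology import AnnotationMap, OntologyGraph, propagate

__all__ = [
    "GENE_CLASSES",
    "TruthSpec",
    "PlantedTruth",
    "PlantedTerm",
    "SyntheticBundle",
    "generate_expression",
    "generate_ontology",
    "generate_phenotype",
    "generate_metabolites",
    "generate_bundle",
    "term_id",
]

GENE_CLASSES = (
    "salt_up",
    "salt_down",
    "osmotic_up",
    "osmotic_down",
    "sorbitol_only_up",
    "sorbitol_only_down",
)

_STREAM_EXPRESSION = 1
_STREAM_ONTOLOGY = 2
_STREAM_PHENOTYPE = 3
_STREAM_METABOLITES = 4

PROFILES = ("flat", "linear", "saturating")


@dataclass(frozen=True)
class TruthSpec:
    """Planted-effect specification for :func:`generate_expression`.

    ``proportions`` maps gene classes to fractions of the gene set
    (remainder is the null class); assignment is deterministic: after one
    seeded shuffle the first ceil(p*N) genes go to each class in
    :data:`GENE_CLASSES` order, so class counts are exact.
    """

    proportions: Mapping[str, float] = field(default_factory=dict)
    effect: float = 2.0  # log2 units at the top dose
    profile: str = "saturating"
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        for cls in self.proportions:
            if cls not in GENE_CLASSES:
                raise DataValidationError(f"unknown gene class {cls!r}")
        if any(p < 0 for p in self.proportions.values()):
            raise DataValidationError("negative class proportion")
        if sum(self.proportions.values()) > 1 + 1e-12:
            raise DataValidationError("class proportions must sum to <= 1")
        if self.profile not in PROFILES:
            raise DataValidationError(f"unknown effect profile {self.profile!r}")
        if not self.noise_sd > 0:
            raise DataValidationError("noise sd must be positive")


@dataclass
class PlantedTerm:
    """One ontology term planted to over-annotate a target gene set."""

    term: str
    genes: tuple[str, ...]
    fraction: float


@dataclass
class PlantedTruth:
    """Everything the generator decided: the oracle for recovery tests."""

    classes: pd.Series  # gene -> class ('null' for unaffected genes)
    effects: pd.DataFrame  # gene x non-control condition, log2 effect
    baseline: pd.Series  # gene -> baseline log2 intensity
    noise_sd: float
    planted_terms: dict[str, PlantedTerm] = field(default_factory=dict)

    def genes_of(self, *classes: str) -> set[str]:
        return set(self.classes.index[self.classes.isin(classes)])

    @property
    def salt_specific(self) -> set[str]:
        return self.genes_of("salt_up", "salt_down")

    @property
    def osmotic(self) -> set[str]:
        return self.genes_of("osmotic_up", "osmotic_down")


def _profile_weights(profile: str, n_doses: int) -> np.ndarray:
    i = np.arange(1, n_doses + 1, dtype=float)
    if profile == "flat":
        return np.ones(n_doses)
    if profile == "linear":
        return i / n_doses
    # saturating: geometric approach to the plateau, top dose at full effect
    w = 1.0 - 0.5**i
    return w / w[-1]


def _class_effect_row(
    cls: str, design: StudyDesign, effect: float, profile: str
) -> dict[str, float]:
    """Planted log2 effect per non-control condition for one gene class."""
    row: dict[str, float] = {}
    sign = 1.0 if cls.endswith("_up") else -1.0
    if cls.startswith("salt"):
        arms = {design.arm_names[0]}
    elif cls.startswith("osmotic"):
        arms = set(design.arm_names)
    elif cls.startswith("sorbitol_only"):
        arms = {design.arm_names[1]}
    else:
        arms = set()
    for arm, doses in design.arms:
        weights = _profile_weights(profile, len(doses))
        for dose, w in zip(doses, weights):
            label = condition_label(arm, dose)
            row[label] = sign * effect * w if arm in arms else 0.0
    return row


def generate_expression(
    n_genes: int,
    spec: TruthSpec,
    design: StudyDesign = DEFAULT_DESIGN,
    seed: int = 0,
) -> tuple[ExpressionSet, PlantedTruth]:
    """Strictly positive intensity matrix with planted differential structure.

    Each entry is ``2 ** (baseline + effect + Normal(0, noise_sd))``; the
    effect is zero for control samples and for the null class.
    """
    if n_genes < 1:
        raise InvalidDesignError("gene count must be positive")
    if design.replicates < 2:
        raise InvalidDesignError("need >= 2 replicates per condition")
    rng = np.random.default_rng([seed, _STREAM_EXPRESSION])
    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]

    shuffled = list(genes)
    rng.shuffle(shuffled)
    classes = pd.Series("null", index=pd.Index(genes, name="gene"), dtype=object)
    cursor = 0
    for cls in GENE_CLASSES:
        p = spec.proportions.get(cls, 0.0)
        count = math.ceil(p * n_genes)
        if cursor + count > n_genes:
            raise DataValidationError("class proportions allocate more genes than exist")
        classes[shuffled[cursor : cursor + count]] = cls
        cursor += count

    cond_labels = [
        condition_label(a, d) for a, d in design.conditions() if a != CONTROL_ARM
    ]
    class_rows = {
        cls: _class_effect_row(cls, design, spec.effect, spec.profile)
        for cls in (*GENE_CLASSES, "null")
    }
    effects = pd.DataFrame(
        [class_rows[classes[g]] for g in genes], index=classes.index, columns=cond_labels
    )

    baseline = pd.Series(
        rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes),
        index=classes.index,
        name="baseline",
    )

    frame = design.to_frame()
    effect_by_sample = np.zeros((n_genes, len(frame)))
    for j, (arm, dose) in enumerate(zip(frame["arm"], frame["dose"])):
        if arm != CONTROL_ARM:
            effect_by_sample[:, j] = effects[condition_label(arm, dose)].to_numpy()
    log2_values = (
        baseline.to_numpy()[:, None]
        + effect_by_sample
        + rng.normal(0.0, spec.noise_sd, size=effect_by_sample.shape)
    )
    es = ExpressionSet(genes=genes, design=frame, values=2.0**log2_values, stage="raw")
    truth = PlantedTruth(
        classes=classes, effects=effects, baseline=baseline, noise_sd=spec.noise_sd
    )
    return es, truth


def term_id(i: int) -> str:
    """Synthetic ontology term identifier; index 0 is the root."""
    return f"GO:9{i:06d}"


def generate_ontology(
    n_terms: int,
    max_depth: int,
    genes: Sequence[str],
    planted: Sequence[PlantedTerm] = (),
    seed: int = 0,
    namespace: str = "biological_process",
    mean_annotations: float = 2.0,
) -> tuple[OntologyGraph, dict[str, set[str]]]:
    """Random single-rooted DAG plus *direct* (pre-propagation) annotations.

    Term ids are :func:`term_id`(0..n_terms-1) with index 0 the root.
    Every non-root term has one primary parent (chosen among earlier terms
    of depth < max_depth, so acyclicity holds by construction) and
    sometimes a second, shallower parent via ``part_of``. Background
    annotations scatter each gene over ~``mean_annotations`` random terms;
    each planted term additionally annotates ``round(fraction * |target|)``
    of its target genes directly.
    """
    if n_terms < 2:
        raise InvalidDesignError("need at least 2 terms (root alone is not usable)")
    if max_depth < 1:
        raise InvalidDesignError("max depth must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_ONTOLOGY])
    import networkx as nx

    g = nx.DiGraph()
    depths = {term_id(0): 0}
    g.add_node(term_id(0), name="root process", namespace=namespace)
    for i in range(1, n_terms):
        tid = term_id(i)
        g.add_node(tid, name=f"synthetic process {i}", namespace=namespace)
        eligible = [t for t, d in depths.items() if d < max_depth]
        parent = eligible[rng.integers(len(eligible))]
        g.add_edge(tid, parent, relation="is_a")
        depths[tid] = depths[parent] + 1
        if depths[tid] > 1 and rng.random() < 0.3:
            shallower = [t for t, d in depths.items() if d < depths[tid] and t != parent]
            if shallower:
                extra = shallower[rng.integers(len(shallower))]
                relation = "part_of" if rng.random() < 0.5 else "is_a"
                g.add_edge(tid, extra, relation=relation)
    assert nx.is_directed_acyclic_graph(g), "ontology generator produced a cycle"
    graph = OntologyGraph(graph=g, namespace=namespace)

    known = set(graph.terms)
    for plant in planted:
        if plant.term not in known:
            raise DataValidationError(f"planted term {plant.term!r} does not exist")
        if not (0 <= plant.fraction <= 1):
            raise DataValidationError("planted fraction must lie in [0, 1]")

    non_root = [term_id(i) for i in range(1, n_terms)]
    direct: dict[str, set[str]] = {}
    for gene in genes:
        count = 1 + rng.poisson(max(mean_annotations - 1.0, 0.0))
        count = min(count, len(non_root))
        picks = rng.choice(len(non_root), size=count, replace=False)
        direct[gene] = {non_root[i] for i in np.sort(picks)}
    for plant in planted:
        target = list(plant.genes)
        take = round(plant.fraction * len(target))
        picks = rng.choice(len(target), size=take, replace=False)
        for i in np.sort(picks):
            direct.setdefault(target[i], set()).add(plant.term)
    return graph, direct


def generate_phenotype(
    design: StudyDesign = DEFAULT_DESIGN,
    survival: Mapping[str, float] | float = 0.9,
    plant_mass_mg: Mapping[str, float] | float = 10.0,
    plates: int = 4,
    seeds_per_plate: int = 50,
    mass_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plate survival counts and total seedling mass.

    ``survival`` and ``plant_mass_mg`` are either scalars or mappings from
    condition label to the per-seed survival probability / mean per-plant
    mass. Survivors are Binomial(seeds_per_plate, p); plate mass is
    survivors times a mean-preserving lognormal per-plant mass.
    """
    if plates < 1 or seeds_per_plate < 1:
        raise InvalidDesignError("plates and seeds per plate must be positive")
    rng = np.random.default_rng([seed, _STREAM_PHENOTYPE])
    labels = design.condition_labels()

    def lookup(param, label, name):
        value = param.get(label) if isinstance(param, Mapping) else param
        if value is None:
            raise DataValidationError(f"{name} missing for condition {label!r}")
        return float(value)

    rows = []
    sigma = math.sqrt(math.log(1.0 + mass_cv**2))
    for label in labels:
        p = lookup(survival, label, "survival probability")
        if not (0.0 <= p <= 1.0):
            raise DataValidationError(f"survival probability {p} outside [0, 1]")
        mass_mean = lookup(plant_mass_mg, label, "plant mass")
        if mass_mean <= 0:
            raise DataValidationError("mean plant mass must be positive")
        for plate in range(1, plates + 1):
            survivors = int(rng.binomial(seeds_per_plate, p))
            if survivors == 0:
                mass = 0.0
            else:
                per_plant = mass_mean * np.exp(
                    rng.normal(-(sigma**2) / 2.0, sigma, size=survivors)
                )
                mass = float(per_plant.sum())
            rows.append(
                {
                    "condition": label,
                    "plate": plate,
                    "sown": seeds_per_plate,
                    "survivors": survivors,
                    "mass_mg": mass,
                }
            )
    return pd.DataFrame(rows)


def generate_metabolites(
    analytes: Mapping[str, tuple[float, Mapping[str, float]]],
    design: StudyDesign = DEFAULT_DESIGN,
    replicates: int = 5,
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Lognormal concentration table (units nmol/g DW).

    ``analytes`` maps analyte name to ``(control_mean, folds)`` where
    ``folds`` maps condition labels to fold changes vs control (missing
    labels default to 1). Noise is mean-preserving lognormal with
    coefficient of variation ``cv``.
    """
    if replicates < 2:
        raise InvalidDesignError("need >= 2 replicates")
    rng = np.random.default_rng([seed, _STREAM_METABOLITES])
    labels = design.condition_labels()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    rows = []
    for analyte in sorted(analytes):
        control_mean, folds = analytes[analyte]
        if control_mean <= 0:
            raise DataValidationError(f"non-positive control mean for {analyte!r}")
        for label in labels:
            fold = float(folds.get(label, 1.0)) if label != CONTROL_ARM else 1.0
            mean = control_mean * fold
            if mean <= 0:
                raise DataValidationError(
                    f"non-positive mean for {analyte!r} at {label!r}"
                )
            noise = np.exp(rng.normal(-(sigma**2) / 2.0, sigma, size=replicates))
            for rep, value in enumerate(mean * noise, start=1):
                rows.append(
                    {
                        "analyte": analyte,
                        "condition": label,
                        "replicate": rep,
                        "concentration": float(value),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class SyntheticBundle:
    """A complete self-consistent synthetic study."""

    design: StudyDesign
    expression: ExpressionSet
    truth: PlantedTruth
    ontology: OntologyGraph
    annotations: dict[str, set[str]]  # direct, pre-propagation
    phenotype: pd.DataFrame
    metabolites: pd.DataFrame
    seed: int

    def annotation_map(self) -> AnnotationMap:
        return propagate(self.ontology, self.annotations)


_GROUP_ALIASES = {
    "salt": ("salt_up", "salt_down"),
    "osmotic": ("osmotic_up", "osmotic_down"),
    "sorbitol_only": ("sorbitol_only_up", "sorbitol_only_down"),
}


def generate_bundle(
    n_genes: int = 500,
    spec: TruthSpec | None = None,
    design: StudyDesign = DEFAULT_DESIGN,
    n_terms: int = 60,
    max_depth: int = 5,
    planted_terms: Sequence[tuple[str, float]] = (("salt", 0.8), ("osmotic", 0.8)),
    seed: int = 0,
) -> SyntheticBundle:
    """Generate every component off one seed.

    ``planted_terms`` lists (gene class or alias group, annotation
    fraction) pairs; entry *i* is planted on the *i*-th last generated
    term id (those sit deepest in the DAG on average).
    """
    spec = spec or TruthSpec(
        proportions={"salt_up": 0.05, "salt_down": 0.05, "osmotic_up": 0.05, "osmotic_down": 0.05}
    )
    expression, truth = generate_expression(n_genes, spec, design=design, seed=seed)
    plants = []
    for i, (target, fraction) in enumerate(planted_terms):
        classes = _GROUP_ALIASES.get(target, (target,))
        target_genes = tuple(sorted(truth.genes_of(*classes)))
        tid = term_id(n_terms - 1 - i)
        plants.append(PlantedTerm(term=tid, genes=target_genes, fraction=fraction))
    ontology, annotations = generate_ontology(
        n_terms, max_depth, expression.genes, planted=plants, seed=seed
    )
    truth.planted_terms = {p.term: p for p in plants}
    nacl, sorb = design.arm_names[0], design.arm_names[1]
    survival = {label: 0.95 for label in design.condition_labels()}
    for i, dose in enumerate(design.doses(nacl)):
        survival[condition_label(nacl, dose)] = max(0.0, 0.95 - 0.15 * i)
    metabolite_folds = {
        condition_label(nacl, dose): fold
        for dose, fold in zip(design.doses(nacl), (3.0, 6.6, 5.0, 4.5))
    }
    metabolite_folds.update(
        {
            condition_label(sorb, dose): fold
            for dose, fold in zip(design.doses(sorb), (1.5, 2.0, 3.4, 2.5))
        }
    )
    phenotype = generate_phenotype(design=design, survival=survival, seed=seed)
    metabolites = generate_metabolites(
        {"IAA": (1.0, metabolite_folds)}, design=design, seed=seed
    )
    return SyntheticBundle(
        design=design,
        expression=expression,
        truth=truth,
        ontology=ontology,
        annotations=annotations,
        phenotype=phenotype,
        metabolites=metabolites,
        seed=seed,
    )
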