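"""Core data structures shared by every pipeline stage.

A :class:`StudyDesign` describes the two-arm dose series layout
(control + NaCl doses + iso-osmolar sorbitol doses, each with replicates);
an :class:`ExpressionSet` couples a gene-by-sample intensity matrix to the
per-sample design labels and a processing-stage tag.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, InvalidDesignError, StageError

CONTROL_ARM = "control"
CONTROL_DOSE = "0"

#: Processing stages in mandatory pipeline order.
STAGES = ("raw", "quantile", "zscored", "logscaled")


def condition_label(arm: str, dose: str) -> str:
    """Canonical condition label, e.g. ``NaCl-75``; control is just ``control``."""
    if arm == CONTROL_ARM:
        return CONTROL_ARM
    return f"{arm}-{dose}"


@dataclass(frozen=True)
class StudyDesign:
    """Two-arm dose-series layout with a shared untreated control.

    Defaults reproduce the 27-sample layout: 1 control condition x 3
    replicates, 4 NaCl doses x 3 replicates and 4 iso-osmolar sorbitol
    doses x 3 replicates.
    """

    arms: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("NaCl", ("50", "75", "100", "125")),
        ("sorbitol", ("100", "150", "200", "250")),
    )
    replicates: int = 3
    control_replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.control_replicates < 1:
            raise InvalidDesignError("replicate counts must be positive")
        names = [arm for arm, _ in self.arms]
        if len(set(names)) != len(names):
            raise InvalidDesignError("duplicate arm names")
        if CONTROL_ARM in names:
            raise InvalidDesignError(f"arm name {CONTROL_ARM!r} is reserved")
        for arm, doses in self.arms:
            if len(doses) == 0:
                raise InvalidDesignError(f"arm {arm!r} has no dose levels")
            if len(set(doses)) != len(doses):
                raise InvalidDesignError(f"duplicate dose labels in arm {arm!r}")

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(arm for arm, _ in self.arms)

    def doses(self, arm: str) -> tuple[str, ...]:
        for name, doses in self.arms:
            if name == arm:
                return doses
        raise InvalidDesignError(f"unknown arm {arm!r}")

    def conditions(self) -> list[tuple[str, str]]:
        """All (arm, dose) pairs, control first."""
        out = [(CONTROL_ARM, CONTROL_DOSE)]
        for arm, doses in self.arms:
            out.extend((arm, d) for d in doses)
        return out

    def condition_labels(self) -> list[str]:
        return [condition_label(a, d) for a, d in self.conditions()]

    def to_frame(self) -> pd.DataFrame:
        """Sample table with columns sample/arm/dose/replicate.

        Sample names are ``{arm}-{dose}-r{i}`` (``control-r{i}`` for the
        control) and are guaranteed unique by construction.
        """
        rows = []
        for i in range(1, self.control_replicates + 1):
            rows.append((f"control-r{i}", CONTROL_ARM, CONTROL_DOSE, i))
        for arm, doses in self.arms:
            for dose in doses:
                for i in range(1, self.replicates + 1):
                    rows.append((f"{arm}-{dose}-r{i}", arm, dose, i))
        frame = pd.DataFrame(rows, columns=["sample", "arm", "dose", "replicate"])
        if frame["sample"].duplicated().any():
            raise InvalidDesignError("sample labels are not unique")
        return frame

    @property
    def n_samples(self) -> int:
        return self.control_replicates + sum(
            len(doses) * self.replicates for _, doses in self.arms
        )


DEFAULT_DESIGN = StudyDesign()


@dataclass
class ExpressionSet:
    """Gene x sample intensity matrix with design labels and a stage tag."""

    genes: list[str]
    design: pd.DataFrame  # columns: sample, arm, dose, replicate
    values: np.ndarray  # shape (n_genes, n_samples)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise DataValidationError(f"unknown stage {self.stage!r}")
        required = {"sample", "arm", "dose", "replicate"}
        if not required.issubset(self.design.columns):
            raise DataValidationError(
                f"design is missing columns {sorted(required - set(self.design.columns))}"
            )
        if self.values.shape != (len(self.genes), len(self.design)):
            raise DataValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.design)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataValidationError("duplicate gene identifiers")
        if self.design["sample"].duplicated().any():
            raise DataValidationError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise DataValidationError("missing values are not allowed")
        if self.stage == "raw" and not (self.values > 0).all():
            raise DataValidationError("raw intensities must be strictly positive")

    @property
    def samples(self) -> list[str]:
        return self.design["sample"].tolist()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.design)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r}, got {self.stage!r}"
            )

    def sample_indices(self, arm: str, dose: str | None = None) -> np.ndarray:
        """Column indices for one arm (optionally one dose) in design order."""
        mask = self.design["arm"] == arm
        if dose is not None:
            mask &= self.design["dose"] == dose
        idx = np.flatnonzero(mask.to_numpy())
        return idx

    def condition_indices(self) -> dict[str, np.ndarray]:
        """Column indices per condition label, control included."""
        out: dict[str, np.ndarray] = {}
        labels = [
            condition_label(a, d)
            for a, d in zip(self.design["arm"], self.design["dose"])
        ]
        series = pd.Series(labels)
        for label in series.unique():
            out[label] = np.flatnonzero((series == label).to_numpy())
        return out

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionSet":
        return ExpressionSet(
            genes=list(self.genes),
            design=self.design.copy(),
            values=np.asarray(values, dtype=float),
            stage=stage,
        )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)
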