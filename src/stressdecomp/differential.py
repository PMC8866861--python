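"""Grouped Mann-Whitney differential calls and the salt/osmotic decomposition.

For each treatment arm the control replicates are tested against *all*
pooled arm samples (3 vs 12 in the default design). With a total group
size of at most ``exact_limit`` the two-sided p-value comes from exact
enumeration of the tie-aware rank-sum permutation null; larger groups fall
back to the tie-corrected normal approximation with continuity correction.

Significance is Benjamini-Hochberg adjusted p < 0.01 by default (the raw-p
threshold is available behind ``use_adjusted=False``). List algebra then
yields the salt-specific (A \\ B) and osmotic (A intersect B) gene sets,
split up/down by the NaCl-arm direction.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ExpressionSet
from .errors import DataValidationError
from .preprocess import FoldChangeTable

__all__ = [
    "mann_whitney",
    "exact_mw_matrix",
    "bh_adjust",
    "call_arm",
    "decompose",
    "fc_filter",
    "DifferentialResult",
    "Decomposition",
]

#: Largest total group size for which "auto" mode enumerates exactly.
DEFAULT_EXACT_LIMIT = 20


@lru_cache(maxsize=32)
def _combo_indices(n: int, k: int) -> np.ndarray:
    """All C(n, k) index subsets, shape (C, k)."""
    return np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)


def _u_from_ranksum(w: float, n_a: int) -> float:
    return w - n_a * (n_a + 1) / 2.0


def mann_whitney(
    a, b, mode: str = "auto", exact_limit: int = DEFAULT_EXACT_LIMIT
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``a`` vs ``b``.

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first
    group computed with tie mid-ranks. ``mode`` is ``exact`` (full
    enumeration of the C(|a|+|b|, |a|) labelings, p = min(1, 2 * min
    tail)), ``approx`` (tie-corrected normal approximation with continuity
    correction), or ``auto`` (exact when the pooled size is at most
    ``exact_limit``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataValidationError("both groups must be non-empty")
    if mode not in ("exact", "approx", "auto"):
        raise DataValidationError(f"unknown mode {mode!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    u_a = _u_from_ranksum(w_obs, n_a)
    if mode == "auto":
        mode = "exact" if n <= exact_limit else "approx"
    if mode == "exact":
        combos = _combo_indices(n, n_a)
        dist = ranks[combos].sum(axis=1)
        p_low = np.count_nonzero(dist <= w_obs) / dist.size
        p_high = np.count_nonzero(dist >= w_obs) / dist.size
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return float(u_a), float(p)


def exact_mw_matrix(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, chunk: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized exact Mann-Whitney over the rows of a matrix.

    ``values`` is gene x sample; columns ``idx_a`` are tested against
    columns ``idx_b`` per row. Identical to calling :func:`mann_whitney`
    in exact mode row by row, but enumerates the shared labeling index
    set once. Returns per-row ``(U_a, p)`` arrays.
    """
    idx_a = np.asarray(idx_a, dtype=np.intp)
    idx_b = np.asarray(idx_b, dtype=np.intp)
    n_a, n_b = idx_a.size, idx_b.size
    if n_a == 0 or n_b == 0:
        raise DataValidationError("both groups must be non-empty")
    n = n_a + n_b
    combos = _combo_indices(n, n_a)
    m = combos.shape[0]
    sub = values[:, np.concatenate([idx_a, idx_b])]
    u_out = np.empty(sub.shape[0])
    p_out = np.empty(sub.shape[0])
    for start in range(0, sub.shape[0], chunk):
        block = sub[start : start + chunk]
        ranks = sps.rankdata(block, axis=1)
        w_obs = ranks[:, :n_a].sum(axis=1)
        dist = ranks[:, combos].sum(axis=2)  # (rows, C)
        p_low = (dist <= w_obs[:, None]).sum(axis=1) / m
        p_high = (dist >= w_obs[:, None]).sum(axis=1) / m
        p = np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))
        u_out[start : start + chunk] = w_obs - n_a * (n_a + 1) / 2.0
        p_out[start : start + chunk] = p
    return u_out, p_out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DataValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class DifferentialResult:
    """Per-gene differential call for one treatment arm vs the control."""

    arm: str
    table: pd.DataFrame  # index gene; U, p, padj, significant, direction, max_abs_log2fc
    alpha: float
    use_adjusted: bool

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def significant(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def directed(self, direction: str) -> set[str]:
        mask = self.table["significant"] & (self.table["direction"] == direction)
        return set(self.table.index[mask])


def call_arm(
    es: ExpressionSet,
    arm: str,
    fc: FoldChangeTable | None = None,
    alpha: float = 0.01,
    use_adjusted: bool = True,
    mode: str = "auto",
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> DifferentialResult:
    """Test control replicates against all pooled samples of one arm.

    Runs on the fully normalized (logscaled) matrix; direction is the sign
    of the treated-minus-control median difference (mean difference breaks
    exact median ties), reported only for significant genes.
    """
    es.require_stage("logscaled")
    idx_c = es.sample_indices("control")
    idx_t = es.sample_indices(arm)
    if idx_c.size == 0:
        raise DataValidationError("control group absent from design")
    if idx_t.size < 2:
        raise DataValidationError(f"arm {arm!r} has fewer than 2 samples")
    n = idx_c.size + idx_t.size
    exact = mode == "exact" or (mode == "auto" and n <= exact_limit)
    if exact:
        u, p = exact_mw_matrix(es.values, idx_c, idx_t)
    else:
        res = sps.mannwhitneyu(
            es.values[:, idx_c],
            es.values[:, idx_t],
            axis=1,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
        )
        u, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    padj = bh_adjust(p)
    significant = (padj if use_adjusted else p) < alpha
    diff = np.median(es.values[:, idx_t], axis=1) - np.median(
        es.values[:, idx_c], axis=1
    )
    tie = diff == 0
    if tie.any():
        diff = np.where(
            tie,
            es.values[:, idx_t].mean(axis=1) - es.values[:, idx_c].mean(axis=1),
            diff,
        )
    direction = np.where(
        significant, np.where(diff > 0, "up", np.where(diff < 0, "down", "none")), "none"
    )
    table = pd.DataFrame(
        {
            "U": u,
            "p": p,
            "padj": padj,
            "significant": significant,
            "direction": direction,
        },
        index=pd.Index(es.genes, name="gene"),
    )
    if fc is not None:
        table["max_abs_log2fc"] = fc.arm_max_abs(arm).reindex(table.index)
    return DifferentialResult(
        arm=arm, table=table, alpha=alpha, use_adjusted=use_adjusted
    )


@dataclass
class Decomposition:
    """The four headline gene sets plus bookkeeping.

    ``salt_specific_*`` is A \\ B, ``osmotic_*`` is A intersect B (A =
    NaCl list, B = sorbitol list); up/down follow the NaCl-arm direction.
    ``go_input`` holds the post-fold-filter subsets once
    :func:`fc_filter` has run.
    """

    salt_specific_up: set[str]
    salt_specific_down: set[str]
    osmotic_up: set[str]
    osmotic_down: set[str]
    sorbitol_only: set[str]
    discordant: set[str]
    universe: list[str]
    go_input: dict[str, set[str]] = field(default_factory=dict)

    @property
    def salt_specific(self) -> set[str]:
        return self.salt_specific_up | self.salt_specific_down

    @property
    def osmotic(self) -> set[str]:
        return self.osmotic_up | self.osmotic_down

    def sets(self) -> dict[str, set[str]]:
        return {
            "salt_specific_up": self.salt_specific_up,
            "salt_specific_down": self.salt_specific_down,
            "osmotic_up": self.osmotic_up,
            "osmotic_down": self.osmotic_down,
        }


def decompose(res_nacl: DifferentialResult, res_sorb: DifferentialResult) -> Decomposition:
    """Set algebra on the two significant-gene lists.

    Osmotic genes whose two arms disagree in direction are placed by the
    NaCl direction and recorded in ``discordant``.
    """
    if res_nacl.genes != res_sorb.genes:
        raise DataValidationError("differential results cover different gene universes")
    a = res_nacl.significant
    b = res_sorb.significant
    nacl_dir = res_nacl.table["direction"]
    sorb_dir = res_sorb.table["direction"]
    salt = a - b
    osmotic = a & b
    discordant = {
        g for g in osmotic if nacl_dir[g] != sorb_dir[g]
    }
    return Decomposition(
        salt_specific_up={g for g in salt if nacl_dir[g] == "up"},
        salt_specific_down={g for g in salt if nacl_dir[g] == "down"},
        osmotic_up={g for g in osmotic if nacl_dir[g] == "up"},
        osmotic_down={g for g in osmotic if nacl_dir[g] == "down"},
        sorbitol_only=b - a,
        discordant=discordant,
        universe=res_nacl.genes,
    )


def fc_filter(
    dec: Decomposition,
    fc: FoldChangeTable,
    nacl_arm: str = "NaCl",
    sorbitol_arm: str = "sorbitol",
    threshold: float = 2.0,
) -> Decomposition:
    """Fill the GO-input subsets with the two-fold rule.

    A gene survives iff its |log2FC| reaches log2(threshold) in at least
    one dose of its relevant arm(s): the NaCl arm for salt-specific genes,
    either arm for osmotic genes.
    """
    if not threshold > 1:
        raise DataValidationError("fold threshold must exceed 1")
    cut = np.log2(threshold)
    max_nacl = fc.arm_max_abs(nacl_arm)
    max_sorb = fc.arm_max_abs(sorbitol_arm)
    pass_nacl = set(max_nacl.index[max_nacl >= cut])
    pass_either = pass_nacl | set(max_sorb.index[max_sorb >= cut])
    go_input = {
        "salt_specific_up": dec.salt_specific_up & pass_nacl,
        "salt_specific_down": dec.salt_specific_down & pass_nacl,
        "osmotic_up": dec.osmotic_up & pass_either,
        "osmotic_down": dec.osmotic_down & pass_either,
    }
    return replace(dec, go_input=go_input)
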