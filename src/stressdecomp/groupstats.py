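"""Group-comparison statistics for phenotype, metabolite and ion data.

One-way ANOVA with (unprotected) Fisher LSD pairwise comparisons and a
compact letter display, independent pooled-variance t-tests with
Bonferroni correction, per-sample Na:K ratios, and fold-change summaries
of condition means against the untreated control.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataValidationError

__all__ = [
    "anova_lsd",
    "ttest_bonferroni",
    "na_k_ratio",
    "fold_summary",
    "compact_letters",
    "AnovaResult",
]


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_error: int
    mse: float
    pairwise: pd.DataFrame  # square matrix of LSD p-values
    letters: dict[str, str]
    summary: pd.DataFrame  # group, n, mean, se, letters


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise DataValidationError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise DataValidationError(f"group {name!r} has fewer than 2 replicates")
        out[str(name)] = arr
    return out


def compact_letters(
    names: Sequence[str],
    significant: Mapping[tuple[str, str], bool],
    means: Mapping[str, float],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are pairwise non-significant. Letters are
    assigned scanning groups in descending-mean order (ties broken by the
    input order of ``names``), so the output is a deterministic function
    of the significance matrix.
    """
    position = {name: i for i, name in enumerate(names)}
    ordered = sorted(names, key=lambda g: (-means[g], position[g]))
    columns: list[set[str]] = [set(ordered)]
    for i, gi in enumerate(ordered):
        for gj in ordered[i + 1 :]:
            key = (gi, gj) if (gi, gj) in significant else (gj, gi)
            if not significant.get(key, False):
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                a, b = col - {gj}, col - {gi}
                for piece in (a, b):
                    if not any(piece <= other for other in columns):
                        columns.append(piece)
    # absorb any residual subsets, then order columns by their best member
    columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(ordered.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for idx, col in enumerate(columns):
        mark = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for g in col:
            letters[g] += mark
    return {g: "".join(sorted(letters[g])) for g in names}


def anova_lsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Fisher LSD pairwise t-tests and a letter display.

    The LSD comparisons use the pooled within-group mean square with the
    ANOVA error degrees of freedom and are run regardless of the omnibus F
    (unprotected LSD); with exactly two groups the LSD p-value equals the
    ordinary pooled two-sample t-test.
    """
    data = _validate_groups(groups)
    names = list(data)
    sizes = {g: a.size for g, a in data.items()}
    means = {g: float(a.mean()) for g, a in data.items()}
    n_total = sum(sizes.values())
    grand = sum(a.sum() for a in data.values()) / n_total
    ss_between = sum(sizes[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(((a - means[g]) ** 2).sum() for g, a in data.items())
    df_between = len(names) - 1
    df_error = n_total - len(names)
    mse = ss_within / df_error
    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif mse == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / mse
        p = float(sps.f.sf(f_stat, df_between, df_error))
    pw = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    significant: dict[tuple[str, str], bool] = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            delta = means[gi] - means[gj]
            if mse == 0:
                p_ij = 1.0 if delta == 0 else 0.0
            else:
                se = np.sqrt(mse * (1 / sizes[gi] + 1 / sizes[gj]))
                t = delta / se
                p_ij = float(2 * sps.t.sf(abs(t), df_error))
            pw.loc[gi, gj] = pw.loc[gj, gi] = p_ij
            significant[(gi, gj)] = p_ij <= alpha
    letters = compact_letters(names, significant, means)
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [sizes[g] for g in names],
            "mean": [means[g] for g in names],
            "se": [float(data[g].std(ddof=1) / np.sqrt(sizes[g])) for g in names],
            "letters": [letters[g] for g in names],
        }
    )
    return AnovaResult(
        F=float(f_stat),
        p=float(p),
        df_between=df_between,
        df_error=df_error,
        mse=float(mse),
        pairwise=pw,
        letters=letters,
        summary=summary,
    )


def ttest_bonferroni(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    m: int | None = None,
) -> pd.DataFrame:
    """Two-sided pooled-variance t-tests with Bonferroni-corrected p-values.

    ``m`` defaults to the number of pairs and must not be smaller.
    """
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise DataValidationError("Bonferroni m smaller than the number of tests")
    rows = []
    for i, (a, b) in enumerate(pairs):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise DataValidationError(f"pair {i}: each side needs >= 2 values")
        if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            t, p = 0.0, 1.0
        else:
            res = sps.ttest_ind(a, b, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"pair": i, "t": t, "p": p, "p_bonferroni": min(1.0, m * p)})
    return pd.DataFrame(rows).set_index("pair")


def na_k_ratio(
    na: Sequence[float],
    k: Sequence[float],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sample Na/K ratios; with group labels, adds a mean +/- SE summary.

    Returns a frame with per-sample ratios; the group summary (if
    requested) is attached as ``frame.attrs['summary']``.
    """
    na = np.asarray(na, dtype=float)
    k = np.asarray(k, dtype=float)
    if na.shape != k.shape:
        raise DataValidationError("Na and K vectors differ in length")
    bad = np.flatnonzero(k <= 0)
    if bad.size:
        raise DataValidationError(f"non-positive K concentration at samples {bad.tolist()}")
    out = pd.DataFrame({"na": na, "k": k, "ratio": na / k})
    if groups is not None:
        out["group"] = list(groups)
        grp = out.groupby("group", sort=False)["ratio"]
        out.attrs["summary"] = pd.DataFrame(
            {"mean": grp.mean(), "se": grp.sem(ddof=1)}
        )
    return out


def fold_summary(
    metab: pd.DataFrame,
    control_label: str = "control",
    arm_of=None,
) -> pd.DataFrame:
    """Per-analyte per-condition fold change of mean concentration vs control.

    ``metab`` is long-format with columns analyte/condition/concentration.
    ``arm_of`` maps a condition label to its arm (default: text before the
    last ``-``); the row of greatest |log2 fold| per arm is flagged in the
    ``arm_max`` column.
    """
    required = {"analyte", "condition", "concentration"}
    if not required.issubset(metab.columns):
        raise DataValidationError(f"metabolite table needs columns {sorted(required)}")
    if (metab["concentration"] <= 0).any():
        raise DataValidationError("concentrations must be strictly positive")
    if arm_of is None:
        arm_of = lambda label: label.rsplit("-", 1)[0]
    means = metab.groupby(["analyte", "condition"], sort=False)["concentration"].mean()
    rows = []
    for analyte, sub in means.groupby(level="analyte", sort=False):
        sub = sub.droplevel("analyte")
        if control_label not in sub.index:
            raise DataValidationError(f"analyte {analyte!r} lacks a control condition")
        control_mean = sub[control_label]
        for condition, value in sub.items():
            if condition == control_label:
                continue
            rows.append(
                {
                    "analyte": analyte,
                    "condition": condition,
                    "arm": arm_of(condition),
                    "fold": value / control_mean,
                }
            )
    out = pd.DataFrame(rows)
    out["arm_max"] = False
    for (_, _), idx in out.groupby(["analyte", "arm"], sort=False).groups.items():
        sub = out.loc[idx, "fold"]
        out.loc[np.abs(np.log2(sub)).idxmax(), "arm_max"] = True
    return out
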