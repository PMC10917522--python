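"""Time-point differential expression testing.

The pipeline mirrors standard label-free practice: log2 transform (the
intensities are log-normal), per-sample median centring to equalize
variances, a two-sample t-test per protein for each pair of time points,
Benjamini-Hochberg adjustment at 5% FDR within each contrast, and a
|log2 fold change| >= 1 filter applied symmetrically.

Welch's unequal-variance t-test is the default; a pooled-variance test is
available via ``ContrastSpec(equal_var=True)``. With only two replicates
per group p-values are unstable — a warning is emitted and simulation-based
validation should use more replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, TransformError
from .matrix import AbundanceMatrix, group_label


@dataclass(frozen=True)
class ContrastSpec:
    """One sample-pair contrast: group A vs group B, each a (batch, hours) pair."""

    group_a: tuple[int, float]
    group_b: tuple[int, float]
    fdr_level: float = 0.05
    min_abs_log2fc: float = 1.0
    equal_var: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise InputError("fdr_level must lie in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise InputError("min_abs_log2fc must be >= 0")


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 of every detected value; missing cells stay missing."""
    vals = matrix.values
    arr = vals.to_numpy(float)
    if np.nanmin(arr, initial=np.inf) <= 0:
        raise TransformError("non-positive value encountered before log2 transform")
    return matrix.derive(np.log2(vals), "log2")


def log2_median_centre(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2 transform followed by per-sample median subtraction.

    After centring every sample's median over its detected proteins is 0.
    Accepts either a raw positive matrix or an already log2 matrix.
    """
    if matrix.value_kind != "log2":
        matrix = log2_transform(matrix)
    logged = matrix.values
    centred = logged.sub(logged.median(axis=0, skipna=True), axis=1)
    return matrix.derive(centred, "log2-centred")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` clipped at 1, mapped back to the
    input order; ties are handled stably.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _group_block(matrix: AbundanceMatrix, group: tuple[int, float]) -> pd.DataFrame:
    batch, hours = group
    sel = matrix.samples[(matrix.samples["batch"] == batch)
                         & (matrix.samples["hours"] == hours)]
    if sel.empty:
        raise InputError(f"no samples for group (batch={batch}, hours={hours})")
    return matrix.values[list(sel.index)]


def test_contrast(matrix: AbundanceMatrix, spec: ContrastSpec) -> pd.DataFrame:
    """Per-protein two-sample t-test between two time-point groups.

    Expects a log2-centred matrix with replicate columns. Only proteins
    detected in *every* replicate of both groups are tested (the strict
    both-replicates detection rule); skipped proteins are returned with a
    ``reason`` and ``NaN`` statistics. BH adjustment runs over the tested
    set only. ``log2fc = mean_A - mean_B``; a DEP call requires both
    ``p_adj < fdr_level`` and ``|log2fc| >= min_abs_log2fc``.
    """
    if matrix.value_kind != "log2-centred":
        raise InputError("test_contrast expects a log2-centred matrix")
    a = _group_block(matrix, spec.group_a)
    b = _group_block(matrix, spec.group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        warnings.warn("groups with <2 replicate columns cannot be tested", stacklevel=2)
    if a.shape[1] == 2 or b.shape[1] == 2:
        warnings.warn(
            "n=2 per group: t-test p-values are unstable; interpret with care",
            stacklevel=2)

    complete = a.notna().all(axis=1) & b.notna().all(axis=1)
    enough = complete & (a.shape[1] >= 2) & (b.shape[1] >= 2)

    result = pd.DataFrame(index=matrix.proteins)
    result["mean_a"] = a.mean(axis=1)
    result["mean_b"] = b.mean(axis=1)
    result["log2fc"] = result["mean_a"] - result["mean_b"]
    result["p_raw"] = np.nan
    result["p_adj"] = np.nan
    result["is_dep"] = False
    result["direction"] = pd.NA
    result["reason"] = pd.NA
    result.loc[~enough, ["mean_a", "mean_b", "log2fc"]] = np.nan
    result.loc[~enough, "reason"] = "not detected in all replicates of both groups"

    tested = result.index[enough]
    if len(tested):
        av = a.loc[tested].to_numpy(float)
        bv = b.loc[tested].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = stats.ttest_ind(av, bv, axis=1, equal_var=spec.equal_var)
        p = np.asarray(stat.pvalue, dtype=float)
        diff = av.mean(axis=1) - bv.mean(axis=1)
        # zero variance in both groups: identical values -> no evidence (p=1)
        degenerate = np.isnan(p)
        p[degenerate & (diff == 0)] = 1.0
        p[degenerate & (diff != 0)] = 0.0
        result.loc[tested, "p_raw"] = p
        result.loc[tested, "p_adj"] = bh_adjust(p)
        lfc = result.loc[tested, "log2fc"]
        dep = (result.loc[tested, "p_adj"] < spec.fdr_level) & (lfc.abs() >= spec.min_abs_log2fc)
        result.loc[tested, "is_dep"] = dep
        result.loc[tested, "direction"] = np.where(lfc >= 0, "up-in-A", "up-in-B")
    result.index.name = "protein_id"
    return result


def dep_count_matrix(matrix: AbundanceMatrix, fdr_level: float = 0.05,
                     min_abs_log2fc: float = 1.0, equal_var: bool = False) -> pd.DataFrame:
    """Symmetric all-by-all DEP count matrix over (batch, hours) groups.

    Entry (i, j) is the number of proteins called differentially expressed
    between group i and group j; the diagonal is 0.
    """
    groups = [key for key, _ in matrix.groups()]
    if len(groups) < 2:
        raise InputError("at least two time-point groups are required")
    labels = [group_label(b, h) for b, h in groups]
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                spec = ContrastSpec(groups[i], groups[j], fdr_level=fdr_level,
                                    min_abs_log2fc=min_abs_log2fc, equal_var=equal_var)
                res = test_contrast(matrix, spec)
                n = int(res["is_dep"].sum())
                counts.iloc[i, j] = n
                counts.iloc[j, i] = n
    return counts
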