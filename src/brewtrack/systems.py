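"""Pairwise-correlation views of the proteome.

Four related analyses on a proteins x time-points abundance matrix
(typically replicate-summed log2 values):

* sample-by-sample Pearson similarity over co-detected proteins;
* all-by-all protein-pair Pearson correlation across shared detected time
  points, for proteins seen in at least ``min_timepoints`` time points;
* per-group (complex / compartment) detection coverage and within-group
  pair-correlation distributions, duplicating multi-localized proteins into
  each of their groups;
* interacting vs non-interacting pair-correlation distributions with a
  rank-based location-shift test (Mann-Whitney U).

Pairs sharing fewer than 3 time points are excluded from distribution
summaries: a two-point correlation is +/-1 by construction. The eligibility
rule (detected in >= 2 time points) governs which proteins enter, not which
pairs are summarized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .matrix import AbundanceMatrix


@dataclass
class SampleSimilarity:
    """Samples x samples Pearson matrix with per-cell co-detection counts."""

    r: pd.DataFrame
    n: pd.DataFrame
    unreliable: pd.DataFrame  # True where fewer than 3 shared proteins


@dataclass
class PairCorrelations:
    """Protein x protein Pearson matrix over shared detected time points.

    ``r`` is NaN where fewer than ``min_shared`` time points overlap;
    ``n`` counts the shared time points per pair.
    """

    r: pd.DataFrame
    n: pd.DataFrame
    min_shared: int

    def pair_table(self) -> pd.DataFrame:
        """Long-format upper-triangle pairs with valid correlations."""
        ids = self.r.index
        iu = np.triu_indices(len(ids), k=1)
        rv = self.r.to_numpy()[iu]
        nv = self.n.to_numpy()[iu]
        ok = ~np.isnan(rv)
        return pd.DataFrame({
            "protein_a": ids.to_numpy()[iu[0]][ok],
            "protein_b": ids.to_numpy()[iu[1]][ok],
            "r": rv[ok],
            "n_shared": nv[ok].astype(int),
        })


def _values(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, AbundanceMatrix) else matrix


def sample_similarity(matrix) -> SampleSimilarity:
    """All-by-all Pearson correlation between samples over co-detected proteins."""
    df = _values(matrix)
    if df.shape[1] < 2:
        raise InputError("at least 2 samples are required")
    r = df.corr(method="pearson", min_periods=2)
    present = df.notna().astype(float)
    n = present.T @ present
    np.fill_diagonal(r.to_numpy(), 1.0)
    unreliable = n < 3
    return SampleSimilarity(r=r, n=n.astype(int), unreliable=unreliable)


def protein_pair_correlations(matrix, min_timepoints: int = 2,
                              min_shared: int = 3) -> PairCorrelations:
    """Pearson correlation across time points for all eligible protein pairs.

    Proteins detected in fewer than ``min_timepoints`` time points are
    dropped; pairs sharing fewer than ``min_shared`` detected time points
    are flagged (NaN correlation).
    """
    if min_timepoints < 2:
        raise InputError("min_timepoints must be >= 2")
    df = _values(matrix)
    eligible = df.notna().sum(axis=1) >= min_timepoints
    df = df[eligible]
    if len(df) < 2:
        raise InputError("fewer than 2 eligible proteins")
    r = df.T.corr(method="pearson", min_periods=min_shared)
    present = df.notna().astype(float)
    n = present @ present.T
    np.fill_diagonal(r.to_numpy(), 1.0)
    return PairCorrelations(r=r, n=n.astype(int), min_shared=min_shared)


def group_correlation_profiles(pairs: PairCorrelations,
                               annotations: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group detection coverage and member-pair correlation values.

    ``annotations`` needs columns group_id / protein_id (group_type carried
    through if present). A protein annotated to several groups contributes
    to each. Returns ``(profiles, pair_values)``: one summary row per group
    and a long table of within-group pairs with valid correlations.
    """
    for col in ("group_id", "protein_id"):
        if col not in annotations.columns:
            raise InputError(f"annotations lack column {col!r}")
    detected = set(pairs.r.index)
    rmat = pairs.r

    profile_rows, pair_rows = [], []
    for gid, sub in annotations.groupby("group_id", sort=True):
        members = sorted(set(sub["protein_id"]))
        gtype = sub["group_type"].iloc[0] if "group_type" in sub.columns else ""
        present = [m for m in members if m in detected]
        rs = []
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                val = rmat.at[present[i], present[j]]
                if not np.isnan(val):
                    rs.append(val)
                    pair_rows.append({"group_id": gid, "protein_a": present[i],
                                      "protein_b": present[j], "r": float(val)})
        profile_rows.append({
            "group_id": gid, "group_type": gtype,
            "n_members": len(members), "n_detected": len(present),
            "fraction_detected": len(present) / len(members) if members else 0.0,
            "n_pairs": len(rs),
            "median_r": float(np.median(rs)) if rs else np.nan,
            "mean_r": float(np.mean(rs)) if rs else np.nan,
        })
    profiles = pd.DataFrame(profile_rows)
    pair_values = pd.DataFrame(pair_rows, columns=["group_id", "protein_a", "protein_b", "r"])
    return profiles, pair_values


@dataclass
class ShiftResult:
    """Interacting vs non-interacting pair correlation comparison.

    ``shift`` is the difference of medians (interacting minus
    non-interacting); ``p_value`` a one-sided Mann-Whitney U test that
    interacting pairs are more correlated. ``degenerate`` is set when one
    class is empty.
    """

    interacting: np.ndarray
    noninteracting: np.ndarray
    shift: float
    u_statistic: float
    p_value: float
    degenerate: bool = False


def interacting_vs_noninteracting(pairs: PairCorrelations, interactions) -> ShiftResult:
    """Partition all evaluated pairs by physical interaction and compare.

    ``interactions`` is an iterable of (protein_a, protein_b) pairs or a
    DataFrame with those columns; order within a pair does not matter.
    """
    if isinstance(interactions, pd.DataFrame):
        interactions = list(zip(interactions["protein_a"], interactions["protein_b"]))
    interacting_keys = {frozenset(p) for p in interactions}

    table = pairs.pair_table()
    keys = [frozenset((a, b)) for a, b in zip(table["protein_a"], table["protein_b"])]
    mask = np.array([k in interacting_keys for k in keys], dtype=bool)
    r_int = table["r"].to_numpy()[mask]
    r_non = table["r"].to_numpy()[~mask]

    if len(r_int) == 0 or len(r_non) == 0:
        return ShiftResult(interacting=r_int, noninteracting=r_non,
                           shift=np.nan, u_statistic=np.nan, p_value=np.nan,
                           degenerate=True)
    u, p = stats.mannwhitneyu(r_int, r_non, alternative="greater")
    shift = float(np.median(r_int) - np.median(r_non))
    return ShiftResult(interacting=r_int, noninteracting=r_non, shift=shift,
                       u_statistic=float(u), p_value=float(p))
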