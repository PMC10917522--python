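"""Sliding-window copy number and allele-frequency (LOH) profiling.

Copy number is estimated from tiled 1,000-bp window read depths as
``ploidy * depth / baseline depth``, so the estimate is invariant to a
global rescaling of coverage. The baseline is the median of per-chromosome
median depths rather than the plain genome-wide median: a whole-chromosome
gain can cover a quarter of all windows and would otherwise drag the
baseline off the euploid level. Integer copy calls round a rolling-median
smoothed estimate (window 5, per chromosome) — raw Poisson counting noise
at ~30x otherwise misrounds a visible fraction of windows near half-copy
boundaries, while a short median filter removes isolated flips without
moving block edges by more than a window.

Allele-frequency tracks apply the variant filters (minimum coverage,
minimum alternate count, minimum frequency), exclude the mitochondrial
contig, and assign concatenated whole-genome positions from a supplied
chromosome order so frequency can be plotted against a single axis. LOH
candidates are maximal runs of consecutive variants whose allele frequency
leaves the heterozygous band.

Coordinates: windows are 0-based half-open; variant positions are 1-based.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, IntegrityError, ProfileError

MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M", "chrmt"})


def copy_number_profile(depths: pd.DataFrame, ploidy: int = 4,
                        smooth_window: int = 5) -> pd.DataFrame:
    """Per-window copy estimates from window read depths.

    ``depths`` needs columns chrom / start / depth (end optional). Returns
    the input plus ``copy`` (continuous, unsmoothed), ``copy_smoothed``
    (rolling median per chromosome) and ``copy_int`` (rounded smoothed
    estimate), with a ``chrom_median_copy`` column repeating each
    chromosome's median copy.
    """
    for col in ("chrom", "start", "depth"):
        if col not in depths.columns:
            raise InputError(f"depth table lacks column {col!r}")
    if (depths["depth"] < 0).any():
        raise InputError("negative depths")
    counts = depths.groupby("chrom")["start"].count()
    if counts.max() < 10:
        raise InputError("need at least one chromosome with >= 10 windows")

    baseline = float(depths.groupby("chrom")["depth"].median().median())
    if baseline <= 0:
        raise ProfileError("baseline (median of per-chromosome median depths) is zero")

    out = depths.copy()
    out["copy"] = ploidy * out["depth"] / baseline
    smoothed = (
        out.groupby("chrom", sort=False)["copy"]
        .transform(lambda s: s.rolling(smooth_window, center=True, min_periods=1).median())
    )
    out["copy_smoothed"] = smoothed
    out["copy_int"] = np.rint(smoothed).astype(int)
    out["chrom_median_copy"] = out.groupby("chrom", sort=False)["copy"].transform("median")
    return out


def call_deletions(profile: pd.DataFrame, min_consecutive: int = 3) -> pd.DataFrame:
    """Maximal runs of >= ``min_consecutive`` copy-zero windows.

    Deletions are called on the *unsmoothed* copy estimate: a window of
    (near-)zero depth is unambiguous on its own, and skipping the median
    filter keeps two deletions separated by a single normal window apart.
    Returns half-open intervals (chrom, start, end, n_windows).
    """
    if "copy" not in profile.columns:
        raise InputError("profile lacks copy estimates (run copy_number_profile)")
    rows = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        zero = (np.rint(sub["copy"].to_numpy()) == 0)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy() if "end" in sub.columns else None
        i = 0
        while i < len(zero):
            if zero[i]:
                j = i
                while j + 1 < len(zero) and zero[j + 1]:
                    j += 1
                if j - i + 1 >= min_consecutive:
                    end = int(ends[j]) if ends is not None else int(starts[j] + (starts[1] - starts[0]))
                    rows.append({"chrom": chrom, "start": int(starts[i]), "end": end,
                                 "n_windows": j - i + 1})
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


def allele_frequency_track(
    variants: pd.DataFrame,
    chrom_lengths: Mapping[str, int] | Sequence[tuple[str, int]],
    min_coverage: int = 10,
    min_count: int = 2,
    min_freq: float = 0.0,
) -> pd.DataFrame:
    """Filtered allele-frequency track with concatenated genome positions.

    ``chrom_lengths`` supplies the chromosome order (insertion order) and
    lengths for the cumulative offsets. Mitochondrial variants are removed
    before filtering; a variant on a chromosome absent from
    ``chrom_lengths`` raises an integrity error. Frequency is
    alt_count / coverage; filters: coverage >= min_coverage, alt_count >=
    min_count, frequency >= min_freq.
    """
    for col in ("chrom", "pos", "coverage", "alt_count"):
        if col not in variants.columns:
            raise InputError(f"variant table lacks column {col!r}")
    lengths = dict(chrom_lengths)

    v = variants[~variants["chrom"].isin(MITO_NAMES)].copy()
    unknown = set(v["chrom"]) - set(lengths)
    if unknown:
        raise IntegrityError(f"variants on chromosomes missing from the order list: "
                             f"{sorted(unknown)}")
    if (v["alt_count"] > v["coverage"]).any():
        raise IntegrityError("alt_count exceeds coverage")

    keep = (v["coverage"] >= min_coverage) & (v["alt_count"] >= min_count)
    v = v[keep].copy()
    v["frequency"] = v["alt_count"] / v["coverage"]
    v = v[v["frequency"] >= min_freq]

    offsets = {}
    running = 0
    for chrom, length in lengths.items():
        offsets[chrom] = running
        running += int(length)
    v["concat_pos"] = v["chrom"].map(offsets) + v["pos"]
    v["chrom"] = pd.Categorical(v["chrom"], categories=list(lengths), ordered=True)
    v = v.sort_values(["chrom", "pos"]).reset_index(drop=True)
    v["chrom"] = v["chrom"].astype(str)
    return v


def loh_segments(track: pd.DataFrame, het_band: tuple[float, float] = (0.1, 0.9),
                 min_run: int = 10, max_gap: int = 1) -> pd.DataFrame:
    """Candidate LOH intervals from homozygous-like allele-frequency runs.

    A variant is homozygous-like when its frequency lies outside
    ``het_band``. Runs of at least ``min_run`` such variants (within a
    chromosome) are reported as (chrom, start_pos, end_pos, n_variants)
    with 1-based inclusive positions. Up to ``max_gap`` consecutive
    in-band variants are tolerated inside a run — at modest coverage a
    fixed site occasionally mis-estimates onto the band edge — but every
    run still starts and ends on a homozygous-like variant, so boundaries
    are not inflated by the tolerance.
    """
    lo, hi = het_band
    if not 0.0 <= lo < hi <= 1.0:
        raise InputError("het_band must satisfy 0 <= lo < hi <= 1")
    if max_gap < 0:
        raise InputError("max_gap must be >= 0")
    if "frequency" not in track.columns:
        raise InputError("track lacks a 'frequency' column")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        homo = ((sub["frequency"] < lo) | (sub["frequency"] > hi)).to_numpy()
        pos = sub["pos"].to_numpy()
        homo_idx = np.flatnonzero(homo)
        if homo_idx.size == 0:
            continue
        # group homozygous-like variants separated by <= max_gap in-band ones
        breaks = np.flatnonzero(np.diff(homo_idx) > max_gap + 1)
        groups = np.split(homo_idx, breaks + 1)
        for g in groups:
            if len(g) >= min_run:
                rows.append({"chrom": chrom, "start_pos": int(pos[g[0]]),
                             "end_pos": int(pos[g[-1]]), "n_variants": len(g)})
    return pd.DataFrame(rows, columns=["chrom", "start_pos", "end_pos", "n_variants"])
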