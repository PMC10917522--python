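"""Peptide evidence -> protein abundance matrices.

Implements the spectral-count route to protein abundance used for shotgun
proteomics of fermenting yeast:

* in-silico tryptic digestion (cleave after K/R unless followed by P) with a
  configurable missed-cleavage count and a 7-40 residue length window;
* ppm abundances from PSM counts: per protein, summed (PSM x peptide length)
  scaled by a length correction factor (the reciprocal of the summed lengths
  of the protein's in-range theoretical peptides), expressed as parts per
  million of the per-sample total;
* iBAQ: summed peptide intensity divided by the number of in-range
  theoretical peptides;
* median-ratio between-sample intensity normalization (a deliberately simple
  scaling; it does not attempt MaxLFQ-style delayed normalization);
* replicate merging by summation with a strict "detected in both replicates"
  flag, and a minimum-unique-peptides detection filter.

The ppm correction factor uses 0 missed cleavages so the theoretical peptide
space does not double-count overlapping peptides, while observed evidence
peptides may carry up to 2 missed cleavages (matching common search-engine
settings).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    InputError,
    IntegrityError,
    NormalizationError,
    QuantificationError,
)
from .matrix import AbundanceMatrix, group_label

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

EVIDENCE_COLUMNS = ("protein_id", "peptide_seq", "sample_id", "psm_count", "intensity")


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion parameters.

    ``min_len``/``max_len`` bound the retained peptide length in residues
    (inclusive). ``max_len=None`` disables the upper bound.
    """

    missed_cleavages: int = 0
    min_len: int = 7
    max_len: int | None = 40
    protease: str = "trypsin"

    def __post_init__(self) -> None:
        if self.protease != "trypsin":
            raise InputError(f"unsupported protease {self.protease!r}")
        if self.missed_cleavages < 0:
            raise InputError("missed_cleavages must be >= 0")
        if self.min_len < 1:
            raise InputError("min_len must be >= 1")
        if self.max_len is not None and self.min_len > self.max_len:
            raise InputError("min_len must be <= max_len")


class Peptide(NamedTuple):
    """A theoretical peptide: sequence, 0-based [start, end) and missed-cleavage count."""

    seq: str
    start: int
    end: int
    missed: int


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[Peptide]:
    """In-silico tryptic digestion of one protein sequence.

    Cleaves after K or R except when the next residue is P. Peptides
    containing up to ``params.missed_cleavages`` internal sites are included,
    then filtered to the [min_len, max_len] window. Output is ordered by
    start position, then end position.
    """
    if not sequence:
        raise InputError("empty protein sequence")
    bad = set(sequence) - _AA_SET
    if bad:
        raise InputError(f"invalid residue character(s): {sorted(bad)}")

    # cleavage boundaries: 0, each position after K/R not before P, len(seq)
    cuts = [0]
    n = len(sequence)
    for i in range(n - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(n)

    lo, hi = params.min_len, params.max_len
    peptides: list[Peptide] = []
    nfrag = len(cuts) - 1
    for i in range(nfrag):
        for m in range(params.missed_cleavages + 1):
            j = i + m
            if j >= nfrag:
                break
            start, end = cuts[i], cuts[j + 1]
            length = end - start
            if length < lo or (hi is not None and length > hi):
                continue
            peptides.append(Peptide(sequence[start:end], start, end, m))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def theoretical_peptides(sequence: str, params: DigestParams = DigestParams()) -> list[Peptide]:
    """In-range theoretical peptides for quantification (0 missed cleavages).

    The length window comes from ``params``; the missed-cleavage setting is
    forced to 0 so the theoretical space partitions the sequence.
    """
    zero_mc = DigestParams(missed_cleavages=0, min_len=params.min_len,
                           max_len=params.max_len, protease=params.protease)
    return digest(sequence, zero_mc)


# ----------------------------------------------------------------------
# evidence -> matrices
# ----------------------------------------------------------------------

@dataclass
class QuantResult:
    """Outcome of a quantification pass.

    ``matrix`` holds the per-sample values; ``info`` one row per quantified
    protein (correction_factor, n_theoretical_peptides); ``excluded`` lists
    proteins that could not be quantified (no in-range theoretical peptides).
    """

    matrix: AbundanceMatrix
    info: pd.DataFrame
    excluded: list[str]


def _check_evidence(evidence: pd.DataFrame, proteome: Mapping[str, str]) -> None:
    missing_cols = set(EVIDENCE_COLUMNS) - set(evidence.columns)
    if missing_cols:
        raise InputError(f"evidence table lacks columns {sorted(missing_cols)}")
    unknown = set(evidence["protein_id"]) - set(proteome)
    if unknown:
        raise IntegrityError(f"evidence references unknown proteins: {sorted(unknown)[:5]}")
    # each reported peptide must occur in its protein's sequence
    pep_map = evidence[["protein_id", "peptide_seq"]].drop_duplicates()
    for pid, pep in pep_map.itertuples(index=False):
        if pep not in proteome[pid]:
            raise IntegrityError(f"peptide {pep!r} not found in protein {pid}")


def _sample_frame(evidence: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = set(evidence["sample_id"]) - set(meta.index)
    if missing:
        raise IntegrityError(f"evidence samples absent from metadata: {sorted(missing)[:5]}")
    return meta


def ppm_quantify(
    evidence: pd.DataFrame,
    proteome: Mapping[str, str],
    metadata: pd.DataFrame,
    params: DigestParams = DigestParams(),
) -> QuantResult:
    """ppm protein abundances from PSM counts.

    Per sample, a protein's signal is ``sum(psm x peptide_length)`` over its
    observed peptides, multiplied by a correction factor ``1 / sum(lengths of
    the protein's in-range theoretical peptides)``; ppm is the signal times
    1e6 divided by the summed signal of all proteins in that sample, so each
    sample's ppm column sums to exactly one million.
    """
    _check_evidence(evidence, proteome)
    meta = _sample_frame(evidence, metadata)

    detected_proteins = sorted(set(evidence["protein_id"]))
    cf: dict[str, float] = {}
    n_theo: dict[str, int] = {}
    excluded: list[str] = []
    for pid in detected_proteins:
        peps = theoretical_peptides(proteome[pid], params)
        total_len = sum(p.end - p.start for p in peps)
        if total_len == 0:
            excluded.append(pid)
            continue
        cf[pid] = 1.0 / total_len
        n_theo[pid] = len(peps)
    if excluded:
        warnings.warn(
            f"{len(excluded)} protein(s) without in-range theoretical peptides "
            f"excluded from ppm quantification", stacklevel=2)

    ev = evidence[evidence["protein_id"].isin(cf)].copy()
    ev["weighted"] = ev["psm_count"].to_numpy(float) * ev["peptide_seq"].str.len().to_numpy(float)
    signal = (
        ev.groupby(["protein_id", "sample_id"], sort=True)["weighted"].sum().unstack("sample_id")
    )
    signal = signal.mul(pd.Series(cf), axis=0)
    signal = signal.reindex(columns=meta.index)

    totals = signal.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise QuantificationError(f"sample(s) with zero total signal: {bad}")
    ppm = signal.div(totals, axis=1) * 1e6

    info = pd.DataFrame(
        {
            "correction_factor": pd.Series(cf),
            "n_theoretical_peptides": pd.Series(n_theo),
        }
    ).loc[ppm.index]
    matrix = AbundanceMatrix(values=ppm, samples=meta, value_kind="ppm")
    return QuantResult(matrix=matrix, info=info, excluded=excluded)


def ibaq_quantify(
    evidence: pd.DataFrame,
    proteome: Mapping[str, str],
    metadata: pd.DataFrame,
    params: DigestParams = DigestParams(),
) -> QuantResult:
    """iBAQ abundances: summed peptide intensity / n in-range theoretical peptides."""
    _check_evidence(evidence, proteome)
    meta = _sample_frame(evidence, metadata)

    detected_proteins = sorted(set(evidence["protein_id"]))
    n_theo: dict[str, int] = {}
    excluded: list[str] = []
    for pid in detected_proteins:
        n = len(theoretical_peptides(proteome[pid], params))
        if n == 0:
            excluded.append(pid)
        else:
            n_theo[pid] = n
    if excluded:
        warnings.warn(
            f"{len(excluded)} protein(s) without in-range theoretical peptides "
            f"excluded from iBAQ quantification", stacklevel=2)

    ev = evidence[evidence["protein_id"].isin(n_theo)]
    summed = (
        ev.groupby(["protein_id", "sample_id"], sort=True)["intensity"].sum().unstack("sample_id")
    )
    ibaq = summed.div(pd.Series(n_theo), axis=0).reindex(columns=meta.index)

    info = pd.DataFrame({"n_theoretical_peptides": pd.Series(n_theo)}).loc[ibaq.index]
    matrix = AbundanceMatrix(values=ibaq, samples=meta, value_kind="ibaq")
    return QuantResult(matrix=matrix, info=info, excluded=excluded)


def intensity_matrix(evidence: pd.DataFrame, proteome: Mapping[str, str],
                     metadata: pd.DataFrame) -> AbundanceMatrix:
    """Summed raw peptide intensities per protein, with unique-peptide counts.

    This is the label-free intensity surface the downstream time-course
    analyses run on (normalization, replicate merging, log transform).
    """
    _check_evidence(evidence, proteome)
    meta = _sample_frame(evidence, metadata)
    grouped = evidence.groupby(["protein_id", "sample_id"], sort=True)
    values = grouped["intensity"].sum().unstack("sample_id").reindex(columns=meta.index)
    counts = grouped["peptide_seq"].nunique().unstack("sample_id").reindex(columns=meta.index)
    return AbundanceMatrix(values=values, samples=meta, value_kind="intensity",
                           peptide_counts=counts)


# ----------------------------------------------------------------------
# matrix-level operations
# ----------------------------------------------------------------------

def normalize_intensities(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, pd.Series]:
    """Median-ratio scaling of each sample to a geometric-mean pseudo-reference.

    The reference is built over proteins detected in every sample. Each
    sample is multiplied by ``1 / median(sample / reference)``; the returned
    Series holds those multiplicative factors.
    """
    if matrix.value_kind != "intensity":
        raise InputError("normalize_intensities expects a raw intensity matrix")
    vals = matrix.values
    universal = vals.dropna(axis=0)
    universal = universal[(universal > 0).all(axis=1)]
    if len(universal) < 3:
        raise NormalizationError(
            f"only {len(universal)} proteins detected in all samples; >=3 required")
    log_ref = np.log(universal).mean(axis=1)
    ratios = np.log(universal).sub(log_ref, axis=0)
    factors = np.exp(-ratios.median(axis=0))
    factors = factors / factors.median()  # typical sample keeps factor 1
    normalized = vals.mul(factors, axis=1)
    out = matrix.derive(normalized, "normalized-intensity",
                        meta={**matrix.meta, "scaling_factors": factors.to_dict()})
    return out, factors


def merge_replicates(matrix: AbundanceMatrix, strict: bool = True) -> AbundanceMatrix:
    """Collapse replicates to one column per (batch, hours) time point.

    The merged value is the sum of the replicate values (NaN-aware: a protein
    seen in one replicate keeps that replicate's signal). The ``detected``
    flags require presence in *all* replicates of the time point when
    ``strict`` is True — the rule applied before differential testing — and
    presence in any replicate otherwise.
    """
    if matrix.merged:
        raise InputError("matrix is already replicate-merged")
    if "replicate" not in matrix.samples.columns:
        raise IntegrityError("sample metadata lacks a 'replicate' column")

    declared = matrix.samples.groupby(["batch", "hours"])["replicate"].nunique()
    if declared.nunique() != 1:
        raise IntegrityError("unequal replicate counts across (batch, hours) groups")

    cols, labels, meta_rows = [], [], []
    detected_cols = []
    for (batch, hours), sub in matrix.groups():
        ids = list(sub.index)
        block = matrix.values[ids]
        merged = block.sum(axis=1, min_count=1)
        present = block.notna()
        flag = present.all(axis=1) if strict else present.any(axis=1)
        label = group_label(batch, hours)
        cols.append(merged.rename(label))
        detected_cols.append(flag.rename(label))
        labels.append(label)
        meta_rows.append({"batch": batch, "hours": hours})

    values = pd.concat(cols, axis=1)
    detected = pd.concat(detected_cols, axis=1)
    samples = pd.DataFrame(meta_rows, index=pd.Index(labels, name="sample_id"))
    return AbundanceMatrix(values=values, samples=samples, value_kind=matrix.value_kind,
                           detected=detected, merged=True, meta=dict(matrix.meta))


def filter_min_unique_peptides(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Mask cells supported by fewer than ``k`` unique peptides.

    Proteins left with no remaining observation are dropped entirely.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if matrix.peptide_counts is None:
        raise InputError("matrix carries no per-cell unique-peptide counts")
    keep_mask = matrix.peptide_counts >= k
    values = matrix.values.where(keep_mask)
    counts = matrix.peptide_counts.where(keep_mask)
    row_keep = values.notna().any(axis=1)
    values, counts = values[row_keep], counts[row_keep]
    out = matrix.derive(values, matrix.value_kind)
    out.peptide_counts = counts
    return out


def proteome_dict(records: Iterable) -> dict[str, str]:
    """Map Biopython SeqRecords (or (id, seq) pairs) to {protein_id: sequence}."""
    out: dict[str, str] = {}
    for rec in records:
        if hasattr(rec, "id") and hasattr(rec, "seq"):
            out[rec.id] = str(rec.seq)
        else:
            pid, seq = rec
            out[pid] = str(seq)
    return out
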