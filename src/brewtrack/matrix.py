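"""Protein-by-sample abundance container.

The :class:`AbundanceMatrix` couples a proteins x samples value table with
the sample metadata (batch, time point in hours, replicate), a ``value_kind``
tag recording where the values sit in the transform chain, and optional
per-cell unique-peptide counts / detection flags.

Missing observations are stored as ``NaN`` — never as zero — until after the
log transform; downstream code relies on this to distinguish "not detected"
from "present at low level".

The value kind moves only along the documented chain::

    psm / ppm / ibaq / intensity --> normalized-intensity (intensity only)
                                 --> log2 --> log2-centred
                                          --> row-centred
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import IntegrityError, TransformError

RAW_KINDS = frozenset({"psm", "ppm", "ibaq", "intensity"})

#: allowed transitions of ``value_kind`` (merging replicates keeps the kind).
_ALLOWED_TRANSITIONS: dict[str, frozenset[str]] = {
    "psm": frozenset({"log2"}),
    "ppm": frozenset({"log2"}),
    "ibaq": frozenset({"log2"}),
    "intensity": frozenset({"normalized-intensity", "log2"}),
    "normalized-intensity": frozenset({"log2"}),
    "log2": frozenset({"log2-centred", "row-centred"}),
    "log2-centred": frozenset({"row-centred"}),
    "row-centred": frozenset(),
}

SAMPLE_COLUMNS = ("batch", "hours", "replicate")


@dataclass
class AbundanceMatrix:
    """Proteins x samples quantification with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        ``NaN`` marks a protein not detected in that sample.
    samples
        DataFrame indexed by sample id with columns ``batch`` (int),
        ``hours`` (float) and, before replicate merging, ``replicate`` (int).
    value_kind
        Tag from the documented transform chain (see module docstring).
    peptide_counts
        Optional per-cell count of unique peptides supporting the value.
    detected
        Optional boolean detection flags; populated by replicate merging.
    merged
        True once replicates have been collapsed to one column per
        (batch, hours) group.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    value_kind: str
    peptide_counts: pd.DataFrame | None = None
    detected: pd.DataFrame | None = None
    merged: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value_kind not in _ALLOWED_TRANSITIONS:
            raise TransformError(f"unknown value_kind {self.value_kind!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise IntegrityError("matrix columns do not match sample metadata index")
        for col in ("batch", "hours"):
            if col not in self.samples.columns:
                raise IntegrityError(f"sample metadata lacks required column {col!r}")
        if self.value_kind in RAW_KINDS or self.value_kind == "normalized-intensity":
            if np.nanmin(self.values.to_numpy(), initial=0.0) < 0:
                raise TransformError(
                    f"negative values are not allowed before the log transform "
                    f"(value_kind={self.value_kind!r})"
                )

    # ------------------------------------------------------------------
    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def derive(self, values: pd.DataFrame, value_kind: str, **kwargs) -> "AbundanceMatrix":
        """Return a copy with new values, enforcing the value-kind chain."""
        if value_kind != self.value_kind:
            allowed = _ALLOWED_TRANSITIONS[self.value_kind]
            if value_kind not in allowed:
                raise TransformError(
                    f"cannot move value_kind {self.value_kind!r} -> {value_kind!r}; "
                    f"allowed: {sorted(allowed) or 'none'}"
                )
        return replace(self, values=values, value_kind=value_kind, **kwargs)

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Group sample metadata by (batch, hours)."""
        return self.samples.groupby(["batch", "hours"], sort=True)

    def subset_samples(self, sample_ids) -> "AbundanceMatrix":
        sample_ids = list(sample_ids)
        return replace(
            self,
            values=self.values[sample_ids],
            samples=self.samples.loc[sample_ids],
            peptide_counts=None if self.peptide_counts is None else self.peptide_counts[sample_ids],
            detected=None if self.detected is None else self.detected[sample_ids],
        )


def group_label(batch, hours) -> str:
    """Canonical column label for a merged (batch, hours) sample group."""
    return f"b{int(batch)}_t{hours:g}h"
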