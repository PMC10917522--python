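"""Synthetic fermentation-study data with known ground truth.

Everything the downstream modules consume can be generated here: a random
proteome (FASTA), per-sample peptide evidence with log-normally distributed
intensities, sample metadata for a 2-batch x ~7-time-point x 2-replicate
design, annotation tables (complexes, compartments, term sets, pathways),
and genome tracks (window read depths, variant allele counts) with planted
copy-number changes and loss-of-heterozygosity blocks.

The generative model, briefly:

* protein base abundances are log-normal (natural-log mean/sd configurable,
  defaults give a ~4 orders-of-magnitude dynamic range as seen in label-free
  yeast proteomes);
* each planted cluster carries a multiplicative trajectory over the time
  points; background proteins (cluster label 0) are flat;
* proteins in a planted complex share a latent temporal signal so that the
  expected within-complex log-abundance correlation equals the complex's
  target rho, against an uncorrelated background;
* technical replicate noise is log-normal with a configurable CV;
* detection is abundance-dependent: a logistic function of log abundance
  centred at ``detection_limit``, reproducing the observation that low-copy
  proteins drop out of shotgun MS runs;
* PSM counts are Poisson with mean proportional to log intensity above a
  floor, clamped to >= 1 for anything reported;
* genome windows draw Poisson read counts scaled by (true copy / ploidy);
  LOH blocks emit variants with allele fraction near 0 or 1, heterozygous
  regions draw from the tetraploid fractions {0.25, 0.5, 0.75}.

All generators are deterministic under ``SimulationConfig.seed``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.special import expit

from .errors import ConfigError, IntegrityError
from .quantify import AMINO_ACIDS, DigestParams, theoretical_peptides

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_cluster_profiles",
    "generate_proteome",
    "generate_evidence",
    "generate_genome_tracks",
    "generate_annotations",
    "planted_driver_pathways",
    "simulate_two_group_log2",
]

_COMPARTMENTS = (
    "cytoplasm", "nucleus", "mitochondrion", "endoplasmic_reticulum",
    "golgi", "vacuole", "peroxisome", "plasma_membrane",
)


def _orthonormal_contrasts(n_points: int, k: int) -> np.ndarray:
    """First ``k`` orthonormal polynomial contrasts over ``n_points`` (rows)."""
    if k > n_points - 1:
        raise ConfigError(f"cannot build {k} contrasts over {n_points} time points")
    t = np.linspace(-1.0, 1.0, n_points)
    basis: list[np.ndarray] = []
    for d in range(1, k + 1):
        v = t ** d
        v = v - v.mean()
        for b in basis:
            v = v - (v @ b) * b
        v = v / np.linalg.norm(v)
        basis.append(v)
    return np.asarray(basis)


def default_cluster_profiles(n_timepoints: int = 7, n_clusters: int = 6,
                             amplitude: float = 1.5) -> tuple[tuple[float, ...], ...]:
    """Well-separated multiplicative trajectory archetypes.

    For the default six clusters the archetypes form three correlated pairs
    built from orthonormal polynomial contrasts: two pairs share orthogonal
    family signals and the third pair sits opposite both, so profile
    correlation splits the archetype families cleanly before it splits
    archetypes within a family. ``amplitude`` is the peak log2 deviation
    (1.5 -> roughly 8-fold swing over the course, typical of strongly
    responding fermentation proteins). For other cluster counts, plain
    orthogonal contrasts are used.
    """
    if n_clusters == 0:
        return ()
    if n_clusters == 6:
        c = _orthonormal_contrasts(n_timepoints, 5)
        s3 = -(c[0] + c[1]) / np.sqrt(2.0)
        raw = [
            np.sqrt(0.75) * c[0] + 0.5 * c[2],
            np.sqrt(0.75) * c[0] - 0.5 * c[2],
            np.sqrt(0.75) * c[1] + 0.5 * c[3],
            np.sqrt(0.75) * c[1] - 0.5 * c[3],
            np.sqrt(0.75) * s3 + 0.5 * c[4],
            np.sqrt(0.75) * s3 - 0.5 * c[4],
        ]
    else:
        raw = list(_orthonormal_contrasts(n_timepoints, n_clusters))
    profiles = []
    for v in raw:
        log2p = amplitude * v / np.max(np.abs(v))
        profiles.append(tuple(float(x) for x in 2.0 ** log2p))
    return tuple(profiles)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for all three generators.

    Proteomics defaults emulate the fermentation design: 2 batches x 7 time
    points x 2 independent replicates, six planted trajectory archetypes on
    top of a flat background, and twenty 5-member complexes with target
    within-complex correlation 0.7. Genome defaults describe a toy
    tetraploid of 4 chromosomes x 500 one-kilobase windows at 30x coverage
    with one whole-chromosome gain, one segmental loss, one deletion and two
    LOH blocks planted.
    """

    # --- proteome / evidence ------------------------------------------------
    n_proteins: int = 600
    n_batches: int = 2
    timepoints_hours: tuple[tuple[float, ...], ...] = (
        (0.0, 6.0, 24.0, 48.0, 72.0, 96.0, 120.0),
        (0.0, 6.0, 24.0, 48.0, 72.0, 96.0, 120.0),
    )
    n_replicates: int = 2
    n_planted_clusters: int = 6
    cluster_profiles: tuple[tuple[float, ...], ...] | None = None
    cluster_weights: tuple[float, ...] | None = None
    background_fraction: float = 0.25
    complex_specs: tuple[tuple[int, float], ...] = ((5, 0.7),) * 20
    base_abundance_log_mean: float = 13.0
    base_abundance_log_sd: float = 2.0
    temporal_cv: float = 0.10
    replicate_cv: float = 0.20
    detection_limit: float = 6.0e4
    detection_scale: float = 0.5
    psm_rate: float = 1.0
    psm_floor: float = 600.0
    peptide_observability: float = 0.6
    protein_length_range: tuple[int, int] = (100, 1000)
    # --- genome ---------------------------------------------------------------
    n_chromosomes: int = 4
    windows_per_chromosome: int = 500
    window_size: int = 1000
    ploidy: int = 4
    coverage: float = 30.0
    read_length: int = 150
    variant_spacing: int = 300
    cnv_specs: tuple[tuple[int, int, int, int], ...] = (
        (1, 0, 500, 5),    # whole-chromosome gain (copy 5 of 4)
        (2, 250, 40, 3),   # segmental loss
        (0, 120, 8, 0),    # homozygous deletion
    )
    loh_specs: tuple[tuple[int, int, int, float], ...] = (
        (3, 100, 150, 1.0),
        (0, 300, 80, 0.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ConfigError("n_batches and n_replicates must be >= 1")
        if self.n_planted_clusters < 0:
            raise ConfigError("n_planted_clusters must be >= 0")
        if len(self.timepoints_hours) != self.n_batches:
            raise ConfigError("one time-point list per batch is required")
        n_tp = {len(tp) for tp in self.timepoints_hours}
        if len(n_tp) != 1:
            raise ConfigError("all batches must share the same number of time points")
        for tps in self.timepoints_hours:
            arr = np.asarray(tps, dtype=float)
            if (arr < 0).any():
                raise ConfigError("time points must be non-negative")
            if not (np.diff(arr) > 0).all():
                raise ConfigError("time points must be strictly increasing within a batch")
        profiles = self.resolved_cluster_profiles()
        if len(profiles) != self.n_planted_clusters:
            raise ConfigError("need one trajectory per planted cluster")
        for p in profiles:
            if len(p) != self.n_timepoints:
                raise ConfigError("cluster trajectory length must equal the time-point count")
            if min(p) <= 0:
                raise ConfigError("trajectory multipliers must be positive")
        if self.cluster_weights is not None:
            if len(self.cluster_weights) != self.n_planted_clusters:
                raise ConfigError("one weight per planted cluster required")
            if min(self.cluster_weights) <= 0:
                raise ConfigError("cluster weights must be positive")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigError("background_fraction must lie in [0, 1]")
        for size, rho in self.complex_specs:
            if size < 2:
                raise ConfigError("complex size must be >= 2")
            if not 0.0 <= rho < 1.0:
                raise ConfigError("complex target correlation must lie in [0, 1)")
        if self.temporal_cv < 0 or self.replicate_cv < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        if self.detection_limit <= 0 or self.detection_scale <= 0:
            raise ConfigError("detection_limit and detection_scale must be positive")
        if self.psm_rate <= 0 or self.psm_floor <= 0:
            raise ConfigError("psm_rate and psm_floor must be positive")
        lo, hi = self.protein_length_range
        if lo < 20 or hi < lo:
            raise ConfigError("protein_length_range must satisfy 20 <= lo <= hi")
        if self.ploidy < 1 or self.window_size < 1 or self.coverage <= 0:
            raise ConfigError("invalid genome parameters")

    # ------------------------------------------------------------------
    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_hours[0])

    def resolved_cluster_profiles(self) -> tuple[tuple[float, ...], ...]:
        if self.cluster_profiles is not None:
            return tuple(tuple(p) for p in self.cluster_profiles)
        return default_cluster_profiles(self.n_timepoints, self.n_planted_clusters)

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for b in range(1, self.n_batches + 1):
            for t in self.timepoints_hours[b - 1]:
                for r in range(1, self.n_replicates + 1):
                    rows.append({
                        "sample_id": f"b{b}_t{t:g}_r{r}",
                        "batch": b, "hours": float(t), "replicate": r,
                    })
        return pd.DataFrame(rows)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators.

    ``cluster_labels`` maps every protein to exactly one cluster (0 =
    background); ``complexes`` maps complex id -> member proteins;
    ``true_abundance`` holds the expected (pre-technical-noise) intensity per
    protein and sample; the genome fields are filled by
    :func:`generate_genome_tracks`.
    """

    cluster_labels: pd.Series | None = None
    complexes: dict[str, list[str]] = field(default_factory=dict)
    complex_rho: dict[str, float] = field(default_factory=dict)
    true_abundance: pd.DataFrame | None = None
    window_copy: pd.DataFrame | None = None
    variant_truth: pd.DataFrame | None = None


# ----------------------------------------------------------------------
# proteome
# ----------------------------------------------------------------------

def generate_proteome(config: SimulationConfig) -> tuple[list[SeqRecord], GroundTruth]:
    """Random proteome plus cluster / complex membership ground truth.

    Sequences draw the 20 standard residues uniformly (K+R therefore ~10%
    combined), which makes tryptic digestion productive: essentially every
    100-1000 residue protein yields in-range (7-40 aa) peptides.
    """
    rng = config._rng(0)
    lo, hi = config.protein_length_range
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    records = []
    for pid in ids:
        length = int(rng.integers(lo, hi + 1))
        seq = bytes(aa[rng.integers(0, len(aa), size=length)]).decode()
        records.append(SeqRecord(Seq(seq), id=pid, description=""))

    # cluster assignment: background first, then planted clusters by weight
    perm = rng.permutation(config.n_proteins)
    n_bg = int(round(config.background_fraction * config.n_proteins))
    labels = np.zeros(config.n_proteins, dtype=int)
    planted = perm[n_bg:]
    k = config.n_planted_clusters
    if k > 0 and len(planted) > 0:
        if config.cluster_weights is not None:
            w = np.asarray(config.cluster_weights, dtype=float)
        elif k == 6:
            # four larger and two smaller archetype clusters; real cluster
            # size spectra are far from uniform
            w = np.array([2.5, 2.5, 2.5, 2.5, 1.0, 1.0])
        else:
            w = np.ones(k)
        w = w / w.sum()
        counts = np.floor(w * len(planted)).astype(int)
        for i in range(len(planted) - counts.sum()):
            counts[i % k] += 1
        pos = 0
        for c in range(k):
            labels[planted[pos:pos + counts[c]]] = c + 1
            pos += counts[c]

    truth = GroundTruth(cluster_labels=pd.Series(labels, index=pd.Index(ids, name="protein_id")))

    # complexes: disjoint, drawn from the background pool so complex
    # co-regulation is not confounded with cluster trajectories
    pool = [ids[i] for i in perm[:n_bg]]
    if len(pool) < sum(s for s, _ in config.complex_specs):
        pool = pool + [ids[i] for i in planted]
    cursor = 0
    for c_idx, (size, rho) in enumerate(config.complex_specs):
        if cursor + size > len(pool):
            break
        cid = f"CPX{c_idx + 1:03d}"
        truth.complexes[cid] = pool[cursor:cursor + size]
        truth.complex_rho[cid] = float(rho)
        cursor += size
    return records, truth


# ----------------------------------------------------------------------
# evidence
# ----------------------------------------------------------------------

def generate_evidence(
    config: SimulationConfig,
    proteome: Sequence[SeqRecord] | Mapping[str, str],
    truth: GroundTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample peptide evidence table and sample metadata.

    Returns ``(evidence, metadata)`` where evidence has columns
    (protein_id, peptide_seq, sample_id, psm_count, intensity) and metadata
    has (sample_id, batch, hours, replicate). Also fills
    ``truth.true_abundance``.
    """
    if hasattr(proteome, "items"):
        seqs = {pid: str(s) for pid, s in proteome.items()}
    else:
        seqs = {rec.id: str(rec.seq) for rec in proteome}
    if truth.cluster_labels is None:
        raise IntegrityError("ground truth lacks cluster labels; run generate_proteome first")
    unknown = set(truth.cluster_labels.index) - set(seqs)
    if unknown:
        raise IntegrityError(f"ground truth references unknown proteins: {sorted(unknown)[:5]}")

    rng = config._rng(1)
    ids = list(truth.cluster_labels.index)
    n_prot = len(ids)
    labels = truth.cluster_labels.to_numpy()
    profiles = config.resolved_cluster_profiles()

    meta = config.sample_table()
    n_tp_total = config.n_batches * config.n_timepoints
    n_rep = config.n_replicates
    sample_ids = meta["sample_id"].to_numpy()

    # log2 trajectory per protein per (batch, time) column
    log2_profile = np.zeros((n_prot, n_tp_total))
    if profiles:
        prof = np.log2(np.asarray(profiles))          # (k, T)
        tiled = np.tile(prof, (1, config.n_batches))  # same trajectory in every batch
        planted_mask = labels > 0
        log2_profile[planted_mask] = tiled[labels[planted_mask] - 1]

    # temporal (biological) deviations, with shared complex latents
    sd_t = float(np.sqrt(np.log1p(config.temporal_cv ** 2)))
    eps = rng.standard_normal((n_prot, n_tp_total))
    mix = eps.copy()
    idx_of = {pid: i for i, pid in enumerate(ids)}
    for cid, members in truth.complexes.items():
        rho = truth.complex_rho.get(cid, 0.0)
        if rho <= 0:
            continue
        z = rng.standard_normal(n_tp_total)
        w = np.sqrt(rho)
        rows = [idx_of[m] for m in members if m in idx_of]
        mix[rows] = w * z + np.sqrt(1.0 - rho) * eps[rows]

    ln_base = rng.normal(config.base_abundance_log_mean, config.base_abundance_log_sd, n_prot)
    ln_expected = ln_base[:, None] + np.log(2.0) * log2_profile + sd_t * mix  # (P, BT)

    truth.true_abundance = pd.DataFrame(
        np.repeat(np.exp(ln_expected), n_rep, axis=1),
        index=pd.Index(ids, name="protein_id"), columns=sample_ids,
    )

    # technical replicate noise; the zero-CV limit produces byte-identical
    # replicates (counting noise included), so replicate streams are drawn
    # once per time point and tiled in that case
    sd_r = float(np.sqrt(np.log1p(config.replicate_cv ** 2)))
    zero_noise = config.replicate_cv == 0.0
    if zero_noise:
        ln_obs = np.repeat(ln_expected, n_rep, axis=1)
    else:
        ln_obs = (np.repeat(ln_expected, n_rep, axis=1)
                  + rng.normal(0.0, sd_r, (n_prot, n_tp_total * n_rep)))

    # abundance-dependent detection (logistic in log abundance)
    p_detect = expit((ln_obs - np.log(config.detection_limit)) / config.detection_scale)
    if zero_noise:
        u = np.repeat(rng.random((n_prot, n_tp_total)), n_rep, axis=1)
    else:
        u = rng.random((n_prot, n_tp_total * n_rep))
    detected = u < p_detect

    # observable peptides per protein (flyability-weighted intensity shares)
    dp = DigestParams()
    pep_protein: list[int] = []
    pep_seqs: list[str] = []
    for i, pid in enumerate(ids):
        peps = theoretical_peptides(seqs[pid], dp)
        if not peps:
            continue
        obs = rng.random(len(peps)) < config.peptide_observability
        if not obs.any():
            obs[0] = True
        for p, keep in zip(peps, obs):
            if keep:
                pep_protein.append(i)
                pep_seqs.append(p.seq)
    pep_protein_arr = np.asarray(pep_protein, dtype=int)
    fly = rng.lognormal(0.0, 0.5, len(pep_seqs))
    share = np.empty_like(fly)
    for i in range(n_prot):
        sel = pep_protein_arr == i
        if sel.any():
            share[sel] = fly[sel] / fly[sel].sum()

    intensity = np.exp(ln_obs)[pep_protein_arr] * share[:, None]   # (Npep, S)
    lam = config.psm_rate * np.clip(np.log(intensity / config.psm_floor), 0.0, None)
    if zero_noise:
        lam_tp = lam[:, ::n_rep]
        psm = np.repeat(np.maximum(1, rng.poisson(lam_tp)), n_rep, axis=1)
    else:
        psm = np.maximum(1, rng.poisson(lam))

    keep = detected[pep_protein_arr]
    rows, cols = np.nonzero(keep)
    id_arr = np.asarray(ids, dtype=object)
    pep_arr = np.asarray(pep_seqs, dtype=object)
    evidence = pd.DataFrame({
        "protein_id": id_arr[pep_protein_arr[rows]],
        "peptide_seq": pep_arr[rows],
        "sample_id": sample_ids[cols],
        "psm_count": psm[rows, cols].astype(int),
        "intensity": intensity[rows, cols],
    })
    return evidence, meta


# ----------------------------------------------------------------------
# genome tracks
# ----------------------------------------------------------------------

def generate_genome_tracks(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Window-depth and variant allele-count tables with planted CNV / LOH.

    Window read counts are Poisson with mean ``coverage * window / read_len
    * copy / ploidy``; depth is reported as mean reads per base. Variants
    are spaced regularly; heterozygous positions draw allele fractions from
    the tetraploid set {0.25, 0.5, 0.75}, LOH positions sit near 0 or 1
    (with a 0.5% sequencing-error floor). A small mitochondrial contig
    ("chrM") is included among the variants to exercise its exclusion
    downstream.
    """
    rng = config._rng(2)
    truth = truth or GroundTruth()

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    n_win = config.windows_per_chromosome
    wsize = config.window_size
    lam0 = config.coverage * wsize / config.read_length

    copy = np.full((config.n_chromosomes, n_win), config.ploidy, dtype=int)
    for chrom_idx, start, n, c in config.cnv_specs:
        copy[chrom_idx, start:start + n] = c

    depth_rows = []
    copy_rows = []
    for ci, chrom in enumerate(chroms):
        reads = rng.poisson(lam0 * copy[ci] / config.ploidy)
        depth = reads * config.read_length / wsize
        starts = np.arange(n_win) * wsize
        depth_rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + wsize, "depth": depth,
        }))
        copy_rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + wsize, "copy": copy[ci],
        }))
    depth_df = pd.concat(depth_rows, ignore_index=True)
    truth.window_copy = pd.concat(copy_rows, ignore_index=True)

    loh_by_chrom: dict[int, list[tuple[int, int, float]]] = {}
    for chrom_idx, start, n, target in config.loh_specs:
        loh_by_chrom.setdefault(chrom_idx, []).append((start * wsize, (start + n) * wsize, target))

    var_rows = []
    truth_rows = []
    het_choices = np.array([0.25, 0.5, 0.75])
    alleles = np.array(list("ACGT"))
    chrom_len = n_win * wsize
    for ci, chrom in enumerate(chroms):
        positions = np.arange(config.variant_spacing, chrom_len, config.variant_spacing)
        for pos in positions:
            win = (pos - 1) // wsize
            true_freq = float(rng.choice(het_choices))
            in_loh = False
            for lo, hi, target in loh_by_chrom.get(ci, []):
                if lo <= pos - 1 < hi:
                    true_freq, in_loh = target, True
                    break
            p_alt = float(np.clip(true_freq, 0.005, 0.995))
            cov = int(rng.poisson(config.coverage * copy[ci, win] / config.ploidy))
            alt = int(rng.binomial(cov, p_alt)) if cov > 0 else 0
            ref, alt_base = rng.choice(alleles, size=2, replace=False)
            var_rows.append({
                "chrom": chrom, "pos": int(pos), "ref": str(ref), "alt": str(alt_base),
                "coverage": cov, "alt_count": alt,
            })
            truth_rows.append({
                "chrom": chrom, "pos": int(pos), "true_freq": true_freq, "loh": in_loh,
            })
    # mitochondrial variants (to be removed by the allele-frequency track)
    for pos in range(1000, 21000, 1000):
        cov = int(rng.poisson(config.coverage * 10))  # mito is high copy
        alt = int(rng.binomial(cov, 0.5))
        var_rows.append({"chrom": "chrM", "pos": pos, "ref": "A", "alt": "G",
                         "coverage": cov, "alt_count": alt})

    variants = pd.DataFrame(var_rows)
    truth.variant_truth = pd.DataFrame(truth_rows)
    return depth_df, variants, truth


# ----------------------------------------------------------------------
# annotations
# ----------------------------------------------------------------------

def generate_annotations(config: SimulationConfig, truth: GroundTruth) -> dict[str, pd.DataFrame]:
    """Annotation fixtures keyed by kind.

    Returns complexes, interactions (within-complex pairs), compartments
    (1-2 per protein; ~20% multi-localized), flat term sets (one per planted
    cluster plus random decoys) and random small pathways.
    """
    if truth.cluster_labels is None:
        raise IntegrityError("ground truth lacks cluster labels")
    rng = config._rng(3)
    ids = list(truth.cluster_labels.index)

    cpx_rows = [
        {"group_id": cid, "protein_id": pid, "group_type": "complex"}
        for cid, members in truth.complexes.items() for pid in members
    ]
    complexes = pd.DataFrame(cpx_rows, columns=["group_id", "protein_id", "group_type"])

    int_rows = [
        {"protein_a": a, "protein_b": b}
        for members in truth.complexes.values()
        for a, b in itertools.combinations(sorted(members), 2)
    ]
    interactions = pd.DataFrame(int_rows, columns=["protein_a", "protein_b"])

    comp_rows = []
    for pid in ids:
        primary = rng.integers(0, len(_COMPARTMENTS))
        comp_rows.append({"group_id": _COMPARTMENTS[primary], "protein_id": pid,
                          "group_type": "compartment"})
        if rng.random() < 0.2:
            second = (primary + 1 + rng.integers(0, len(_COMPARTMENTS) - 1)) % len(_COMPARTMENTS)
            comp_rows.append({"group_id": _COMPARTMENTS[second], "protein_id": pid,
                              "group_type": "compartment"})
    compartments = pd.DataFrame(comp_rows)

    term_rows = []
    for c in range(1, config.n_planted_clusters + 1):
        members = truth.cluster_labels.index[truth.cluster_labels == c]
        term_rows += [{"term_id": f"T_cluster{c:02d}", "protein_id": pid} for pid in members]
    for t in range(10):
        size = int(rng.integers(5, 31))
        members = rng.choice(ids, size=min(size, len(ids)), replace=False)
        term_rows += [{"term_id": f"T_random{t:02d}", "protein_id": pid} for pid in members]
    terms = pd.DataFrame(term_rows, columns=["term_id", "protein_id"])

    pw_rows = []
    for p in range(12):
        n_rxn = int(rng.integers(2, 6))
        for r in range(n_rxn):
            n_ent = int(rng.integers(1, 4))
            members = rng.choice(ids, size=n_ent, replace=False)
            pw_rows += [{"pathway_id": f"PWY{p + 1:03d}", "reaction_id": f"PWY{p + 1:03d}_R{r + 1}",
                         "protein_id": pid} for pid in members]
    pathways = pd.DataFrame(pw_rows, columns=["pathway_id", "reaction_id", "protein_id"])

    return {"complexes": complexes, "interactions": interactions,
            "compartments": compartments, "terms": terms, "pathways": pathways}


def planted_driver_pathways(
    driver_ids: Sequence[str],
    filler_ids: Sequence[str],
    background_ids: Sequence[str] | None = None,
    n_driver_pathways: int = 5,
    n_background_pathways: int = 10,
    fillers_per_reaction: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway table where a few shared enzymes drive the top scores.

    Each driver pathway contains one reaction holding one of the shared
    ``driver_ids`` (cycled) plus enzymes from ``filler_ids``, and one
    filler-only reaction; background pathways draw from ``background_ids``
    (defaults to the same filler pool). Supplying low-range fillers and
    moderate-range background enzymes makes the leave-drivers-out demotion
    structural rather than sampling luck.
    """
    rng = np.random.default_rng(seed)
    fillers = list(filler_ids)
    background = list(background_ids) if background_ids is not None else fillers
    rows = []
    for p in range(n_driver_pathways):
        pwy = f"DRV{p + 1:03d}"
        driver = driver_ids[p % len(driver_ids)]
        picks = rng.choice(fillers, size=fillers_per_reaction, replace=False)
        rows.append({"pathway_id": pwy, "reaction_id": f"{pwy}_R1", "protein_id": driver})
        rows += [{"pathway_id": pwy, "reaction_id": f"{pwy}_R1", "protein_id": f}
                 for f in picks]
        picks2 = rng.choice(fillers, size=fillers_per_reaction, replace=False)
        rows += [{"pathway_id": pwy, "reaction_id": f"{pwy}_R2", "protein_id": f}
                 for f in picks2]
    for p in range(n_background_pathways):
        pwy = f"BKG{p + 1:03d}"
        for r in range(2):
            picks = rng.choice(background, size=fillers_per_reaction, replace=False)
            rows += [{"pathway_id": pwy, "reaction_id": f"{pwy}_R{r + 1}", "protein_id": f}
                     for f in picks]
    return pd.DataFrame(rows, columns=["pathway_id", "reaction_id", "protein_id"])


# ----------------------------------------------------------------------
# direct log2 matrix simulation (for testing the DE stage in isolation)
# ----------------------------------------------------------------------

def simulate_two_group_log2(
    n_proteins: int,
    n_replicates: int,
    cv: float,
    n_planted: int = 0,
    log2fc: float = 0.0,
    seed: int = 0,
):
    """Two-condition log2-centred matrix with optional planted fold changes.

    Group A is (batch 1, 0 h), group B (batch 1, 6 h); the first
    ``n_planted`` proteins are shifted up in group B by ``log2fc`` log2
    units. Replicate noise is normal on the log2 scale with the standard
    deviation implied by a log-normal CV of ``cv``. Returns
    ``(AbundanceMatrix, planted_protein_index)``.
    """
    from .matrix import AbundanceMatrix  # local import to avoid cycle at import time

    rng = np.random.default_rng(seed)
    sd_log2 = float(np.sqrt(np.log1p(cv ** 2)) / np.log(2.0))
    ids = pd.Index([f"P{i + 1:04d}" for i in range(n_proteins)], name="protein_id")
    base = rng.normal(0.0, 1.0, n_proteins)

    cols, meta_rows = [], []
    for grp, hours in (("a", 0.0), ("b", 6.0)):
        for r in range(1, n_replicates + 1):
            sid = f"b1_t{hours:g}_r{r}"
            shift = np.zeros(n_proteins)
            if grp == "b" and n_planted:
                shift[:n_planted] = log2fc
            cols.append(pd.Series(base + shift + rng.normal(0.0, sd_log2, n_proteins),
                                  index=ids, name=sid))
            meta_rows.append({"sample_id": sid, "batch": 1, "hours": hours, "replicate": r})
    values = pd.concat(cols, axis=1)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = AbundanceMatrix(values=values, samples=samples, value_kind="log2-centred")
    return matrix, ids[:n_planted]
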