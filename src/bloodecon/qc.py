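"""Quality-control filters applied before basis construction or deconvolution.

The pipeline mirrors standard methylation-array practice: mask cells whose
detection p-value indicates the signal is indistinguishable from background
(cutoff 0.01), drop CpGs with >10% missing data, then drop samples with >1%
missing data (computed on the surviving CpGs), impute remaining missing
values by k-nearest-CpG averaging, and remove probes overlapping common
SNPs (caller-supplied exclusion list).  Batch correction and probe-chemistry
normalization are upstream concerns; this module consumes already-normalized
beta values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BetaMatrix

__all__ = [
    "QCParams",
    "mask_by_detection",
    "filter_missingness",
    "impute_knn",
    "remove_snp_probes",
]


@dataclass
class QCParams:
    """Thresholds for the QC pipeline.

    detection_p_cutoff : p-values at or above this mask the cell (0.01).
    max_cpg_missing_frac : CpGs with a strictly greater missing fraction
        are removed (0.10).
    max_sample_missing_frac : samples with a strictly greater missing
        fraction are removed (0.01).
    knn_k : number of nearest CpG rows averaged during imputation.
    snp_exclusion_ids : CpG IDs of probes overlapping SNPs (MAF > 0.01
        lists are built upstream).
    """

    detection_p_cutoff: float = 0.01
    max_cpg_missing_frac: float = 0.10
    max_sample_missing_frac: float = 0.01
    knn_k: int = 10
    snp_exclusion_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("detection_p_cutoff", "max_cpg_missing_frac", "max_sample_missing_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def mask_by_detection(
    betas: BetaMatrix, detection_p: BetaMatrix, cutoff: float = 0.01
) -> BetaMatrix:
    """Mask cells whose detection p-value is >= ``cutoff``.

    A cell is missing in the output iff it was already missing or its
    detection p-value fails the cutoff (the boundary value is masked, the
    conservative reading of "significant signal could not be detected").
    Never unmasks a cell.
    """
    if betas.cpg_ids != detection_p.cpg_ids or betas.sample_ids != detection_p.sample_ids:
        raise ValueError("beta matrix and detection p-values are not aligned")
    vals = betas.values.copy()
    fail = np.isfinite(detection_p.values) & (detection_p.values >= cutoff)
    # treat a missing p-value as undetected as well
    fail |= ~np.isfinite(detection_p.values)
    vals[fail] = np.nan
    return BetaMatrix(list(betas.cpg_ids), list(betas.sample_ids), vals)


def filter_missingness(
    betas: BetaMatrix,
    max_cpg_frac: float = 0.10,
    max_sample_frac: float = 0.01,
) -> tuple[BetaMatrix, dict[str, list[str]]]:
    """Remove high-missingness CpGs, then high-missingness samples.

    CpG rows with missing fraction strictly greater than ``max_cpg_frac``
    are removed first; sample columns are then assessed on the surviving
    CpGs against ``max_sample_frac`` (strict inequality in both cases).
    Returns the reduced matrix and a report of removed IDs.
    """
    miss = betas.missing_mask
    cpg_frac = miss.mean(axis=1)
    keep_cpg = cpg_frac <= max_cpg_frac
    removed_cpgs = [c for c, k in zip(betas.cpg_ids, keep_cpg) if not k]
    miss2 = miss[keep_cpg]
    if miss2.shape[0] == 0:
        raise ValueError(
            "no CpGs survive the missingness filter; review max_cpg_frac"
        )
    sample_frac = miss2.mean(axis=0)
    keep_sample = sample_frac <= max_sample_frac
    removed_samples = [s for s, k in zip(betas.sample_ids, keep_sample) if not k]
    if not keep_sample.any():
        raise ValueError(
            "no samples survive the missingness filter; review max_sample_frac"
        )
    out = BetaMatrix(
        [c for c, k in zip(betas.cpg_ids, keep_cpg) if k],
        [s for s, k in zip(betas.sample_ids, keep_sample) if k],
        betas.values[np.ix_(keep_cpg, keep_sample)],
    )
    return out, {"removed_cpgs": removed_cpgs, "removed_samples": removed_samples}


def impute_knn(betas: BetaMatrix, k: int = 10) -> BetaMatrix:
    """Fill missing cells from the k nearest CpG rows.

    The distance between two CpG rows is the root-mean-square difference
    over their shared observed samples (so rows observed on different
    subsets of samples remain comparable).  For each missing cell, the k
    nearest rows *observed at that sample* are averaged.  Non-missing
    cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    V = betas.values.copy()
    obs = np.isfinite(V)
    if obs.all():
        return betas.copy()
    empty_rows = ~obs.any(axis=1)
    if empty_rows.any():
        i = int(np.argmax(empty_rows))
        raise ValueError(
            f"CpG {betas.cpg_ids[i]!r} has no observed values; remove it first"
        )
    Vz = np.where(obs, V, 0.0)
    for i in np.where(~obs.all(axis=1))[0]:
        shared = obs & obs[i]
        diff = np.where(shared, Vz - Vz[i], 0.0)
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff * diff).sum(axis=1) / cnt)
        dist[i] = np.inf
        dist[cnt == 0] = np.inf
        for j in np.where(~obs[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(dist))[0]
            if cand.size == 0:
                raise ValueError(
                    f"no neighbour observed at sample {betas.sample_ids[j]!r} "
                    f"for CpG {betas.cpg_ids[i]!r}"
                )
            order = cand[np.argsort(dist[cand], kind="stable")][:k]
            V[i, j] = V[order, j].mean()
    return BetaMatrix(list(betas.cpg_ids), list(betas.sample_ids), V)


def remove_snp_probes(
    betas: BetaMatrix, exclusion_ids: set[str]
) -> BetaMatrix:
    """Drop CpG rows whose ID is in ``exclusion_ids``; order preserved."""
    keep = [c not in exclusion_ids for c in betas.cpg_ids]
    if not any(keep):
        warnings.warn("all CpGs removed by the SNP exclusion list")
    return BetaMatrix(
        [c for c, k in zip(betas.cpg_ids, keep) if k],
        list(betas.sample_ids),
        betas.values[np.asarray(keep, dtype=bool)],
    )


def read_snp_exclusion_list(path) -> set[str]:
    """One CpG ID per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
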