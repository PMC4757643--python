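"""In-silico mixture generation and a synthetic sorted-cell reference.

Two simulation modes mirror how reference-based deconvolution is
validated when no bulk samples with measured subtype counts exist:

* ``whole_blood`` — per sample, a proportion is drawn for every main cell
  type from a truncated normal (negatives clamped to 0) and the vector is
  renormalized to sum to 1; for parents with subtype groups, subtype
  proportions are drawn the same way and rescaled so they sum to the
  parent's simulated value.  A donor is drawn uniformly at random (with
  replacement) from each sorted data set and the mixture is the
  proportion-weighted linear combination of the donor columns, using
  subtype donors in place of the parent wherever subtype truth exists.
* ``sorted:<parent>`` — the same construction restricted to one parent's
  subtypes, with the subtype proportions rescaled to sum to 1; this
  emulates a sorted parent-cell sample of known subtype composition.

The module also provides a synthetic sorted-cell reference generator so
the whole toolkit is testable without array downloads: a bimodal baseline
profile, per-type private CpGs shifted toward the opposite methylation
mode, subtype profiles inheriting the parent plus smaller private shifts,
and truncated Gaussian per-sample noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BetaMatrix, CellTypeHierarchy, ProportionSet, default_hierarchy

__all__ = [
    "SimulationSpec",
    "SyntheticTruth",
    "SyntheticReference",
    "default_simulation_spec",
    "draw_main_proportions",
    "draw_subtype_proportions",
    "simulate_truth",
    "compose_mixture",
    "generate_synthetic_reference",
]

_MAX_REDRAWS = 100

# Normal-blood leukocyte composition: approximate reference ranges for
# healthy adults (fraction of leukocytes), with subtype means expressed on
# the absolute scale before renormalization.  These are the generator's
# own defaults, not values from any particular cohort.
_DEFAULT_MAIN: dict[str, tuple[float, float]] = {
    "Gran": (0.55, 0.10),
    "CD4": (0.15, 0.05),
    "CD8": (0.10, 0.04),
    "CD14": (0.08, 0.03),
    "NK": (0.07, 0.03),
    "CD19": (0.05, 0.02),
}
_DEFAULT_SUBTYPE: dict[str, tuple[float, float]] = {
    "Tnaive": (0.0675, 0.020),
    "Tmem": (0.0675, 0.020),
    "Treg": (0.0150, 0.005),
    "CD8naive": (0.0500, 0.015),
    "CD8mem": (0.0500, 0.015),
    "Bnaive": (0.0300, 0.010),
    "Bmem_switched": (0.0100, 0.004),
    "Bmem_unswitched": (0.0100, 0.004),
}


@dataclass
class SimulationSpec:
    """Proportion-draw parameters: per type/subtype (mean, sd) fractions.

    ``mode`` is ``"whole_blood"`` or ``"sorted:<parent>"``; in sorted
    mode only the parent's subtypes are mixed and their proportions sum
    to 1.
    """

    main_params: dict[str, tuple[float, float]]
    subtype_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_samples: int = 100
    seed: int = 0
    mode: str = "whole_blood"

    def __post_init__(self) -> None:
        for name, (mean, sd) in {**self.main_params, **self.subtype_params}.items():
            if mean < 0 or sd < 0:
                raise ValueError(f"negative mean or sd for {name!r}")
        if self.mode != "whole_blood" and not self.mode.startswith("sorted:"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    @property
    def sorted_parent(self) -> str | None:
        if self.mode.startswith("sorted:"):
            return self.mode.split(":", 1)[1]
        return None


def default_simulation_spec(
    n_samples: int = 100, seed: int = 0, mode: str = "whole_blood"
) -> SimulationSpec:
    return SimulationSpec(
        main_params=dict(_DEFAULT_MAIN),
        subtype_params=dict(_DEFAULT_SUBTYPE),
        n_samples=n_samples,
        seed=seed,
        mode=mode,
    )


@dataclass
class SyntheticTruth:
    """Known composition of a simulated data set.

    ``main`` rows sum to exactly 1; within ``subtypes`` each parent's
    block sums to the parent's value.  ``donor_assignments`` (sample ×
    type) records which sorted sample was mixed in, filled by
    :func:`compose_mixture`.
    """

    main: ProportionSet
    subtypes: ProportionSet | None = None
    donor_assignments: pd.DataFrame | None = None

    def merged_subtypes(self, hierarchy: CellTypeHierarchy) -> ProportionSet:
        """Subtype truth with report merges applied (e.g. Bmem)."""
        if self.subtypes is None:
            raise ValueError("no subtype truth simulated")
        frame = self.subtypes.to_frame()
        out = pd.DataFrame(index=frame.index)
        for parent in hierarchy.subtype_groups:
            for name in hierarchy.reported_subtypes(parent):
                members = [
                    m
                    for m in hierarchy.report_merges.get(name, [name])
                    if m in frame.columns
                ]
                if members:
                    out[name] = frame[members].sum(axis=1)
        return ProportionSet.from_frame(out, check_sum=False)


def _truncated_rows(
    rng: np.random.Generator, means: np.ndarray, sds: np.ndarray, n: int
) -> np.ndarray:
    draws = rng.normal(means, sds, size=(n, means.size))
    return np.where(draws < 0, 0.0, draws)


def draw_main_proportions(
    spec: SimulationSpec, rng: np.random.Generator
) -> ProportionSet:
    """Truncated-normal draws per main type, renormalized to sum to 1.

    A sample whose draws are all zero is redrawn (bounded retries)."""
    types = list(spec.main_params)
    means = np.array([spec.main_params[t][0] for t in types])
    sds = np.array([spec.main_params[t][1] for t in types])
    if not (means > 0).any():
        raise ValueError("at least one main type must have mean > 0")
    draws = _truncated_rows(rng, means, sds, spec.n_samples)
    for _ in range(_MAX_REDRAWS):
        zero = draws.sum(axis=1) == 0
        if not zero.any():
            break
        draws[zero] = _truncated_rows(rng, means, sds, int(zero.sum()))
    else:
        raise RuntimeError("could not draw a nonzero proportion vector")
    draws /= draws.sum(axis=1, keepdims=True)
    ids = [f"sim{j:04d}" for j in range(spec.n_samples)]
    return ProportionSet(ids, types, draws)


def draw_subtype_proportions(
    spec: SimulationSpec,
    main: ProportionSet,
    rng: np.random.Generator,
    hierarchy: CellTypeHierarchy | None = None,
) -> ProportionSet:
    """Per parent, truncated-normal subtype draws rescaled so the subtype
    block sums to the parent's simulated proportion."""
    hierarchy = hierarchy or default_hierarchy()
    main_frame = main.to_frame()
    blocks: list[pd.DataFrame] = []
    for parent, subs in hierarchy.subtype_groups.items():
        if parent not in main_frame.columns:
            raise ValueError(f"main proportions lack parent {parent!r}")
        missing = [s for s in subs if s not in spec.subtype_params]
        if missing:
            raise ValueError(f"spec lacks subtype parameters for {missing}")
        means = np.array([spec.subtype_params[s][0] for s in subs])
        sds = np.array([spec.subtype_params[s][1] for s in subs])
        parent_vals = main_frame[parent].to_numpy(dtype=float)
        draws = _truncated_rows(rng, means, sds, main_frame.shape[0])
        for _ in range(_MAX_REDRAWS):
            bad = (draws.sum(axis=1) == 0) & (parent_vals > 0)
            if not bad.any():
                break
            draws[bad] = _truncated_rows(rng, means, sds, int(bad.sum()))
        else:
            raise RuntimeError(f"could not draw subtype proportions for {parent!r}")
        totals = draws.sum(axis=1)
        scale = np.divide(
            parent_vals, totals, out=np.zeros_like(totals), where=totals > 0
        )
        blocks.append(
            pd.DataFrame(draws * scale[:, None], index=main_frame.index, columns=subs)
        )
    frame = pd.concat(blocks, axis=1)
    return ProportionSet.from_frame(frame, check_sum=False)


def simulate_truth(
    spec: SimulationSpec,
    rng: np.random.Generator,
    hierarchy: CellTypeHierarchy | None = None,
) -> SyntheticTruth:
    """Draw main and subtype truth for the spec's mode."""
    hierarchy = hierarchy or default_hierarchy()
    parent = spec.sorted_parent
    if parent is None:
        main = draw_main_proportions(spec, rng)
        subs = draw_subtype_proportions(spec, main, rng, hierarchy)
        return SyntheticTruth(main=main, subtypes=subs)
    if parent not in hierarchy.subtype_groups:
        raise ValueError(f"sorted mode parent {parent!r} has no subtype group")
    ids = [f"sim{j:04d}" for j in range(spec.n_samples)]
    types = list(spec.main_params)
    P = np.zeros((spec.n_samples, len(types)))
    P[:, types.index(parent)] = 1.0
    main = ProportionSet(ids, types, P)
    subs = draw_subtype_proportions(spec, main, rng, hierarchy)
    return SyntheticTruth(main=main, subtypes=subs)


def compose_mixture(
    truth: SyntheticTruth,
    sorted_samples: dict[str, BetaMatrix],
    rng: np.random.Generator,
    hierarchy: CellTypeHierarchy | None = None,
) -> BetaMatrix:
    """Weighted linear combination of randomly drawn donor columns.

    For parents with subtype truth, subtype donor columns are mixed with
    the subtype weights in place of the parent column.  Donors are drawn
    uniformly with replacement.  Output values are convex combinations of
    inputs and therefore stay inside [0, 1].  Fills
    ``truth.donor_assignments``.
    """
    hierarchy = hierarchy or default_hierarchy()
    main_frame = truth.main.to_frame()
    sub_frame = truth.subtypes.to_frame() if truth.subtypes is not None else None
    # mixing units: subtypes replace their parent when subtype truth exists
    units: list[str] = []
    for t in main_frame.columns:
        subs = hierarchy.subtype_groups.get(t, [])
        if sub_frame is not None and subs and all(s in sub_frame.columns for s in subs):
            units.extend(subs)
        else:
            units.append(t)
    weights = pd.DataFrame(index=main_frame.index, columns=units, dtype=float)
    for u in units:
        weights[u] = (
            sub_frame[u] if sub_frame is not None and u in sub_frame.columns else main_frame[u]
        )
    ref_cpgs = None
    for u in units:
        if weights[u].gt(0).any():
            if u not in sorted_samples:
                raise ValueError(f"no sorted samples for {u!r} with positive weight")
            if ref_cpgs is None:
                ref_cpgs = sorted_samples[u].cpg_ids
            elif sorted_samples[u].cpg_ids != ref_cpgs:
                raise ValueError(f"sorted samples of {u!r} are not CpG-aligned")
    if ref_cpgs is None:
        raise ValueError("all mixing weights are zero")
    n_samples = main_frame.shape[0]
    mix = np.zeros((len(ref_cpgs), n_samples))
    donors = pd.DataFrame(index=main_frame.index, columns=units, dtype=float)
    for u in units:
        if u not in sorted_samples:
            continue
        bm = sorted_samples[u]
        idx = rng.integers(0, bm.n_samples, size=n_samples)
        donors[u] = idx
        w = weights[u].to_numpy(dtype=float)
        mix += bm.values[:, idx] * w[None, :]
    truth.donor_assignments = donors
    mix = np.clip(mix, 0.0, 1.0)  # guard against float round-off at the edges
    return BetaMatrix(list(ref_cpgs), list(main_frame.index), mix)


# ----------------------------------------------------------------------
# Synthetic sorted-cell reference
# ----------------------------------------------------------------------

@dataclass
class SyntheticReference:
    """Synthetic stand-in for sorted-cell array data (no real cohort).

    ``samples`` maps every main type and subtype to its sorted beta
    matrix; ``profiles`` holds the noise-free type profiles; ``planted``
    records which CpGs were made differential for each type.
    """

    cpg_ids: list[str]
    samples: dict[str, BetaMatrix]
    profiles: dict[str, np.ndarray]
    planted: dict[str, list[str]]


def _shift_opposite(values: np.ndarray, shift: float) -> np.ndarray:
    """Move beta values toward the opposite methylation mode."""
    return np.clip(np.where(values < 0.5, values + shift, values - shift), 0.0, 1.0)


def generate_synthetic_reference(
    n_cpgs: int,
    hierarchy: CellTypeHierarchy | None = None,
    n_diff_per_type: int = 500,
    n_samples_per_type: int = 10,
    noise_sd: float = 0.02,
    seed: int = 0,
    main_shift: float = 0.8,
    subtype_shift: float = 0.4,
) -> SyntheticReference:
    """Generate sorted-cell beta matrices with planted differential CpGs.

    The baseline profile is bimodal (Beta(5, 45) / Beta(45, 5) mixture,
    modes near 0.1 and 0.9, as unmethylated/methylated CpGs present on
    arrays).  Each main type and each subtype receives
    ``n_diff_per_type`` private CpGs — interleaved across types so no
    type monopolizes low IDs — shifted toward the opposite mode by
    ``main_shift`` (typical top cell-type markers are near-fully
    switched) or ``subtype_shift`` (subtype differences are subtler).
    Subtypes inherit the parent profile, so parent-level markers carry no
    subtype signal and vice versa.  Per-sample Gaussian noise of sd
    ``noise_sd`` is added and clipped to [0, 1].  Fully deterministic
    given ``seed``.
    """
    hierarchy = hierarchy or default_hierarchy()
    all_types = list(hierarchy.main_types) + hierarchy.all_subtypes
    n_planted = n_diff_per_type * len(all_types)
    if n_planted > n_cpgs:
        raise ValueError(
            f"cannot plant {n_diff_per_type} CpGs for each of "
            f"{len(all_types)} types in {n_cpgs} CpGs"
        )
    rng = np.random.default_rng(seed)
    width = max(6, len(str(n_cpgs)))
    cpg_ids = [f"cg{i:0{width}d}" for i in range(n_cpgs)]
    high = rng.random(n_cpgs) < 0.5
    baseline = np.where(
        high, rng.beta(45.0, 5.0, n_cpgs), rng.beta(5.0, 45.0, n_cpgs)
    )
    # interleave private blocks: type k owns planted indices k, k+T, k+2T, ...
    planted_idx = {
        t: np.arange(k, n_planted, len(all_types))[:n_diff_per_type]
        for k, t in enumerate(all_types)
    }
    profiles: dict[str, np.ndarray] = {}
    for t in hierarchy.main_types:
        prof = baseline.copy()
        idx = planted_idx[t]
        prof[idx] = _shift_opposite(prof[idx], main_shift)
        profiles[t] = prof
    for parent, subs in hierarchy.subtype_groups.items():
        for s in subs:
            prof = profiles[parent].copy()
            idx = planted_idx[s]
            prof[idx] = _shift_opposite(prof[idx], subtype_shift)
            profiles[s] = prof
    samples: dict[str, BetaMatrix] = {}
    for t in all_types:
        noise = rng.normal(0.0, noise_sd, size=(n_cpgs, n_samples_per_type))
        vals = np.clip(profiles[t][:, None] + noise, 0.0, 1.0)
        ids = [f"{t}_s{j:02d}" for j in range(n_samples_per_type)]
        samples[t] = BetaMatrix(cpg_ids, ids, vals)
    planted = {t: [cpg_ids[i] for i in planted_idx[t]] for t in all_types}
    return SyntheticReference(
        cpg_ids=cpg_ids, samples=samples, profiles=profiles, planted=planted
    )
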