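"""Constrained least-squares deconvolution and the two-stage refinement.

Stage 1 regresses a bulk beta-value profile B on the median profiles of
the six main leukocyte types,

    B = p_CD4 X_CD4 + p_CD8 X_CD8 + p_CD14 X_CD14
        + p_CD19 X_CD19 + p_Gran X_Gran + p_NK X_NK + e,

with no intercept and the coefficients constrained to be nonnegative and
sum to at most 1.  Stage 2 refines hard-to-separate populations: the
fitted contributions of all other types are subtracted from B (the
"partitioned" profile), a reduced model over the types of interest is
refit on a panel of CpGs chosen for those types only, and the refined
coefficients are rescaled so their sum equals the corresponding stage-1
sum — refinement therefore never alters the estimates of types outside
the reduced model.  The same partition/refit/rescale step estimates the
nested CD4, CD8 and B-cell subtypes, whose estimates sum exactly to the
parent's (refined) estimate.

The constrained solve is a small convex quadratic program.  It is solved
exactly: plain nonnegative least squares when the sum constraint is slack
at the optimum, otherwise an exhaustive active-set enumeration of the
equality-constrained KKT systems (the number of cell types is at most a
handful, so enumeration is cheap and immune to cycling).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core import BetaMatrix, CellTypeHierarchy, ProportionSet, ReferenceBasis
from .features import CpGPanel, anova_rank, assemble_panel, pairwise_unique_top_n

__all__ = [
    "FitResult",
    "DeconvolutionResult",
    "constrained_ls",
    "estimate_main",
    "partition_profile",
    "refine_pair",
    "estimate_subtypes",
    "deconvolute_full",
    "build_model",
]

_SUM_TOL = 1e-9
_NEG_TOL = 1e-10


@dataclass
class FitResult:
    """Proportions plus per-sample residual sum of squares for one stage."""

    proportions: ProportionSet
    residual_norm: pd.Series
    panel_used: CpGPanel
    stage: str

    def __post_init__(self) -> None:
        if (self.residual_norm < 0).any():
            raise ValueError("negative residual norm")


@dataclass
class DeconvolutionResult:
    """Combined main + subtype report and the per-stage fits."""

    table: ProportionSet
    fits: dict[str, FitResult]


# ----------------------------------------------------------------------
# The constrained solver
# ----------------------------------------------------------------------

def _equality_qp(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """argmin ||y - Xp||^2 s.t. p >= 0, sum(p) = 1, by enumerating the
    active set of the nonnegativity constraints.

    For the optimum p*, the KKT system restricted to its support
    reproduces p*, so the best sign-feasible candidate over all supports
    is exact.  Rank-deficient KKT systems are solved by least squares,
    yielding a minimum-norm representative among the optima.
    """
    d = X.shape[1]
    best_p, best_obj, best_norm = None, np.inf, np.inf
    cols = list(range(d))
    for size in range(1, d + 1):
        for free in itertools.combinations(cols, size):
            G = X[:, free]
            gram = G.T @ G
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = 2.0 * gram
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.concatenate([2.0 * (G.T @ y), [1.0]])
            sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
            pf = sol[:size]
            if (pf < -_NEG_TOL).any() or abs(pf.sum() - 1.0) > 1e-8:
                continue
            r = y - G @ pf
            obj = float(r @ r)
            norm = float(pf @ pf)
            if obj < best_obj - 1e-12 or (
                obj <= best_obj + 1e-12 and norm < best_norm
            ):
                p = np.zeros(d)
                p[list(free)] = pf
                best_p, best_obj, best_norm = p, obj, norm
    if best_p is None:  # pragma: no cover - defensive
        raise RuntimeError("no feasible active set found")
    return best_p


def _kkt_check(X: np.ndarray, y: np.ndarray, p: np.ndarray, tol: float = 1e-6) -> None:
    g = 2.0 * (X.T @ (X @ p - y))
    scale = max(1.0, float(np.abs(g).max(initial=0.0)))
    free = p > 1e-9
    lam = 0.0
    if p.sum() > 1.0 - 1e-9 and free.any():
        lam = float(-g[free].mean())
        lam = max(lam, 0.0)
    ok = True
    if free.any() and np.abs(g[free] + lam).max() > tol * scale:
        ok = False
    if (~free).any() and (g[~free] + lam < -tol * scale).any():
        ok = False
    if not ok:
        warnings.warn("constrained_ls: KKT conditions not met to tolerance")


def constrained_ls(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """argmin ||y - Xp||^2 subject to p >= 0 and sum(p) <= 1.

    Rows where ``y`` is missing are dropped from both ``y`` and ``X``
    before solving; ``X`` itself must be complete.  Requires at least
    one more usable row than columns.  Rank-deficient designs emit a
    warning and return a minimum-norm solution among the optima.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    if not np.isfinite(X).all():
        raise ValueError("basis matrix X contains missing values")
    keep = np.isfinite(y)
    y2, X2 = y[keep], X[keep]
    d = X.shape[1]
    if y2.size < d + 1:
        raise ValueError(
            f"only {y2.size} usable rows for {d} cell types; need >= {d + 1}"
        )
    if np.linalg.matrix_rank(X2) < d:
        warnings.warn("rank-deficient basis; returning a minimum-norm optimum")
    p, _ = nnls(X2, y2)
    if p.sum() > 1.0 + _SUM_TOL:
        p = _equality_qp(X2, y2)
    _kkt_check(X2, y2, p)
    p = np.where(p < 0, 0.0, p)
    return p


# ----------------------------------------------------------------------
# Stage 1
# ----------------------------------------------------------------------

def _restrict(
    mixtures: BetaMatrix, basis: ReferenceBasis, panel: CpGPanel
) -> tuple[np.ndarray, np.ndarray]:
    missing_b = [c for c in panel.cpg_ids if c not in set(basis.cpg_ids)]
    missing_m = [c for c in panel.cpg_ids if c not in set(mixtures.cpg_ids)]
    if missing_b or missing_m:
        raise ValueError(
            f"panel CpGs absent from basis ({missing_b[:5]}) "
            f"or mixtures ({missing_m[:5]})"
        )
    Xb = basis.select_cpgs(panel.cpg_ids).profiles
    Y = mixtures.select_cpgs(panel.cpg_ids).values
    return Y, Xb


def estimate_main(
    mixtures: BetaMatrix, basis: ReferenceBasis, panel: CpGPanel
) -> FitResult:
    """Per-sample constrained least squares over the panel CpGs."""
    Y, Xb = _restrict(mixtures, basis, panel)
    n_samples = mixtures.n_samples
    P = np.zeros((n_samples, len(basis.cell_types)))
    rss = np.zeros(n_samples)
    for j in range(n_samples):
        p = constrained_ls(Y[:, j], Xb)
        P[j] = p
        keep = np.isfinite(Y[:, j])
        r = Y[keep, j] - Xb[keep] @ p
        rss[j] = float(r @ r)
    props = ProportionSet(list(mixtures.sample_ids), list(basis.cell_types), P)
    return FitResult(
        proportions=props,
        residual_norm=pd.Series(rss, index=list(mixtures.sample_ids)),
        panel_used=panel,
        stage="main",
    )


# ----------------------------------------------------------------------
# Partition (Stage 2 outcome construction)
# ----------------------------------------------------------------------

def partition_profile(
    mixtures: BetaMatrix,
    basis: ReferenceBasis,
    main_fit: FitResult,
    keep: set[str],
    cpg_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Subtract the fitted contributions of every type not in ``keep``.

    Returns a CpG × sample DataFrame over ``cpg_ids`` (default: the full
    basis universe).  Values are deliberately *not* clipped to [0, 1]:
    the downstream refit is plain least squares on this residual profile
    and clipping would bias its coefficients.
    """
    keep = set(keep)
    types = list(basis.cell_types)
    if not keep or keep >= set(types):
        raise ValueError("keep must be a non-empty strict subset of basis types")
    unknown = keep - set(types)
    if unknown:
        raise ValueError(f"unknown cell types in keep: {sorted(unknown)}")
    excluded = [t for t in types if t not in keep]
    fitted = main_fit.proportions.to_frame()
    absent = [t for t in excluded if t not in fitted.columns]
    if absent:
        raise ValueError(f"main fit lacks estimates for excluded types: {absent}")
    cpgs = list(basis.cpg_ids) if cpg_ids is None else list(cpg_ids)
    Xe = basis.select_cpgs(cpgs).select_types(excluded).profiles
    Y = mixtures.select_cpgs(cpgs).values
    Pe = fitted.loc[list(mixtures.sample_ids), excluded].to_numpy(dtype=float)
    out = Y - Xe @ Pe.T
    return pd.DataFrame(out, index=cpgs, columns=list(mixtures.sample_ids))


# ----------------------------------------------------------------------
# Stage 2: pair refinement and subtype estimation
# ----------------------------------------------------------------------

def _refit_and_rescale(
    partitioned: pd.DataFrame,
    sub_basis: ReferenceBasis,
    targets: np.ndarray,
    fallback: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained refit on a partitioned profile, rescaled per sample so
    the coefficients sum to ``targets``; rows of ``fallback`` are used
    where the refit returns an all-zero solution."""
    X = sub_basis.profiles
    n_samples = partitioned.shape[1]
    d = len(sub_basis.cell_types)
    out = np.zeros((n_samples, d))
    rss = np.zeros(n_samples)
    vals = partitioned.to_numpy(dtype=float)
    for j in range(n_samples):
        q = constrained_ls(vals[:, j], X)
        total = q.sum()
        if total > 0:
            out[j] = q * (targets[j] / total)
        else:
            warnings.warn(
                "second-stage fit is identically zero; falling back to "
                "stage-1 estimates"
            )
            out[j] = fallback[j]
        keep = np.isfinite(vals[:, j])
        r = vals[keep, j] - X[keep] @ q
        rss[j] = float(r @ r)
    return out, rss


def refine_pair(
    mixtures: BetaMatrix,
    main_basis: ReferenceBasis,
    pair_basis: ReferenceBasis,
    main_fit: FitResult,
    pair_panel: CpGPanel,
) -> FitResult:
    """Refine two similar types on their own panel, conserving their sum.

    The partitioned profile (bulk minus fitted contributions of the other
    types) is refit on the two-type basis over ``pair_panel``, and both
    coefficients are multiplied by a common factor so their sum equals
    the stage-1 sum for the pair.  If the refit is identically zero, the
    stage-1 estimates are retained.  Other types are untouched.
    """
    pair = list(pair_basis.cell_types)
    if len(pair) != 2:
        raise ValueError("pair basis must have exactly two cell types")
    part = partition_profile(
        mixtures, main_basis, main_fit, keep=set(pair), cpg_ids=pair_panel.cpg_ids
    )
    fitted = main_fit.proportions.to_frame()
    targets = fitted[pair].sum(axis=1).to_numpy(dtype=float)
    fallback = fitted[pair].to_numpy(dtype=float)
    refined, rss = _refit_and_rescale(
        part, pair_basis.select_cpgs(pair_panel.cpg_ids), targets, fallback
    )
    new = fitted.copy()
    new[pair] = refined
    props = ProportionSet.from_frame(new)
    return FitResult(
        proportions=props,
        residual_norm=pd.Series(rss, index=list(mixtures.sample_ids)),
        panel_used=pair_panel,
        stage=f"pair:{pair[0]}-{pair[1]}",
    )


def estimate_subtypes(
    mixtures: BetaMatrix,
    main_basis: ReferenceBasis,
    subtype_basis: ReferenceBasis,
    main_fit: FitResult,
    subtype_panel: CpGPanel,
    parent: str,
    hierarchy: CellTypeHierarchy | None = None,
) -> FitResult:
    """Estimate one parent's subtype proportions from the partitioned
    parent profile; subtype estimates sum exactly to the parent estimate.

    ``main_fit`` should be the pair-refined fit where available.  If the
    refit is identically zero while the parent mass is positive, the mass
    is split uniformly across subtypes.  When ``hierarchy`` defines
    report merges for this parent (e.g. switched + unswitched memory B
    cells -> ``Bmem``) the merged columns are summed in the output.
    """
    if parent not in main_basis.cell_types:
        raise ValueError(f"unknown parent cell type {parent!r}")
    subs = list(subtype_basis.cell_types)
    part = partition_profile(
        mixtures, main_basis, main_fit, keep={parent}, cpg_ids=subtype_panel.cpg_ids
    )
    fitted = main_fit.proportions.to_frame()
    targets = fitted[parent].to_numpy(dtype=float)
    uniform = np.tile(targets[:, None] / len(subs), (1, len(subs)))
    refined, rss = _refit_and_rescale(
        part, subtype_basis.select_cpgs(subtype_panel.cpg_ids), targets, uniform
    )
    frame = pd.DataFrame(refined, index=list(mixtures.sample_ids), columns=subs)
    if hierarchy is not None and parent in hierarchy.subtype_groups:
        reported = hierarchy.reported_subtypes(parent)
        out = pd.DataFrame(index=frame.index)
        for name in reported:
            members = hierarchy.report_merges.get(name, [name])
            out[name] = frame[list(members)].sum(axis=1)
        frame = out
    props = ProportionSet.from_frame(frame)
    return FitResult(
        proportions=props,
        residual_norm=pd.Series(rss, index=list(mixtures.sample_ids)),
        panel_used=subtype_panel,
        stage=f"subtype:{parent}",
    )


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

def deconvolute_full(
    mixtures: BetaMatrix,
    bases: dict[str, ReferenceBasis],
    panels: dict[str, CpGPanel],
    hierarchy: CellTypeHierarchy,
) -> DeconvolutionResult:
    """Main fit, CD4/CD8 pair refinement, then all subtype models.

    ``bases`` and ``panels`` are keyed ``"main"``, ``"pair:<A>-<B>"`` and
    ``"subtype:<parent>"``; pair and subtype entries are optional and run
    only when both the basis and the panel are present.  The combined
    table holds the (refined) main-type columns followed by reported
    subtype columns; each parent's subtypes sum to its estimate.
    """
    fits: dict[str, FitResult] = {}
    main_basis = bases["main"]
    fit = estimate_main(mixtures, main_basis, panels["main"])
    fits["main"] = fit
    for key in sorted(k for k in bases if k.startswith("pair:")):
        if key not in panels:
            continue
        fit = refine_pair(mixtures, main_basis, bases[key], fit, panels[key])
        fits[key] = fit
    table = fit.proportions.to_frame()
    for parent in hierarchy.subtype_groups:
        key = f"subtype:{parent}"
        if key not in bases or key not in panels:
            continue
        sub_fit = estimate_subtypes(
            mixtures, main_basis, bases[key], fit, panels[key], parent, hierarchy
        )
        fits[key] = sub_fit
        table = table.join(sub_fit.proportions.to_frame())
    combined = ProportionSet.from_frame(table, check_sum=False)
    return DeconvolutionResult(table=combined, fits=fits)


def build_model(
    reference_samples: dict[str, BetaMatrix],
    hierarchy: CellTypeHierarchy,
    m: int = 300,
    n: int = 50,
    pair_n: int = 300,
    subtype_m: int = 300,
    subtype_n: int = 50,
    two_subtype_n: int = 300,
    refine_pairs: tuple[tuple[str, str], ...] = (("CD4", "CD8"),),
) -> tuple[dict[str, ReferenceBasis], dict[str, CpGPanel]]:
    """Build all bases and panels from sorted-cell reference samples.

    ``reference_samples`` maps every main type and every subtype to its
    sorted-sample beta matrix (all sharing one CpG ordering).  Panel sizes
    default to the package's standard values; callers calibrating against
    measured compositions should use :func:`features.optimize_panel_sizes`
    and :func:`features.two_type_panel` instead and pass the results in.

    Pair refinement of monocytes/granulocytes is not built by default:
    refitting that pair does not improve on the stage-1 estimates.
    """
    from .core import build_reference_basis

    main_samples = {t: reference_samples[t] for t in hierarchy.main_types}
    main_basis, _ = build_reference_basis(main_samples)
    bases: dict[str, ReferenceBasis] = {"main": main_basis}
    panels: dict[str, CpGPanel] = {
        "main": assemble_panel(
            anova_rank(main_samples), pairwise_unique_top_n(main_samples, n), m, n
        )
    }
    for a, b in refine_pairs:
        key = f"pair:{a}-{b}"
        pair_samples = {a: reference_samples[a], b: reference_samples[b]}
        lists = pairwise_unique_top_n(pair_samples, pair_n)
        panels[key] = assemble_panel([], lists, 0, pair_n)
        bases[key] = main_basis.select_types([a, b])
    for parent, subs in hierarchy.subtype_groups.items():
        key = f"subtype:{parent}"
        sub_samples = {s: reference_samples[s] for s in subs}
        sub_basis, _ = build_reference_basis(sub_samples)
        bases[key] = sub_basis
        if len(subs) == 2:
            lists = pairwise_unique_top_n(sub_samples, two_subtype_n)
            panels[key] = assemble_panel([], lists, 0, two_subtype_n)
        else:
            panels[key] = assemble_panel(
                anova_rank(sub_samples),
                pairwise_unique_top_n(sub_samples, subtype_n),
                subtype_m,
                subtype_n,
            )
    return bases, panels
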