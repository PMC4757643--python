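"""Selection of discriminating CpG panels for the mixture regressions.

A deconvolution panel is the union of two sub-lists computed on the
sorted-cell reference samples:

* an ANOVA sub-list — the top ``m`` CpGs ranked by one-way ANOVA p-value
  across all cell types (the overall discriminators), and
* a pairwise sub-list — for every unordered pair of cell types, the top
  ``n`` CpGs by Welch t-test p-value, kept only if they do not appear in
  any other pair's top-``n`` list (pair-specific discriminators).

The sub-list sizes ``(m, n)`` are chosen by minimizing the calibration
error (``bloodecon.evaluation.error_function``) of deconvolution on
samples of known composition, via deterministic alternating coordinate
descent over user-supplied grids.  Two-type models (the CD4/CD8 second
stage, two-subtype models) have a single size ``n`` and use a plain scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, ProportionSet, ReferenceBasis

__all__ = [
    "CpGPanel",
    "PanelSearchResult",
    "anova_rank",
    "pairwise_unique_top_n",
    "assemble_panel",
    "optimize_panel_sizes",
    "two_type_panel",
]


@dataclass
class CpGPanel:
    """Ordered selected CpGs with per-CpG provenance and the sizes used.

    ``provenance[i]`` is ``"anova"`` or ``"pair:<A>-<B>"``; a CpG selected
    by both routes keeps the ``"anova"`` tag.
    """

    cpg_ids: list[str]
    provenance: list[str]
    m: int
    n: int

    def __post_init__(self) -> None:
        if len(self.cpg_ids) != len(self.provenance):
            raise ValueError("cpg_ids and provenance differ in length")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValueError("panel contains duplicate CpGs")
        n_anova = sum(p == "anova" for p in self.provenance)
        if n_anova > self.m:
            raise ValueError("more anova-tagged CpGs than m")
        counts: dict[str, int] = {}
        for p in self.provenance:
            if p != "anova":
                counts[p] = counts.get(p, 0) + 1
        if any(c > self.n for c in counts.values()):
            raise ValueError("a pair sub-list exceeds n")

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cpg_id": self.cpg_ids, "provenance": self.provenance})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CpGPanel":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        prov = list(frame["provenance"])
        m = sum(p == "anova" for p in prov)
        counts: dict[str, int] = {}
        for p in prov:
            if p != "anova":
                counts[p] = counts.get(p, 0) + 1
        return cls(list(frame["cpg_id"]), prov, m, max(counts.values(), default=0))


@dataclass
class PanelSearchResult:
    """Outcome of a panel-size search."""

    best_m: int
    best_n: int
    error_trace: list[tuple[int, int, float]]
    panel: CpGPanel

    def __post_init__(self) -> None:
        errs = [e for _, _, e in self.error_trace if np.isfinite(e)]
        best = [
            e for m, n, e in self.error_trace if m == self.best_m and n == self.best_n
        ]
        if errs and best and min(best) > min(errs) + 1e-12:
            raise ValueError("best (m, n) is not the minimum of the trace")

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.error_trace, columns=["m", "n", "error"])


# ----------------------------------------------------------------------
# Rankings
# ----------------------------------------------------------------------

def _group_arrays(
    reference_samples: dict[str, BetaMatrix], min_samples: int = 2
) -> tuple[list[str], list[str], list[np.ndarray], np.ndarray]:
    """Align groups, enforce sample counts, and build the complete-case mask."""
    if len(reference_samples) < 2:
        raise ValueError("need at least two cell types")
    types = list(reference_samples)
    cpgs = reference_samples[types[0]].cpg_ids
    groups = []
    for t in types:
        bm = reference_samples[t]
        if bm.cpg_ids != cpgs:
            raise ValueError(f"cpg_ids of {t!r} not aligned with {types[0]!r}")
        if bm.n_samples < min_samples:
            raise ValueError(f"cell type {t!r} has fewer than {min_samples} samples")
        groups.append(bm.values)
    complete = np.ones(len(cpgs), dtype=bool)
    for g in groups:
        complete &= np.isfinite(g).all(axis=1)
    return types, cpgs, groups, complete


def _rank_frame(cpgs, pvals, stat) -> pd.DataFrame:
    frame = pd.DataFrame({"cpg_id": cpgs, "p_value": pvals, "statistic": stat})
    frame = frame.sort_values(
        ["p_value", "cpg_id"], ascending=[True, True], kind="mergesort"
    )
    return frame.reset_index(drop=True)


def anova_rank(reference_samples: dict[str, BetaMatrix]) -> pd.DataFrame:
    """Rank CpGs by one-way ANOVA p-value across cell-type groups.

    CpGs with any missing reference value are excluded (complete-case).
    A CpG with zero variance everywhere and equal group means is assigned
    p = 1 (no signal); zero within-group variance with differing means is
    maximally significant (p = 0).  Ties are broken by CpG ID.
    """
    types, cpgs, groups, complete = _group_arrays(reference_samples)
    groups = [g[complete] for g in groups]
    cpgs_cc = [c for c, k in zip(cpgs, complete) if k]
    ns = np.array([g.shape[1] for g in groups], dtype=float)
    N, G = ns.sum(), len(groups)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = (means * ns).sum(axis=1) / N
    ssb = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ssw = np.zeros(len(cpgs_cc))
    for g, mean_g in zip(groups, means.T):
        ssw += ((g - mean_g[:, None]) ** 2).sum(axis=1)
    dfb, dfw = G - 1, N - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(F, dfb, dfw)
    # zero within-group variance: significant iff the group means truly
    # differ (spread compared with a tolerance, not ssb, which picks up
    # float round-off of the grand mean)
    degenerate = ssw == 0.0
    spread = means.max(axis=1) - means.min(axis=1)
    differ = spread > 1e-9
    p[degenerate & differ] = 0.0
    F[degenerate & differ] = np.inf
    p[degenerate & ~differ] = 1.0
    F[degenerate & ~differ] = 0.0
    return _rank_frame(cpgs_cc, p, F)


def _welch_rank(a: np.ndarray, b: np.ndarray, cpgs: list[str]) -> pd.DataFrame:
    """Vectorized Welch two-sample t-test ranking over CpG rows."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    diff = np.abs(m1 - m2) > 1e-9
    p[degenerate & diff] = 0.0
    t[degenerate & diff] = np.inf
    p[degenerate & ~diff] = 1.0
    t[degenerate & ~diff] = 0.0
    return _rank_frame(cpgs, p, np.abs(t))


def pair_key(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}-{b}"


def _pairwise_rankings(
    reference_samples: dict[str, BetaMatrix],
) -> dict[str, pd.DataFrame]:
    types, cpgs, groups, complete = _group_arrays(reference_samples)
    cpgs_cc = [c for c, k in zip(cpgs, complete) if k]
    arrays = {t: g[complete] for t, g in zip(types, groups)}
    out = {}
    for a, b in itertools.combinations(types, 2):
        out[pair_key(a, b)] = _welch_rank(arrays[a], arrays[b], cpgs_cc)
    return out


def _unique_top_n(
    rankings: dict[str, pd.DataFrame], n: int
) -> dict[str, list[str]]:
    tops = {k: list(r["cpg_id"].iloc[:n]) for k, r in rankings.items()}
    owner_count: dict[str, int] = {}
    for ids in tops.values():
        for c in ids:
            owner_count[c] = owner_count.get(c, 0) + 1
    unique = {
        k: [c for c in ids if owner_count[c] == 1] for k, ids in tops.items()
    }
    # disjointness holds by construction; assert defensively
    seen: set[str] = set()
    for ids in unique.values():
        assert not (seen & set(ids)), "pair sub-lists are not disjoint"
        seen |= set(ids)
    return unique


def pairwise_unique_top_n(
    reference_samples: dict[str, BetaMatrix], n: int
) -> dict[str, list[str]]:
    """Per type pair, its top-``n`` t-test CpGs absent from every other
    pair's top-``n`` list.  With a single pair the list is unfiltered.
    Result lists may be shorter than ``n``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return _unique_top_n(_pairwise_rankings(reference_samples), n)


# ----------------------------------------------------------------------
# Panel assembly and size search
# ----------------------------------------------------------------------

def assemble_panel(
    anova_list, pair_lists: dict[str, list[str]], m: int, n: int
) -> CpGPanel:
    """Union of the top-``m`` ANOVA CpGs and the unique pair sub-lists.

    ``anova_list`` is a ranked sequence of CpG IDs (or the frame returned
    by :func:`anova_rank`); ``pair_lists`` is the output of
    :func:`pairwise_unique_top_n` at size ``n``.  Ordering is the ANOVA
    block followed by pair blocks in sorted pair-name order; duplicates
    keep the ``"anova"`` provenance.
    """
    if m < 0 or n < 0:
        raise ValueError("m and n must be >= 0")
    if isinstance(anova_list, pd.DataFrame):
        anova_list = list(anova_list["cpg_id"])
    ids: list[str] = []
    prov: list[str] = []
    taken: set[str] = set()
    for c in list(anova_list)[:m]:
        if c not in taken:
            ids.append(c)
            prov.append("anova")
            taken.add(c)
    for key in sorted(pair_lists):
        for c in pair_lists[key][:n]:
            if c not in taken:
                ids.append(c)
                prov.append(f"pair:{key}")
                taken.add(c)
    return CpGPanel(ids, prov, m=m, n=n)


def _evaluate_panel(
    panel: CpGPanel,
    basis: ReferenceBasis,
    mixtures: BetaMatrix,
    measured: ProportionSet,
) -> float:
    from . import decon
    from .evaluation import error_function

    if len(panel) < len(basis.cell_types) + 1:
        return float("inf")
    fit = decon.estimate_main(mixtures, basis, panel)
    return error_function(fit.proportions, measured)


def optimize_panel_sizes(
    reference_basis: ReferenceBasis,
    reference_samples: dict[str, BetaMatrix],
    calibration: tuple[BetaMatrix, ProportionSet],
    m_grid,
    n_grid,
    max_rounds: int = 20,
) -> PanelSearchResult:
    """Choose (m, n) minimizing the calibration error by alternating
    coordinate descent over the two grids.

    With ``n`` fixed, every ``m`` in ``m_grid`` is scanned and the first
    minimizer kept (ties break toward the earlier, i.e. smaller, grid
    point); then ``m`` is fixed and ``n_grid`` scanned; the alternation
    stops when (m, n) is unchanged or after ``max_rounds`` rounds.
    Deterministic given grids and data.
    """
    m_grid = [int(m) for m in m_grid]
    n_grid = [int(n) for n in n_grid]
    if not m_grid or not n_grid:
        raise ValueError("grids must be non-empty")
    if any(m < 0 for m in m_grid) or any(n < 0 for n in n_grid):
        raise ValueError("grid values must be >= 0")
    mixtures, measured = calibration
    anova = anova_rank(reference_samples)
    rankings = _pairwise_rankings(reference_samples)
    cache: dict[tuple[int, int], float] = {}
    trace: list[tuple[int, int, float]] = []

    def evaluate(m: int, n: int) -> float:
        if (m, n) not in cache:
            panel = assemble_panel(anova, _unique_top_n(rankings, n), m, n)
            err = _evaluate_panel(panel, reference_basis, mixtures, measured)
            cache[(m, n)] = err
            trace.append((m, n, err))
        return cache[(m, n)]

    m, n = m_grid[0], n_grid[0]
    for _ in range(max_rounds):
        errs_m = [evaluate(mm, n) for mm in m_grid]
        new_m = m_grid[int(np.argmin(errs_m))]
        errs_n = [evaluate(new_m, nn) for nn in n_grid]
        new_n = n_grid[int(np.argmin(errs_n))]
        if (new_m, new_n) == (m, n):
            break
        m, n = new_m, new_n
    if not np.isfinite(cache[(m, n)]):
        raise ValueError("calibration error is non-finite for all grid points")
    panel = assemble_panel(anova, _unique_top_n(rankings, n), m, n)
    return PanelSearchResult(best_m=m, best_n=n, error_trace=trace, panel=panel)


def two_type_panel(
    reference_samples: dict[str, BetaMatrix],
    calibration: tuple[BetaMatrix, ProportionSet],
    n_grid,
) -> PanelSearchResult:
    """One-dimensional panel-size scan for a two-type model.

    With only two cell types the ANOVA sub-list is redundant and there is
    a single pairwise ranking, so ``m`` is fixed at 0 and the error is
    scanned over ``n_grid`` (ties break toward the smaller ``n``).
    """
    from .core import build_reference_basis

    if len(reference_samples) != 2:
        raise ValueError("two_type_panel requires exactly two cell types")
    n_grid = [int(n) for n in n_grid]
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    mixtures, measured = calibration
    basis, _ = build_reference_basis(reference_samples)
    rankings = _pairwise_rankings(reference_samples)
    trace: list[tuple[int, int, float]] = []
    best_n, best_err = None, np.inf
    for n in n_grid:
        panel = assemble_panel([], _unique_top_n(rankings, n), 0, n)
        err = _evaluate_panel(panel, basis, mixtures, measured)
        trace.append((0, n, err))
        if err < best_err:
            best_n, best_err = n, err
    if best_n is None or not np.isfinite(best_err):
        raise ValueError("calibration error is non-finite for all grid points")
    panel = assemble_panel([], _unique_top_n(rankings, best_n), 0, best_n)
    return PanelSearchResult(best_m=0, best_n=best_n, error_trace=trace, panel=panel)
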