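"""Core containers and I/O for methylation deconvolution.

The central objects are:

* :class:`BetaMatrix` — a CpG × sample matrix of methylation beta values
  (proportion methylated, in ``[0, 1]``) with an explicit missing marker
  (NaN internally, ``"NA"`` or empty string on disk).
* :class:`CellTypeHierarchy` — the six main leukocyte types and the nested
  T/B-cell subtype groups, plus the merge rule used for reporting
  (switched + unswitched memory B cells are reported as one "Bmem").
* :class:`ReferenceBasis` — per-cell-type median beta profiles used as the
  regressor columns of the mixture model.
* :class:`ProportionSet` — per-sample nonnegative mixing proportions.

All on-disk formats are plain tab-delimited text; beta matrices carry CpG
IDs in the first column (header ``cpg_id``) and sample IDs in the header
row, proportion tables carry sample IDs in the first column
(header ``sample_id``).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "CellTypeHierarchy",
    "ReferenceBasis",
    "ProportionSet",
    "read_beta_matrix",
    "write_beta_matrix",
    "build_reference_basis",
    "default_hierarchy",
    "read_proportions",
    "write_proportions",
]


def _find_duplicate(ids) -> str | None:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class BetaMatrix:
    """CpG × sample matrix of beta values; missing cells are NaN."""

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.cpg_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.cpg_ids)} CpGs, {len(self.sample_ids)} samples)"
            )
        for name, ids in (("cpg_id", self.cpg_ids), ("sample_id", self.sample_ids)):
            dup = _find_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} {dup!r}")
        finite = np.isfinite(self.values)
        bad = finite & ((self.values < 0.0) | (self.values > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at "
                f"CpG {self.cpg_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean CpG × sample mask, True where the value is missing."""
        return ~np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.cpg_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.cpg_ids), list(self.sample_ids), self.values.copy())

    def select_cpgs(self, cpg_ids) -> "BetaMatrix":
        """Return the sub-matrix over ``cpg_ids`` in the requested order."""
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise KeyError(
                f"{len(missing)} CpGs absent from matrix, e.g. {missing[:5]}"
            )
        rows = [index[c] for c in cpg_ids]
        return BetaMatrix(list(cpg_ids), list(self.sample_ids), self.values[rows])

    def select_samples(self, sample_ids) -> "BetaMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return BetaMatrix(list(self.cpg_ids), list(sample_ids), self.values[:, cols])


def read_beta_matrix(path, missing_token: str = "NA") -> BetaMatrix:
    """Read a tab-delimited beta matrix.

    First column holds CpG IDs (header ``cpg_id``), remaining columns are
    samples.  Cells equal to ``missing_token`` or empty are treated as
    missing.  Out-of-range or non-numeric cells raise with their
    coordinates; ragged rows raise a parse error.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    ncol = len(header)
    if ncol < 2:
        raise ValueError(f"{path}: header must contain cpg_id plus >=1 sample")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {ncol})"
            )
    sample_ids = header[1:]
    cpg_ids = [row[0] for row in rows[1:]]
    if rows[1:]:
        raw = np.array([row[1:] for row in rows[1:]], dtype=object)
        miss = (raw == missing_token) | (raw == "")
        parsed = np.asarray(
            pd.to_numeric(raw.ravel(), errors="coerce"), dtype=float
        ).reshape(raw.shape)
        bad = ~np.isfinite(parsed) & ~miss
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: unparseable value {raw[i, j]!r} at "
                f"CpG {cpg_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        parsed[miss] = np.nan
    else:
        parsed = np.empty((0, len(sample_ids)))
    return BetaMatrix(cpg_ids, sample_ids, parsed)


def write_beta_matrix(betas: BetaMatrix, path, missing_token: str = "NA") -> None:
    betas.to_frame().to_csv(
        path, sep="\t", na_rep=missing_token, index_label="cpg_id"
    )


# ----------------------------------------------------------------------
# Cell-type hierarchy
# ----------------------------------------------------------------------

@dataclass
class CellTypeHierarchy:
    """Main leukocyte types, nested subtype groups and report merges.

    ``subtype_groups`` maps a parent main type to its ordered subtypes;
    ``report_merges`` maps a reported name to the set of raw subtypes it
    aggregates (memory B cells are modelled as isotype-class-switched and
    unswitched populations but reported as a single memory fraction).
    """

    main_types: list[str]
    subtype_groups: dict[str, list[str]] = field(default_factory=dict)
    report_merges: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = _find_duplicate(self.main_types)
        if dup is not None:
            raise ValueError(f"duplicate main type {dup!r}")
        owner: dict[str, str] = {}
        for parent, subs in self.subtype_groups.items():
            if parent not in self.main_types:
                raise ValueError(f"subtype parent {parent!r} is not a main type")
            for s in subs:
                if s in owner:
                    raise ValueError(
                        f"subtype {s!r} assigned to both {owner[s]!r} and {parent!r}"
                    )
                owner[s] = parent
        for merged, members in self.report_merges.items():
            parents = {owner.get(m) for m in members}
            if None in parents or len(parents) != 1:
                raise ValueError(
                    f"report merge {merged!r} must combine subtypes of one parent"
                )

    # ------------------------------------------------------------------
    @property
    def all_subtypes(self) -> list[str]:
        return [s for subs in self.subtype_groups.values() for s in subs]

    def parent_of(self, subtype: str) -> str:
        for parent, subs in self.subtype_groups.items():
            if subtype in subs:
                return parent
        raise KeyError(subtype)

    def reported_subtypes(self, parent: str) -> list[str]:
        """Subtype names after applying report merges, in model order."""
        merged_members = {m for ms in self.report_merges.values() for m in ms}
        out: list[str] = []
        for s in self.subtype_groups[parent]:
            if s in merged_members:
                for name, members in self.report_merges.items():
                    if s in members and name not in out:
                        out.append(name)
            else:
                out.append(s)
        return out

    def to_dict(self) -> dict:
        return {
            "main_types": list(self.main_types),
            "subtype_groups": {k: list(v) for k, v in self.subtype_groups.items()},
            "report_merges": {k: list(v) for k, v in self.report_merges.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTypeHierarchy":
        return cls(
            list(d["main_types"]),
            {k: list(v) for k, v in d.get("subtype_groups", {}).items()},
            {k: list(v) for k, v in d.get("report_merges", {}).items()},
        )


def default_hierarchy() -> CellTypeHierarchy:
    """Standard six main blood leukocyte types with T/B subtype groups."""
    return CellTypeHierarchy(
        main_types=["CD4", "CD8", "CD14", "CD19", "Gran", "NK"],
        subtype_groups={
            "CD4": ["Tmem", "Tnaive", "Treg"],
            "CD8": ["CD8naive", "CD8mem"],
            "CD19": ["Bnaive", "Bmem_switched", "Bmem_unswitched"],
        },
        report_merges={"Bmem": ["Bmem_switched", "Bmem_unswitched"]},
    )


# ----------------------------------------------------------------------
# Reference basis
# ----------------------------------------------------------------------

@dataclass
class ReferenceBasis:
    """CpG × cell-type matrix of median beta profiles (no missing values)."""

    cpg_ids: list[str]
    cell_types: list[str]
    profiles: np.ndarray
    n_samples_per_type: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.cpg_ids), len(self.cell_types)):
            raise ValueError("profiles shape does not match cpg_ids × cell_types")
        dup = _find_duplicate(self.cell_types)
        if dup is not None:
            raise ValueError(f"duplicate cell type {dup!r}")
        if not np.isfinite(self.profiles).all():
            raise ValueError("reference profiles contain missing values")
        if ((self.profiles < 0) | (self.profiles > 1)).any():
            raise ValueError("reference profiles outside [0, 1]")

    def select_cpgs(self, cpg_ids) -> "ReferenceBasis":
        index = {c: i for i, c in enumerate(self.cpg_ids)}
        missing = [c for c in cpg_ids if c not in index]
        if missing:
            raise KeyError(
                f"{len(missing)} panel CpGs absent from basis, e.g. {missing[:5]}"
            )
        rows = [index[c] for c in cpg_ids]
        return ReferenceBasis(
            list(cpg_ids),
            list(self.cell_types),
            self.profiles[rows],
            dict(self.n_samples_per_type),
        )

    def select_types(self, cell_types) -> "ReferenceBasis":
        index = {t: j for j, t in enumerate(self.cell_types)}
        missing = [t for t in cell_types if t not in index]
        if missing:
            raise KeyError(f"cell types absent from basis: {missing}")
        cols = [index[t] for t in cell_types]
        return ReferenceBasis(
            list(self.cpg_ids),
            list(cell_types),
            self.profiles[:, cols],
            {t: self.n_samples_per_type.get(t, 0) for t in cell_types},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.profiles.copy(), index=list(self.cpg_ids), columns=list(self.cell_types)
        )


def build_reference_basis(
    samples_by_type: dict[str, BetaMatrix],
) -> tuple[ReferenceBasis, list[str]]:
    """Median profile per cell type; returns (basis, dropped CpG IDs).

    All input matrices must share an identical ``cpg_ids`` ordering.  The
    median at each CpG is taken over the non-missing samples of that type;
    CpGs for which any type has no observed value are dropped from the
    basis and reported in the second return value, because the basis must
    be complete for least squares.
    """
    if not samples_by_type:
        raise ValueError("no cell types given")
    types = list(samples_by_type)
    ref_cpgs = samples_by_type[types[0]].cpg_ids
    for t, bm in samples_by_type.items():
        if bm.n_samples < 1:
            raise ValueError(f"cell type {t!r} has zero samples")
        if bm.cpg_ids != ref_cpgs:
            raise ValueError(
                f"cpg_ids of cell type {t!r} are not aligned with {types[0]!r}"
            )
    med = np.empty((len(ref_cpgs), len(types)))
    all_missing = np.zeros(len(ref_cpgs), dtype=bool)
    for j, t in enumerate(types):
        vals = samples_by_type[t].values
        empty = (~np.isfinite(vals)).all(axis=1)
        all_missing |= empty
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med[:, j] = np.nanmedian(vals, axis=1)
    keep = ~all_missing
    dropped = [c for c, drop in zip(ref_cpgs, all_missing) if drop]
    basis = ReferenceBasis(
        [c for c, k in zip(ref_cpgs, keep) if k],
        types,
        med[keep],
        {t: samples_by_type[t].n_samples for t in types},
    )
    return basis, dropped


# ----------------------------------------------------------------------
# Proportions
# ----------------------------------------------------------------------

@dataclass
class ProportionSet:
    """Per-sample mixing proportions over a named set of cell types.

    With ``check_sum=True`` (the default for single-level tables) each
    row must sum to at most ``1 + tol``.  Combined main + subtype report
    tables repeat the lymphocyte mass at two levels of the hierarchy and
    are constructed with ``check_sum=False``.
    """

    sample_ids: list[str]
    cell_types: list[str]
    proportions: np.ndarray
    check_sum: bool = True

    _TOL = 1e-8

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValueError("proportions shape does not match sample_ids × cell_types")
        for name, ids in (
            ("sample_id", self.sample_ids),
            ("cell type", self.cell_types),
        ):
            dup = _find_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} {dup!r}")
        if (self.proportions < 0).any():
            i, j = np.argwhere(self.proportions < 0)[0]
            raise ValueError(
                f"negative proportion at sample {self.sample_ids[i]!r}, "
                f"type {self.cell_types[j]!r}"
            )
        if self.check_sum:
            sums = self.proportions.sum(axis=1)
            if (sums > 1 + self._TOL).any():
                i = int(np.argmax(sums))
                raise ValueError(
                    f"proportions of sample {self.sample_ids[i]!r} sum to "
                    f"{sums[i]:.6f} > 1"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions.copy(),
            index=list(self.sample_ids),
            columns=list(self.cell_types),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, check_sum: bool = True) -> "ProportionSet":
        return cls(
            list(frame.index),
            list(frame.columns),
            frame.to_numpy(dtype=float),
            check_sum=check_sum,
        )

    def select_types(self, cell_types, check_sum: bool | None = None) -> "ProportionSet":
        frame = self.to_frame()[list(cell_types)]
        return ProportionSet.from_frame(
            frame, check_sum=self.check_sum if check_sum is None else check_sum
        )


def read_proportions(path, check_sum: bool = True) -> ProportionSet:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return ProportionSet.from_frame(frame, check_sum=check_sum)


def write_proportions(props: ProportionSet, path) -> None:
    props.to_frame().to_csv(path, sep="\t", index_label="sample_id")
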