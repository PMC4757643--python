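"""Recovery metrics and the calibration error function.

Panel-size search and model validation both score an estimate against a
known (measured or simulated) composition.  Per cell type we report the
Pearson correlation and the mean squared error of estimated vs. true
proportions across samples; the scalar calibration error combines both so
that the search rewards estimates that are simultaneously accurate (small
MSE) and linearly related to the truth (large r):

    err = mean over types t of [ (1 - r_t) + MSE_t / Var(truth_t) ]

The MSE is standardized by the variance of the true proportions so that
rare populations (a few percent of whole blood) weigh the same as abundant
ones.  Perfect recovery gives 0.  Types whose true proportion is constant
across samples have no defined correlation and are excluded from the
aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ProportionSet

__all__ = ["RecoveryReport", "per_type_metrics", "error_function"]


@dataclass
class RecoveryReport:
    """Per-type recovery table plus the aggregate calibration error.

    ``table`` is indexed by cell type with columns ``pearson_r`` (NaN when
    the truth is constant), ``mse``, ``truth_var`` (sample variance) and
    ``n_samples``; ``error`` is the scalar defined in the module docstring
    (NaN when every type has constant truth).
    """

    table: pd.DataFrame
    error: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table.round(4)}\noverall error: {self.error:.4f}"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_type")


def _aligned(estimated: ProportionSet, truth: ProportionSet):
    if set(estimated.sample_ids) != set(truth.sample_ids):
        raise ValueError("estimated and truth cover different samples")
    common = [t for t in truth.cell_types if t in estimated.cell_types]
    if not common:
        raise ValueError("estimated and truth share no cell types")
    est = estimated.to_frame().loc[list(truth.sample_ids), common]
    tru = truth.to_frame()[common]
    return est, tru


def per_type_metrics(estimated: ProportionSet, truth: ProportionSet) -> RecoveryReport:
    """Pearson r and MSE per cell type, over the shared types and samples.

    Requires at least 3 samples (the correlation is meaningless below
    that).  A type with constant truth gets ``pearson_r = NaN`` and is
    excluded from the aggregate error; a varying truth met by a constant
    estimate scores ``r = 0``.
    """
    est, tru = _aligned(estimated, truth)
    n = est.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 samples to score recovery, got {n}")
    records = {}
    for t in tru.columns:
        e = est[t].to_numpy(dtype=float)
        x = tru[t].to_numpy(dtype=float)
        mse = float(np.mean((e - x) ** 2))
        var_t = float(np.var(x, ddof=1))
        if var_t == 0.0:
            r = np.nan
        elif np.var(e) == 0.0:
            r = 0.0
        else:
            r = float(np.corrcoef(e, x)[0, 1])
        records[t] = {
            "pearson_r": r,
            "mse": mse,
            "truth_var": var_t,
            "n_samples": n,
        }
    table = pd.DataFrame.from_dict(records, orient="index")
    usable = table["truth_var"] > 0
    if usable.any():
        sub = table[usable]
        error = float(
            np.mean((1.0 - sub["pearson_r"]) + sub["mse"] / sub["truth_var"])
        )
    else:
        error = float("nan")
    return RecoveryReport(table=table, error=error)


def error_function(estimated: ProportionSet, truth: ProportionSet) -> float:
    """Scalar calibration error; lower is better, 0 iff perfect recovery."""
    report = per_type_metrics(estimated, truth)
    if np.isnan(report.error):
        raise ValueError("all truth columns are constant; error undefined")
    return report.error
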