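"""Per-gene fold change, two-group significance test, and DEG selection.

Fold change for gene *i* is the ratio of arithmetic group means of
linear-scale normalized intensities, FC_i = SI_i(case) / SI_i(control);
the differential test is Welch's two-sided t on log2 intensities.  A gene
is a DEG when it passes both the p-value cutoff and the two-sided
fold-change cutoff (FC > t or FC < 1/t).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset

FC_COLUMNS = ["fc", "log2fc", "p_value", "mean_case", "mean_control"]


def fold_change(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-gene fold change table (no p-values).

    Returns a DataFrame indexed by gene with columns ``fc``, ``log2fc``,
    ``mean_case``, ``mean_control``.  Group summaries are arithmetic means
    of the linear-scale intensities.  Raises on nonpositive intensities,
    for which the log-ratio is undefined.
    """
    mat = dataset.matrix
    bad = mat.index[(mat <= 0).any(axis=1)]
    if len(bad):
        raise ValueError(f"nonpositive intensity for gene {bad[0]!r}")
    mean_case = mat[dataset.case_samples].mean(axis=1)
    mean_control = mat[dataset.control_samples].mean(axis=1)
    fc = mean_case / mean_control
    return pd.DataFrame(
        {
            "fc": fc,
            "log2fc": np.log2(fc),
            "mean_case": mean_case,
            "mean_control": mean_control,
        }
    )


def differential_test(dataset: ExpressionDataset) -> pd.Series:
    """Two-sided Welch t-test on log2 intensities, per gene.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means agree and p = 0 when they differ — no noise model can
    temper the latter, so it is flagged as maximally significant.
    """
    case = dataset.matrix[dataset.case_samples]
    control = dataset.matrix[dataset.control_samples]
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("differential test needs >= 2 samples per group")
    log_case = np.log2(case.to_numpy(dtype=float))
    log_control = np.log2(control.to_numpy(dtype=float))
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trip scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(log_case, log_control, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # scipy yields nan when both within-group variances vanish
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(log_case.mean(axis=1), log_control.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=dataset.matrix.index, name="p_value")


def fold_change_table(dataset: ExpressionDataset) -> pd.DataFrame:
    """Fold changes plus Welch p-values, one row per gene."""
    table = fold_change(dataset)
    table["p_value"] = differential_test(dataset)
    return table[FC_COLUMNS]


def select_degs(
    fc_table: pd.DataFrame, fc_threshold: float = 1.5, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Genes passing both cutoffs; the FC cutoff is applied two-sidedly.

    A gene is kept iff p_value < p_threshold and (fc > fc_threshold or
    fc < 1/fc_threshold), so down-regulation is treated symmetrically
    to up-regulation.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    fc_pass = (fc_table["fc"] > fc_threshold) | (fc_table["fc"] < 1.0 / fc_threshold)
    p_pass = fc_table["p_value"] < p_threshold
    return fc_table.loc[fc_pass & p_pass]
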