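"""Relative miRNA quantification from qPCR Ct tables.

Implements the comparative-Ct (2^-ddCt) method with a small-nuclear-RNA
reference (U6 by default) and a designated calibrator sample, replicate
SEM on the fold scale, one-way ANOVA across groups, and a quantitative
tissue-specificity call.  Amplification efficiency is fixed at 2.0 (pure
ddCt, no efficiency correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc

REQUIRED_COLUMNS = ("mirna", "group", "replicate", "ct_target", "ct_reference")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    return table


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classic one-way ANOVA: between/within mean-square ratio.

    The p-value comes from the F distribution via the regularized
    incomplete beta function.  Degenerate inputs: identical group means
    give F = 0, p = 1; zero within-group variance with unequal means gives
    F = inf, p = 0 by convention.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n = sum(len(a) for a in arrs)
    df_between = k - 1
    df_within = n - k
    if df_within < 2:
        raise ValueError("need >= 2 error degrees of freedom")
    grand = np.concatenate(arrs).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        warnings.warn("zero within-group variance with unequal means; p set to 0")
        return math.inf, 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    # survival function of F(df_between, df_within)
    p = float(betainc(df_within / 2.0, df_between / 2.0, df_within / (df_within + df_between * f)))
    return float(f), min(max(p, 0.0), 1.0)


@dataclass
class ExpressionResult:
    """Per-(miRNA, group) fold changes and per-miRNA ANOVA statistics."""

    folds: pd.DataFrame  # mirna, group, n, delta_ct, ddct, fold, fold_sem
    anova: pd.DataFrame  # mirna, F, p


def delta_delta_ct(
    table: pd.DataFrame, calibrator_group: str
) -> ExpressionResult:
    """Relative expression by the comparative-Ct method.

    Per (miRNA, group): dCt = mean Ct(target) - mean Ct(reference);
    ddCt = dCt(group) - dCt(calibrator); fold = 2^-ddCt, so the calibrator
    group itself always has fold 1.  SEM is computed on per-replicate folds
    (each replicate's dCt against the calibrator mean), matching a
    "mean +/- SEM" bar-plot presentation; with a single replicate the SEM
    is reported as NaN.  ANOVA runs on per-replicate dCt values across
    groups.
    """
    validate_ct_table(table)
    rows = []
    anova_rows = []
    for mirna, sub in table.groupby("mirna", sort=True):
        groups = {g: s for g, s in sub.groupby("group", sort=True)}
        if calibrator_group not in groups:
            raise ValueError(f"calibrator group {calibrator_group!r} missing for {mirna}")
        dct = {
            g: s["ct_target"].mean() - s["ct_reference"].mean() for g, s in groups.items()
        }
        dct_cal = dct[calibrator_group]
        rep_dct = {
            g: (s["ct_target"] - s["ct_reference"]).to_numpy() for g, s in groups.items()
        }
        for g in groups:
            ddct = dct[g] - dct_cal
            fold = 2.0 ** (-ddct)
            rep_folds = 2.0 ** (-(rep_dct[g] - dct_cal))
            n = len(rep_folds)
            sem = float(rep_folds.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            rows.append((mirna, g, n, dct[g], ddct, fold, sem))
        if len(groups) >= 2 and sum(len(v) for v in rep_dct.values()) - len(groups) >= 2:
            f, p = one_way_anova(list(rep_dct.values()))
            anova_rows.append((mirna, f, p))
        else:
            anova_rows.append((mirna, math.nan, math.nan))
    folds = pd.DataFrame(
        rows, columns=["mirna", "group", "n", "delta_ct", "ddct", "fold", "fold_sem"]
    )
    anova = pd.DataFrame(anova_rows, columns=["mirna", "F", "p"])
    return ExpressionResult(folds=folds, anova=anova)


def tissue_specificity(
    fold_matrix: pd.DataFrame, tau_threshold: float = 0.2, max_tissues: int = 4
) -> dict[str, Optional[frozenset]]:
    """Call each miRNA tissue-specific or ubiquitous.

    A miRNA is specific to the tissue set whose expression is at least
    ``tau_threshold`` times its maximum tissue value, provided that set has
    at most ``max_tissues`` members; otherwise it is ubiquitous (None).
    Rows of all zeros are called ubiquitous with a warning.
    """
    if fold_matrix.shape[1] < 2:
        raise ValueError("need >= 2 tissues")
    calls: dict[str, Optional[frozenset]] = {}
    for mirna, row in fold_matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        mx = vals.max()
        if mx <= 0:
            warnings.warn(f"{mirna}: all-zero expression row, called ubiquitous")
            calls[mirna] = None
            continue
        high = frozenset(fold_matrix.columns[vals >= tau_threshold * mx])
        calls[mirna] = high if len(high) <= max_tissues else None
    return calls
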