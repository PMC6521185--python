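"""Mutation-versus-selection diagnostics and summary statistics.

Covers the expected-ENc curve for GC3-only bias, the neutrality regression
(GC12 on GC3), the pairwise correlation matrix of codon-usage indices, and
one-way ANOVA of an index across subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .composition import CompositionProfile, profiles_frame
from .errors import ComputationError, ValidationError


def expected_enc(s: float) -> float:
    """Expected ENc when GC3 (s) is the only source of bias.

    Wright's curve: ENc(s) = 2 + s + 29 / (s^2 + (1 - s)^2), for s in (0, 1).
    """
    if not 0.0 < s < 1.0:
        raise ValidationError(f"GC3 must lie strictly in (0, 1), got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def expected_enc_curve(grid: Sequence[float] | None = None) -> pd.DataFrame:
    """The expected curve sampled over a GC3 grid (default [0.01, 0.99])."""
    if grid is None:
        grid = np.linspace(0.01, 0.99, 99)
    return pd.DataFrame(
        {"GC3": list(grid), "expected_ENc": [expected_enc(s) for s in grid]}
    )


def enc_gc3_data(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Per-record (GC3, ENc, expected ENc) triples for the ENc-GC3 plot."""
    df = profiles_frame(profiles)
    out = df[["subgroup", "GC3", "GC3s", "ENc"]].copy()
    out["expected_ENc"] = [expected_enc(s) for s in out["GC3s"]]
    return out


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 with the associated Pearson correlation."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    n: int


def neutrality_regression(
    gc12: Sequence[float], gc3: Sequence[float]
) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3; slope near 1 indicates
    genome-wide mutation pressure, near 0 selection on positions 1-2."""
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("GC12 and GC3 vectors differ in length")
    if x.size < 3:
        raise ValidationError("neutrality regression needs at least 3 records")
    if np.ptp(x) == 0:
        raise ComputationError("slope undefined: zero variance in GC3")
    if np.ptp(y) == 0:
        # constant response: slope and correlation are exactly zero
        return NeutralityFit(
            slope=0.0, intercept=float(y[0]), r=0.0, r_squared=0.0,
            p_value=1.0, n=int(x.size),
        )
    fit = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


#: index columns of the correlation table, in publication order (CBI/Fop are
#: not computed by this package: the optimal-codon set was never published)
INDEX_COLUMNS: tuple[str, ...] = (
    "CAI", "ENc", "GC1", "GC2", "GC12", "GC3",
    "A", "C", "U", "G", "GU", "AC", "GU3", "AU3",
)


def index_table(
    profiles: list[CompositionProfile], cai: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-record table of the indices entering the correlation matrix.

    ``cai`` is the output of :func:`codonuse.adaptation.cai_table`; when
    omitted, the CAI column is dropped.
    """
    df = profiles_frame(profiles)
    out = pd.DataFrame(index=df.index)
    if cai is not None:
        out["CAI"] = cai["CAI"]
    out["ENc"] = df["ENc"]
    for col in ("GC1", "GC2", "GC12", "GC3", "A", "C", "U", "G"):
        out[col] = df[col]
    out["GU"] = df["G"] + df["U"]
    out["AC"] = df["A"] + df["C"]
    out["GU3"] = df["GU3"]
    out["AU3"] = df["AU3"]
    return out


def correlation_matrix(
    table: pd.DataFrame, method: str = "pearson"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations with two-tailed p values and significance flags.

    Returns (r, p, flags); flags are '**' at p < 0.01, '*' at p < 0.05,
    '' otherwise. Constant columns yield NaN correlations (reported
    missing). No multiple-testing correction is applied.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if len(table) < 3:
        raise ValidationError("correlation matrix needs at least 3 records")
    cols = list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        xi = table[cols[i]].astype(float)
        if xi.nunique() <= 1:
            r.iloc[i, :] = np.nan
            r.iloc[:, i] = np.nan
            p.iloc[i, :] = np.nan
            p.iloc[:, i] = np.nan
            continue
        for j in range(i + 1, k):
            xj = table[cols[j]].astype(float)
            if xj.nunique() <= 1:
                continue
            res = corr(xi, xj)
            r.iloc[i, j] = r.iloc[j, i] = float(res.statistic)
            p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue)
    flags = p.map(
        lambda v: "" if pd.isna(v) else ("**" if v < 0.01 else ("*" if v < 0.05 else ""))
    )
    np.fill_diagonal(flags.values, "")
    return r, p, flags


def one_way_anova(
    values: Sequence[float], group_labels: Sequence[str]
) -> tuple[float, float, pd.DataFrame]:
    """Classical one-way ANOVA of ``values`` across ``group_labels``.

    Returns (F, p, per-group means table). Requires >= 2 groups with
    >= 2 observations each.
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if v.shape != labels.shape:
        raise ValidationError("values and group labels differ in length")
    groups = {g: v[labels == g] for g in np.unique(labels)}
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    f_stat, p_val = stats.f_oneway(*groups.values())
    means = pd.DataFrame(
        {
            "group": list(groups),
            "n": [arr.size for arr in groups.values()],
            "mean": [arr.mean() for arr in groups.values()],
        }
    ).set_index("group")
    return float(f_stat), float(p_val), means
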