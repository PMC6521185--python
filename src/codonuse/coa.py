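"""Correspondence analysis of per-record RSCU profiles.

Classical CA: the nonnegative table is scaled to a correspondence matrix,
centered by row/column masses, and the standardized residuals are
decomposed by SVD. Axis inertias are the squared singular values; principal
coordinates are mass-rescaled singular vectors. By convention the analysis
runs on the records x 59-codon RSCU matrix (raw-count mode is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codon_bias import rscu
from .errors import ComputationError, ValidationError
from .genetic_code import SYNONYMOUS_CODONS
from .seqio import SequenceSet, count_codons

_DEGENERATE_TOL = 1e-12


def build_rscu_matrix(seqs: SequenceSet) -> pd.DataFrame:
    """Per-record RSCU over the 59 synonymous codons (records x 59).

    RSCU values missing because an amino acid is absent from a record are
    imputed as 0 with a warning.
    """
    if len(seqs) < 3:
        raise ValidationError("correspondence analysis needs at least 3 records")
    tables = count_codons(seqs)
    rows = {}
    imputed = []
    for rec in seqs:
        values = rscu(tables[rec.id]).values
        row = []
        for codon in SYNONYMOUS_CODONS:
            v = values[codon]
            if v is None:
                imputed.append((rec.id, codon))
                v = 0.0
            row.append(v)
        rows[rec.id] = row
    if imputed:
        warnings.warn(
            f"imputed 0 for {len(imputed)} missing RSCU cells "
            f"(absent amino acids), e.g. {imputed[0]}",
            stacklevel=2,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SYNONYMOUS_CODONS)
    )


@dataclass(frozen=True)
class COAResult:
    """Axis inertias and principal coordinates of a correspondence analysis."""

    inertias: np.ndarray
    inertia_fractions: np.ndarray
    total_inertia: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    degenerate: bool = False

    @property
    def n_axes(self) -> int:
        return len(self.inertias)


def correspondence_analysis(matrix: pd.DataFrame) -> COAResult:
    """Classical correspondence analysis of a nonnegative table.

    A table exactly matching its independence model (e.g. rank-1) has zero
    total inertia and is reported as degenerate with no axes. Axis signs
    are fixed by making the largest-magnitude column coordinate on each
    axis positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("correspondence analysis needs a 2-D table, at least 2x2")
    if (x < 0).any():
        raise ValidationError("correspondence analysis requires a nonnegative table")
    row_sums = x.sum(axis=1)
    if (row_sums == 0).any():
        bad = list(np.asarray(matrix.index)[row_sums == 0])
        raise ValidationError(f"all-zero rows in correspondence table: {bad}")
    total = x.sum()
    if total == 0:
        raise ComputationError("rank-0 table: nothing to decompose")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep_cols = c > 0
    expected = np.outer(r, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(expected > 0, (p - expected) / np.sqrt(expected), 0.0)
    u, sing, vt = np.linalg.svd(s, full_matrices=False)
    max_axes = min(x.shape[0] - 1, int(keep_cols.sum()) - 1)
    sing = sing[:max_axes]
    inertias = sing**2
    nontrivial = inertias > _DEGENERATE_TOL
    inertias = inertias[nontrivial]
    total_inertia = float((s**2).sum())
    if inertias.size == 0 or total_inertia < _DEGENERATE_TOL:
        return COAResult(
            inertias=np.zeros(0),
            inertia_fractions=np.zeros(0),
            total_inertia=total_inertia,
            row_coords=pd.DataFrame(index=matrix.index),
            col_coords=pd.DataFrame(index=matrix.columns),
            degenerate=True,
        )
    k = inertias.size
    u = u[:, :k]
    v = vt[:k].T
    sing = sing[:k]
    with np.errstate(divide="ignore", invalid="ignore"):
        row_coords = (u * sing) / np.sqrt(r)[:, None]
        col_coords = (v * sing) / np.sqrt(np.where(c > 0, c, np.nan))[:, None]
    # fix arbitrary SVD signs: largest-|coordinate| codon positive per axis
    for ax in range(k):
        idx = np.nanargmax(np.abs(col_coords[:, ax]))
        if col_coords[idx, ax] < 0:
            col_coords[:, ax] *= -1
            row_coords[:, ax] *= -1
    axes = [f"axis{i+1}" for i in range(k)]
    return COAResult(
        inertias=inertias,
        inertia_fractions=inertias / inertias.sum(),
        total_inertia=total_inertia,
        row_coords=pd.DataFrame(row_coords, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=matrix.columns, columns=axes),
        degenerate=False,
    )


def axis_contribution_report(result: COAResult, k: int = 2) -> dict:
    """Axis contribution percentages and ending-base-labelled codon coords.

    Axes beyond the available non-trivial ones carry zero inertia by
    construction and are reported as 0%.
    """
    if result.degenerate and result.n_axes == 0:
        raise ComputationError("degenerate analysis: no axes to report")
    if k < 1:
        raise ValidationError("k must be >= 1")
    pct = []
    for i in range(k):
        pct.append(
            float(result.inertia_fractions[i] * 100.0) if i < result.n_axes else 0.0
        )
    coords = result.col_coords.iloc[:, : min(k, result.n_axes)].copy()
    coords["ending"] = [str(codon)[-1] for codon in coords.index]
    return {"axis_pct": pct, "codon_coords": coords}
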