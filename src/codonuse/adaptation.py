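"""Codon adaptation index against a host codon-usage reference.

Sharp & Li formulation: relative adaptiveness w_i = RSCU_i / max RSCU in
the codon's family, CAI = geometric mean of w over the codons of a
sequence, Met/Trp and stops excluded. Zero host counts are replaced by a
pseudo-count of 0.5 before computing RSCU so that w stays positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .codon_bias import rscu_from_reference
from .errors import ComputationError, ValidationError
from .genetic_code import (
    CODON_TO_AA,
    FAMILIES,
    SINGLE_CODON_AAS,
    SYNONYMOUS_CODONS,
    is_unambiguous,
)
from .seqio import CodonUsageReference, SequenceSet

ZERO_COUNT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class RelativeAdaptiveness:
    """w values on (0, 1] over the 59 synonymous codons."""

    w: Mapping[str, float]
    reference_label: str

    def __post_init__(self) -> None:
        w = dict(self.w)
        missing = [c for c in SYNONYMOUS_CODONS if c not in w]
        if missing:
            raise ValidationError(f"relative adaptiveness missing codons: {missing}")
        if any(not (0 < v <= 1 + 1e-12) for v in w.values()):
            raise ValidationError("w values must lie in (0, 1]")
        object.__setattr__(self, "w", w)


def relative_adaptiveness(ref: CodonUsageReference) -> RelativeAdaptiveness:
    """w from a host reference (counts, per-thousand, or direct RSCU).

    For count dialects, codons with zero counts get a 0.5 pseudo-count
    before RSCU so every w is strictly positive; a family whose codons are
    ALL zero (or absent from an rscu-direct table) is an error.
    """
    if ref.is_rscu:
        rscu_vals: dict[str, float] = {}
        for c in SYNONYMOUS_CODONS:
            v = ref.values[c]
            rscu_vals[c] = v
    else:
        adjusted = dict(ref.values)
        for aa, codons in FAMILIES.items():
            if aa in SINGLE_CODON_AAS:
                continue
            if all(adjusted[c] == 0 for c in codons):
                raise ValidationError(
                    f"host reference {ref.source_label!r}: amino-acid family "
                    f"{aa} entirely absent"
                )
            for c in codons:
                if adjusted[c] == 0:
                    adjusted[c] = ZERO_COUNT_PSEUDOCOUNT
        table = rscu_from_reference(
            CodonUsageReference(ref.source_label, adjusted, ref.dialect)
        )
        rscu_vals = {c: table.values[c] for c in SYNONYMOUS_CODONS}
    w: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if aa in SINGLE_CODON_AAS:
            continue
        fam_max = max(rscu_vals[c] for c in codons)
        if fam_max <= 0:
            raise ValidationError(
                f"host reference {ref.source_label!r}: amino-acid family {aa} entirely absent"
            )
        for c in codons:
            w[c] = rscu_vals[c] / fam_max
    # rscu-direct tables can legitimately print 0.00; floor those w so CAI
    # stays defined, mirroring the pseudo-count treatment of zero counts
    floor = min((v for v in w.values() if v > 0), default=None)
    if floor is None:
        raise ValidationError("degenerate host reference: all w zero")
    for c, v in w.items():
        if v == 0:
            w[c] = min(0.01, floor)
    return RelativeAdaptiveness(w=w, reference_label=ref.source_label)


def cai(codons: Sequence[str], w: RelativeAdaptiveness) -> float:
    """Geometric mean of w over the synonymous codons of a sequence.

    Computed in log space to avoid underflow on long sequences. Met, Trp,
    stop and ambiguous codons are excluded; zero usable codons is an error.
    """
    log_sum = 0.0
    n = 0
    for codon in codons:
        if not is_unambiguous(codon):
            continue
        aa = CODON_TO_AA[codon]
        if aa == "*" or aa in SINGLE_CODON_AAS:
            continue
        log_sum += math.log(w.w[codon])
        n += 1
    if n == 0:
        raise ComputationError("CAI undefined: no synonymous codons in sequence")
    return math.exp(log_sum / n)


def cai_table(
    seqs: SequenceSet,
    references: Mapping[str, RelativeAdaptiveness],
) -> pd.DataFrame:
    """Per-record CAI, each record scored against its own host's reference.

    ``references`` maps host label -> RelativeAdaptiveness; records whose
    host has no reference raise.
    """
    rows = []
    for rec in seqs:
        host = rec.host or ""
        if host not in references:
            raise ValidationError(f"record {rec.id!r}: no reference for host {host!r}")
        rows.append(
            {
                "id": rec.id,
                "subgroup": rec.subgroup,
                "host": host,
                "CAI": cai(rec.codons, references[host]),
            }
        )
    return pd.DataFrame(rows).set_index("id")


def cai_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup mean and standard error of CAI."""
    out = []
    for sg, sub in table.groupby("subgroup", dropna=False):
        n = len(sub)
        out.append(
            {
                "subgroup": sg,
                "n": n,
                "mean": sub["CAI"].mean(),
                "se": 0.0 if n == 1 else sub["CAI"].std(ddof=1) / math.sqrt(n),
            }
        )
    return pd.DataFrame(out).set_index("subgroup")
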