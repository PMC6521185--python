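"""Relative synonymous codon usage and high-frequency-codon analysis.

This module is the analytical core: RSCU tables, the >= 1.05
high-frequency-codon rule, the host-coincident (HFC_H) versus
virus-specific (HFC_V) classification of a virus codon against its host's
usage, conversion of labels between virus subgroups, and the per-amino-acid
contribution of a high-frequency codon subset (CHFC).

The HFC_H/HFC_V rule is not stated in words in the source material; it is
inferred from the published highlighting and reproduces every published
count, and is therefore documented here as inferred:

    HFC_H  <=>  virus RSCU >= threshold and host RSCU >= threshold
    HFC_V  <=>  virus RSCU >= threshold and host RSCU <  threshold
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import ComputationError, ValidationError
from .genetic_code import (
    AA_ONE_TO_THREE,
    CODON_TO_AA,
    FAMILIES,
    FAMILY_SIZE,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    SYNONYMOUS_CODONS,
)
from .seqio import CodonCountTable, CodonUsageReference

DEFAULT_HFC_THRESHOLD = 1.05

HFC_H = "HFC_H"
HFC_V = "HFC_V"
NON_HFC = "non-HFC"


@dataclass(frozen=True)
class RSCUTable:
    """Per-codon RSCU values; codons of absent amino acids carry None."""

    values: Mapping[str, float | None]
    source: str = "pooled-subgroup"
    label: str | None = None

    def __post_init__(self) -> None:
        vals = dict(self.values)
        unknown = {c for c in vals if c not in SENSE_CODONS}
        if unknown:
            raise ValidationError(f"RSCU table contains non-sense codons: {sorted(unknown)}")
        for c in SENSE_CODONS:
            vals.setdefault(c, None)
        if any(v is not None and v < 0 for v in vals.values()):
            raise ValidationError("negative RSCU value")
        object.__setattr__(self, "values", vals)

    @property
    def family_sizes(self) -> dict[str, int]:
        return dict(FAMILY_SIZE)

    def get(self, codon: str) -> float | None:
        return self.values[codon]


def rscu(counts: CodonCountTable, source: str | None = None) -> RSCUTable:
    """RSCU_ij = g_ij * n_i / sum_family(g): observed over equal-use expectation.

    Families with zero total occurrences yield None for all member codons.
    Met and Trp get RSCU 1 whenever present.
    """
    values: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        family_total = sum(counts.counts[c] for c in codons)
        n_i = FAMILY_SIZE[aa]
        for c in codons:
            if family_total == 0:
                values[c] = None
            else:
                values[c] = counts.counts[c] * n_i / family_total
    return RSCUTable(values, source=source or counts.scope, label=counts.label)


def rscu_from_reference(ref: CodonUsageReference) -> RSCUTable:
    """An RSCUTable from a host reference, whichever dialect it carries."""
    if ref.is_rscu:
        return RSCUTable(dict(ref.values), source="host-reference", label=ref.source_label)
    # counts may be real-valued (per-thousand pseudo-counts); apply the RSCU
    # formula directly rather than going through the integer count table
    values: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        family_total = sum(ref.values[c] for c in codons)
        for c in codons:
            values[c] = None if family_total == 0 else ref.values[c] * FAMILY_SIZE[aa] / family_total
    return RSCUTable(values, source="host-reference", label=ref.source_label)


def high_frequency_codons(
    table: RSCUTable, threshold: float = DEFAULT_HFC_THRESHOLD
) -> frozenset[str]:
    """Codons with RSCU >= threshold; single-codon families never qualify."""
    return frozenset(
        c
        for c in SYNONYMOUS_CODONS
        if table.values[c] is not None and table.values[c] >= threshold
    )


@dataclass(frozen=True)
class HFCClassification:
    """Per-codon HFC_H / HFC_V / non-HFC labels for one (virus, host) pair."""

    labels: Mapping[str, str]
    threshold: float
    virus_label: str
    host_label: str

    def codons_with(self, label: str) -> frozenset[str]:
        return frozenset(c for c, lab in self.labels.items() if lab == label)

    @property
    def hfc_h(self) -> frozenset[str]:
        return self.codons_with(HFC_H)

    @property
    def hfc_v(self) -> frozenset[str]:
        return self.codons_with(HFC_V)

    def summary_counts(self) -> dict[str, int]:
        return {
            HFC_H: len(self.hfc_h),
            HFC_V: len(self.hfc_v),
            NON_HFC: len(self.codons_with(NON_HFC)),
        }


def classify_hfc(
    virus_rscu: RSCUTable,
    host_rscu: RSCUTable | CodonUsageReference,
    threshold: float = DEFAULT_HFC_THRESHOLD,
) -> HFCClassification:
    """Label each of the 59 synonymous codons for a (virus, host) pair.

    Codons of amino acids absent from the virus table are unclassifiable and
    omitted from the label map, as are Met/Trp codons.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if isinstance(host_rscu, CodonUsageReference):
        host_rscu = rscu_from_reference(host_rscu)
    labels: dict[str, str] = {}
    for codon in SYNONYMOUS_CODONS:
        v = virus_rscu.values[codon]
        if v is None:
            continue
        if v < threshold:
            labels[codon] = NON_HFC
            continue
        h = host_rscu.values[codon]
        if h is None:
            raise ValidationError(
                f"host table {host_rscu.label!r} has no RSCU for virus "
                f"high-frequency codon {codon}"
            )
        labels[codon] = HFC_H if h >= threshold else HFC_V
    return HFCClassification(
        labels=labels,
        threshold=threshold,
        virus_label=virus_rscu.label or "virus",
        host_label=host_rscu.label or "host",
    )


@dataclass(frozen=True)
class ConversionReport:
    """Codons whose label flips between two (virus, host) classifications."""

    pair: tuple[str, str]
    v_to_h: frozenset[str]
    h_to_v: frozenset[str]


def conversion_analysis(
    class_a: HFCClassification, class_b: HFCClassification
) -> ConversionReport:
    """Codons HFC_V in A but HFC_H in B (v_to_h), and the reverse (h_to_v)."""
    if set(class_a.labels) != set(class_b.labels):
        only_a = sorted(set(class_a.labels) - set(class_b.labels))
        only_b = sorted(set(class_b.labels) - set(class_a.labels))
        raise ValidationError(
            f"classifications cover different codon sets (only in A: {only_a}; only in B: {only_b})"
        )
    v_to_h = frozenset(class_a.hfc_v & class_b.hfc_h)
    h_to_v = frozenset(class_a.hfc_h & class_b.hfc_v)
    return ConversionReport(
        pair=(class_a.virus_label, class_b.virus_label), v_to_h=v_to_h, h_to_v=h_to_v
    )


@dataclass(frozen=True)
class CHFCSummary:
    """Per-amino-acid and overall contribution of the HFC subsets.

    ``per_aa`` columns: f_j, chfc_h, chfc_v, osc (counts of codon
    occurrences); overall percentages are over total sense codons.
    """

    per_aa: pd.DataFrame
    chfc_h_pct: float
    chfc_v_pct: float
    cosc_pct: float
    virus_label: str
    host_label: str


def chfc(
    counts: CodonCountTable,
    rscu_table: RSCUTable,
    classification: HFCClassification,
    atol: float = 1e-6,
) -> CHFCSummary:
    """Contribution of high-frequency codons, per amino acid and overall.

    Two routes are computed for every subset: the direct count
    sum_{i in S} g_ij and the published formula
    sum_{i in S} RSCU_ij * f_j / n_i. They are algebraically identical; a
    discrepancy beyond ``atol`` indicates the three inputs do not derive
    from the same pooled table and raises ComputationError.
    """
    f = counts.aa_counts()
    total_sense = counts.total_sense()
    if total_sense == 0:
        raise ValidationError("empty codon count table")
    rows = []
    for aa, codons in sorted(FAMILIES.items()):
        f_j = f[aa]
        n_i = FAMILY_SIZE[aa]
        subset_counts = {HFC_H: 0.0, HFC_V: 0.0}
        for label in (HFC_H, HFC_V):
            subset = [c for c in codons if classification.labels.get(c) == label]
            direct = float(sum(counts.counts[c] for c in subset))
            if f_j > 0:
                formula = sum(
                    (rscu_table.values[c] or 0.0) * f_j / n_i for c in subset
                )
            else:
                formula = 0.0
            if abs(direct - formula) > atol:
                raise ComputationError(
                    f"CHFC self-check failed for {aa}/{label}: "
                    f"direct count {direct} vs formula {formula}"
                )
            subset_counts[label] = direct
        osc = f_j - subset_counts[HFC_H] - subset_counts[HFC_V]
        rows.append(
            {
                "aa": aa,
                "f_j": f_j,
                "chfc_h": subset_counts[HFC_H],
                "chfc_v": subset_counts[HFC_V],
                "osc": osc,
            }
        )
    per_aa = pd.DataFrame(rows).set_index("aa")
    return CHFCSummary(
        per_aa=per_aa,
        chfc_h_pct=per_aa["chfc_h"].sum() / total_sense * 100.0,
        chfc_v_pct=per_aa["chfc_v"].sum() / total_sense * 100.0,
        cosc_pct=per_aa["osc"].sum() / total_sense * 100.0,
        virus_label=classification.virus_label,
        host_label=classification.host_label,
    )


def rscu_report(
    tables: Mapping[str, RSCUTable],
    classifications: Mapping[str, HFCClassification] | None = None,
    threshold: float = DEFAULT_HFC_THRESHOLD,
) -> pd.DataFrame:
    """A publication-style wide table: one row per sense codon.

    Columns: ``aa`` (three-letter), one RSCU column per source in
    ``tables``, an ``hfc:<source>`` boolean flag per source, and a
    ``class:<pair>`` column per classification.
    """
    rows = []
    classifications = classifications or {}
    for codon in SENSE_CODONS:
        row: dict[str, object] = {
            "codon": codon,
            "aa": AA_ONE_TO_THREE[CODON_TO_AA[codon]],
        }
        for name, table in tables.items():
            v = table.values[codon]
            row[name] = v
            if CODON_TO_AA[codon] in SINGLE_CODON_AAS:
                row[f"hfc:{name}"] = False
            else:
                row[f"hfc:{name}"] = v is not None and v >= threshold
        for name, cls in classifications.items():
            row[f"class:{name}"] = cls.labels.get(codon, NON_HFC)
        rows.append(row)
    return pd.DataFrame(rows).set_index("codon")
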