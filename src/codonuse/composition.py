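"""Nucleotide/position composition indices, Wright's ENc, Gravy and Aromo.

Composition is computed over the unambiguous sense codons of a record
(terminal stop already stripped on read). Third-position percentages are
plain frequencies over all sense codons, Met and Trp included; the ENc
estimator itself never sees Met/Trp.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dataclass_fields

import pandas as pd

from .errors import ComputationError, ValidationError
from .genetic_code import (
    AROMATIC_AAS,
    DEGENERACY_CLASSES,
    FAMILIES,
    HYDROPATHY,
    SINGLE_CODON_AAS,
)
from .seqio import CodingSequence, CodonCountTable, count_codons


@dataclass(frozen=True)
class CompositionProfile:
    """All per-record indices of the composition summary table.

    Percentages are on [0, 100]; GC1/GC2/GC3/GC12 are fractions on [0, 1].
    """

    id: str
    subgroup: str | None
    A: float
    C: float
    G: float
    U: float
    AU: float
    GC: float
    A3: float
    C3: float
    G3: float
    U3: float
    GC3pct: float
    GA3: float
    GU3: float
    AU3: float
    CU3: float
    GC1: float
    GC2: float
    GC3: float
    GC3s: float
    GC12: float
    ENc: float
    L_sym: int
    L_aa: int
    Gravy: float
    Aromo: float


#: rows of the summary table, in publication order
PROFILE_FIELDS: tuple[str, ...] = (
    "A", "C", "U", "G", "GC", "AU",
    "A3", "C3", "U3", "G3", "GC3pct", "GA3", "GU3", "AU3", "CU3",
    "GC1", "GC2", "GC3", "GC12", "ENc", "L_sym", "L_aa", "Gravy", "Aromo",
)


def nucleotide_composition(seq: CodingSequence) -> dict[str, float]:
    """Overall and third-position nucleotide percentages plus GC1/GC2/GC3.

    Returns a plain dict (the partial profile); ``composition_profile``
    assembles the full record including ENc and the protein indices.
    """
    codons = seq.sense_codons
    if not codons:
        raise ValidationError(f"record {seq.id!r}: no unambiguous codons")
    n = len(codons)
    base_tot = {b: 0 for b in "ACGU"}
    pos_tot = [dict.fromkeys("ACGU", 0) for _ in range(3)]
    syn_n = 0
    syn_gc3 = 0
    for codon in codons:
        for pos, b in enumerate(codon):
            base_tot[b] += 1
            pos_tot[pos][b] += 1
        if codon not in ("AUG", "UGG"):
            syn_n += 1
            syn_gc3 += codon[2] in "GC"
    total = 3 * n
    pct = {b: base_tot[b] / total * 100.0 for b in "ACGU"}
    p3 = {b: pos_tot[2][b] / n * 100.0 for b in "ACGU"}
    gc = [(pos_tot[i]["G"] + pos_tot[i]["C"]) / n for i in range(3)]
    return {
        "A": pct["A"], "C": pct["C"], "G": pct["G"], "U": pct["U"],
        "AU": pct["A"] + pct["U"], "GC": pct["G"] + pct["C"],
        "A3": p3["A"], "C3": p3["C"], "G3": p3["G"], "U3": p3["U"],
        "GC3pct": p3["G"] + p3["C"],
        "GA3": p3["G"] + p3["A"],
        "GU3": p3["G"] + p3["U"],
        "AU3": p3["A"] + p3["U"],
        "CU3": p3["C"] + p3["U"],
        "GC1": gc[0], "GC2": gc[1], "GC3": gc[2],
        # synonymous GC3 (Met/Trp excluded): the x-axis of the ENc-GC3 plot
        "GC3s": syn_gc3 / syn_n if syn_n else gc[2],
        "GC12": (gc[0] + gc[1]) / 2.0,
    }


def effective_number_of_codons(counts: CodonCountTable) -> float:
    """Wright's ENc estimator.

    Per amino acid with n >= 2 occurrences, homozygosity
    F = (n * sum(p_i^2) - 1) / (n - 1); class means over the degeneracy
    classes {2, 3, 4, 6}; ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.

    Amino acids with F <= 0 (possible at tiny n) are excluded from their
    class mean. An empty 3-fold class (Ile unobserved) is imputed as
    (F2 + F4) / 2; an empty 2-, 4- or 6-fold class is an error. Values above
    61 are reported with a warning, never clamped.
    """
    if counts.total_sense() == 0:
        raise ValidationError("empty codon count table")
    f_by_aa: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        if aa in SINGLE_CODON_AAS:
            continue
        n = sum(counts.counts[c] for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.counts[c] / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f > 0:
            f_by_aa[aa] = f
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = [f_by_aa[aa] for aa in aas if aa in f_by_aa]
        if fs:
            class_means[k] = sum(fs) / len(fs)
    if 2 not in class_means or 4 not in class_means or 6 not in class_means:
        raise ComputationError(
            "ENc undefined: a 2-, 4- or 6-fold degeneracy class has no usable amino acid"
        )
    if 3 not in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    enc = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    if enc > 61.0:
        warnings.warn(f"ENc {enc:.3f} exceeds 61 (finite-sample artifact)", stacklevel=2)
    return enc


def gravy_aromo(counts: CodonCountTable) -> tuple[float, float]:
    """Mean Kyte-Doolittle hydropathy and aromatic-residue fraction."""
    aa_counts = counts.aa_counts()
    total = sum(aa_counts.values())
    if total == 0:
        raise ValidationError("no residues to translate")
    gravy = sum(HYDROPATHY[aa] * c for aa, c in aa_counts.items()) / total
    aromo = sum(c for aa, c in aa_counts.items() if aa in AROMATIC_AAS) / total
    return gravy, aromo


def composition_profile(seq: CodingSequence) -> CompositionProfile:
    """The full per-record profile (composition + ENc + protein indices)."""
    comp = nucleotide_composition(seq)
    counts = count_codons([seq])[seq.id]
    gravy, aromo = gravy_aromo(counts)
    l_aa = counts.total_sense()
    l_sym = l_aa - sum(
        counts.counts[c] for aa in SINGLE_CODON_AAS for c in FAMILIES[aa]
    )
    return CompositionProfile(
        id=seq.id,
        subgroup=seq.subgroup,
        ENc=effective_number_of_codons(counts),
        L_sym=l_sym,
        L_aa=l_aa,
        Gravy=gravy,
        Aromo=aromo,
        **comp,
    )


def profiles_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame indexed by record id."""
    rows = []
    for p in profiles:
        row = {f.name: getattr(p, f.name) for f in dataclass_fields(p)}
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def composition_summary(
    profiles: list[CompositionProfile], by_subgroup: bool = True
) -> pd.DataFrame:
    """Mean and standard error of every index, per subgroup and overall.

    SE is sample standard deviation (ddof=1) over sqrt(n); a single record
    reports SE 0 and is flagged by its n=1 column entry.
    """
    if not profiles:
        raise ValidationError("no profiles to summarize")
    df = profiles_frame(profiles)
    groups: dict[str, pd.DataFrame] = {}
    if by_subgroup:
        for sg, sub in df.groupby("subgroup", dropna=False):
            key = sg if isinstance(sg, str) else "(unassigned)"
            groups[key] = sub
    groups["overall"] = df
    out: dict[str, list] = {"index": list(PROFILE_FIELDS)}
    for name, sub in groups.items():
        means, ses = [], []
        n = len(sub)
        for field in PROFILE_FIELDS:
            vals = sub[field].astype(float)
            means.append(vals.mean())
            ses.append(0.0 if n == 1 else vals.std(ddof=1) / math.sqrt(n))
        out[f"{name} mean"] = means
        out[f"{name} se"] = ses
        out[f"{name} n"] = [n] * len(PROFILE_FIELDS)
    return pd.DataFrame(out).set_index("index")
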