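"""Synthetic coding sequences and host tables with controlled codon usage.

Three codon-choice models are supported:

- ``target-rscu``: amino acids drawn from a composition, codons drawn from
  the family-conditional frequencies implied by a target RSCU table. RSCU
  targets are therefore exactly invertible in expectation.
- ``mutation-pressure``: codons drawn from the 61 sense codons with
  probability proportional to the product of per-base weights at all three
  positions, per-record GC bias beta; both GC12 and GC3 track beta, which
  is what gives the neutrality regression a slope near 1.
- ``third-position-selection``: amino-acid composition fixed, only the
  third base weighted by beta; GC3 varies while GC12 stays flat (slope
  near 0).

All randomness flows through ``numpy.random.default_rng(seed)``; the same
spec and seed reproduce byte-identical FASTA on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .genetic_code import (
    FAMILIES,
    FAMILY_SIZE,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
)
from .seqio import (
    FIXTURE_SUBGROUP_HOSTS,
    CodingSequence,
    CodonUsageReference,
    SequenceSet,
    load_reference_rscu,
)

DEFAULT_CODONS_PER_RECORD = 223

TARGET_RSCU = "target-rscu"
MUTATION_PRESSURE = "mutation-pressure"
THIRD_POSITION_SELECTION = "third-position-selection"


@dataclass(frozen=True)
class SubgroupSpec:
    """One subgroup of a synthetic dataset."""

    name: str
    host: str
    n_records: int
    model: str
    #: target-rscu: codon -> RSCU (or family-conditional probability x n_i)
    rscu_targets: Mapping[str, float] | None = None
    #: mutation-pressure / third-position-selection: (low, high) GC bias
    beta_range: tuple[float, float] | None = None
    aa_composition: Mapping[str, float] | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic dataset: subgroups, record length, seed."""

    subgroups: tuple[SubgroupSpec, ...]
    codons_per_record: int = DEFAULT_CODONS_PER_RECORD
    terminal_stop: bool = True
    seed: int = 0


def _normalize_composition(
    composition: Mapping[str, float] | None,
) -> dict[str, float]:
    if composition is None:
        composition = {aa: 1.0 for aa in FAMILIES}
    comp = {aa: float(v) for aa, v in composition.items()}
    unknown = set(comp) - set(FAMILIES)
    if unknown:
        raise ValidationError(f"unknown amino acids in composition: {sorted(unknown)}")
    total = sum(comp.values())
    if total <= 0:
        raise ValidationError("amino-acid composition sums to zero")
    return {aa: v / total for aa, v in comp.items()}


def _family_conditionals(rscu_targets: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Per-family codon probabilities implied by RSCU targets."""
    out: dict[str, np.ndarray] = {}
    for aa, codons in FAMILIES.items():
        vals = np.array([float(rscu_targets.get(c, 1.0)) for c in codons])
        if (vals < 0).any():
            raise ValidationError(f"negative RSCU target in family {aa}")
        total = vals.sum()
        if total == 0:
            raise ValidationError(f"family {aa}: all RSCU targets zero")
        out[aa] = vals / total
    return out


def _validate_rscu_targets(rscu_targets: Mapping[str, float]) -> None:
    """Family sums must equal n_i (targets are RSCU values, tolerantly)."""
    for aa, codons in FAMILIES.items():
        present = [c for c in codons if c in rscu_targets]
        if not present:
            continue
        total = sum(float(rscu_targets[c]) for c in present)
        if abs(total - FAMILY_SIZE[aa]) > 0.25:
            raise ValidationError(
                f"RSCU targets for {aa} sum to {total:.3f}, expected ~{FAMILY_SIZE[aa]}"
            )


def _mutation_pressure_probs(beta: float) -> np.ndarray:
    """Codon probabilities over the 61 sense codons at GC bias beta."""
    base_w = {"G": beta / 2, "C": beta / 2, "A": (1 - beta) / 2, "U": (1 - beta) / 2}
    w = np.array(
        [base_w[c[0]] * base_w[c[1]] * base_w[c[2]] for c in SENSE_CODONS]
    )
    return w / w.sum()


def _third_position_conditionals(beta: float) -> dict[str, np.ndarray]:
    """Family conditionals with only the third base weighted by beta."""
    base_w = {"G": beta / 2, "C": beta / 2, "A": (1 - beta) / 2, "U": (1 - beta) / 2}
    out: dict[str, np.ndarray] = {}
    for aa, codons in FAMILIES.items():
        w = np.array([base_w[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _draw_record(
    rng: np.random.Generator,
    sub: SubgroupSpec,
    n_codons: int,
) -> tuple[str, ...]:
    if sub.model == MUTATION_PRESSURE:
        lo, hi = sub.beta_range or (0.3, 0.7)
        beta = rng.uniform(lo, hi)
        probs = _mutation_pressure_probs(beta)
        idx = rng.choice(len(SENSE_CODONS), size=n_codons, p=probs)
        return tuple(SENSE_CODONS[i] for i in idx)
    composition = _normalize_composition(sub.aa_composition)
    aas = list(composition)
    aa_probs = np.array([composition[a] for a in aas])
    if sub.model == TARGET_RSCU:
        if sub.rscu_targets is None:
            raise ValidationError(f"subgroup {sub.name}: target-rscu model needs targets")
        conditionals = _family_conditionals(sub.rscu_targets)
    elif sub.model == THIRD_POSITION_SELECTION:
        lo, hi = sub.beta_range or (0.2, 0.8)
        beta = rng.uniform(lo, hi)
        conditionals = _third_position_conditionals(beta)
    else:
        raise ValidationError(f"unknown codon-choice model {sub.model!r}")
    aa_idx = rng.choice(len(aas), size=n_codons, p=aa_probs)
    codons = []
    for i in aa_idx:
        aa = aas[i]
        fam = FAMILIES[aa]
        codons.append(fam[rng.choice(len(fam), p=conditionals[aa])])
    return tuple(codons)


def generate_set(
    spec: SyntheticSpec,
) -> tuple[SequenceSet, dict[str, tuple[str, str]], dict]:
    """Generate sequences, the matching group map, and a truth record.

    The truth record stores, per subgroup, the generating model and its
    parameters, for use in parameter-recovery tests.
    """
    if not spec.subgroups:
        raise ValidationError("spec has no subgroups")
    if spec.codons_per_record < 1:
        raise ValidationError("codons_per_record must be >= 1")
    for sub in spec.subgroups:
        if sub.n_records < 1:
            raise ValidationError(f"subgroup {sub.name}: n_records must be >= 1")
        if sub.rscu_targets is not None:
            _validate_rscu_targets(sub.rscu_targets)
    rng = np.random.default_rng(spec.seed)
    records: list[CodingSequence] = []
    group_map: dict[str, tuple[str, str]] = {}
    truth: dict = {"seed": spec.seed, "codons_per_record": spec.codons_per_record, "subgroups": {}}
    for sub in spec.subgroups:
        truth["subgroups"][sub.name] = {
            "host": sub.host,
            "n_records": sub.n_records,
            "model": sub.model,
            "beta_range": list(sub.beta_range) if sub.beta_range else None,
            "rscu_targets": dict(sub.rscu_targets) if sub.rscu_targets else None,
            "aa_composition": dict(sub.aa_composition) if sub.aa_composition else None,
        }
        for i in range(sub.n_records):
            rid = f"{sub.name}_{i+1:03d}"
            codons = _draw_record(rng, sub, spec.codons_per_record)
            records.append(
                CodingSequence(
                    id=rid,
                    codons=codons,
                    subgroup=sub.name,
                    host=sub.host,
                    had_terminal_stop=spec.terminal_stop,
                )
            )
            group_map[rid] = (sub.name, sub.host)
    return SequenceSet(records), group_map, truth


def generate_host_table(
    mode: str = "uniform",
    favored: Sequence[str] = (),
    rscu_targets: Mapping[str, float] | None = None,
    total_per_family: int = 1000,
    favored_share: float = 0.7,
    source_label: str = "synthetic-host",
) -> CodonUsageReference:
    """A synthetic host codon-usage counts table.

    Modes: ``uniform`` (all RSCU 1), ``favor-set`` (each codon in
    ``favored`` takes ``favored_share`` of its family's counts, making it
    the family optimum), ``from-rscu`` (counts proportional to the given
    RSCU targets).
    """
    counts: dict[str, float] = {}
    favored_set = set(favored)
    unknown = favored_set - set(SENSE_CODONS)
    if unknown:
        raise ValidationError(f"unknown favored codons: {sorted(unknown)}")
    for aa, codons in FAMILIES.items():
        n = len(codons)
        fam_favored = [c for c in codons if c in favored_set]
        if mode == "uniform" or aa in SINGLE_CODON_AAS:
            for c in codons:
                counts[c] = total_per_family / n
        elif mode == "favor-set":
            if not fam_favored:
                for c in codons:
                    counts[c] = total_per_family / n
            else:
                rest = n - len(fam_favored)
                for c in codons:
                    if c in fam_favored:
                        counts[c] = total_per_family * favored_share / len(fam_favored)
                    else:
                        counts[c] = total_per_family * (1 - favored_share) / rest
        elif mode == "from-rscu":
            if rscu_targets is None:
                raise ValidationError("from-rscu mode needs rscu_targets")
            vals = [float(rscu_targets.get(c, 1.0)) for c in codons]
            total = sum(vals)
            for c, v in zip(codons, vals):
                counts[c] = total_per_family * v / total if total > 0 else 0.0
        else:
            raise ValidationError(f"unknown host-table mode {mode!r}")
    return CodonUsageReference(
        source_label=source_label, values=counts, dialect="plain-tsv"
    )


def calibrate_aa_composition(
    rscu_targets: Mapping[str, float],
    target_gc3: float,
    mw_weight: float = 0.014,
) -> dict[str, float]:
    """An amino-acid composition whose expected GC3 equals ``target_gc3``.

    Met/Trp are pinned at ``mw_weight`` each (their third base is G); the
    remaining 18 families start uniform and are exponentially tilted by
    their per-family expected third-base G+C until the overall expectation
    matches, via bisection on the tilt parameter.
    """
    conditionals = _family_conditionals(rscu_targets)
    fam_gc3 = {}
    for aa, codons in FAMILIES.items():
        probs = conditionals[aa]
        fam_gc3[aa] = float(
            sum(p for p, c in zip(probs, codons) if c[2] in "GC")
        )
    free = [aa for aa in FAMILIES if aa not in SINGLE_CODON_AAS]
    free_mass = 1.0 - mw_weight * len(SINGLE_CODON_AAS)

    def expected_gc3(lam: float) -> float:
        w = np.array([np.exp(-lam * fam_gc3[aa]) for aa in free])
        w = w / w.sum() * free_mass
        e = float(sum(wi * fam_gc3[aa] for wi, aa in zip(w, free)))
        e += sum(mw_weight * fam_gc3[aa] for aa in SINGLE_CODON_AAS)
        return e

    lo, hi = -50.0, 50.0
    if not expected_gc3(hi) <= target_gc3 <= expected_gc3(lo):
        raise ValidationError(
            f"target GC3 {target_gc3} unreachable for these RSCU targets"
        )
    for _ in range(200):
        mid = (lo + hi) / 2
        if expected_gc3(mid) > target_gc3:
            lo = mid
        else:
            hi = mid
    lam = (lo + hi) / 2
    w = np.array([np.exp(-lam * fam_gc3[aa]) for aa in free])
    w = w / w.sum() * free_mass
    comp = {aa: float(wi) for aa, wi in zip(free, w)}
    for aa in SINGLE_CODON_AAS:
        comp[aa] = mw_weight
    return comp


def ctv_emulation_spec(seed: int = 0, target_gc3: float = 0.385) -> SyntheticSpec:
    """The packaged-table emulation preset: three subgroups of 29/38/55
    records x 223 codons, codon choice targeting the published subgroup
    RSCU columns, amino-acid composition calibrated so per-record GC3 lands
    in the published band (~0.36-0.41)."""
    df = load_reference_rscu()
    sizes = {"Ca-CTV": 29, "Cr-CTV": 38, "Cs-CTV": 55}
    subs = []
    for name, n in sizes.items():
        targets = df[name].to_dict()
        subs.append(
            SubgroupSpec(
                name=name,
                host=FIXTURE_SUBGROUP_HOSTS[name],
                n_records=n,
                model=TARGET_RSCU,
                rscu_targets=targets,
                aa_composition=calibrate_aa_composition(targets, target_gc3),
            )
        )
    return SyntheticSpec(subgroups=tuple(subs), seed=seed)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
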