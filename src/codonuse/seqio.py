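"""Reading, validating and counting coding sequences and codon-usage tables.

The internal alphabet is RNA; DNA input is accepted and T is normalized to U
on read. Terminal stop codons are detected, flagged, and excluded from all
downstream counting. Codons containing IUPAC ambiguity codes are kept on the
record but skipped by every statistic (no defensible assignment exists).
"""

from __future__ import annotations

import re
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .genetic_code import (
    AA_THREE_TO_ONE,
    AMBIGUITY_CODES,
    CODON_TO_AA,
    FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    is_unambiguous,
)

_FIXTURE_RESOURCE = "ctv_citrus_rscu.tsv"

#: default subgroup -> host pairing of the packaged reference table
FIXTURE_SUBGROUP_HOSTS: dict[str, str] = {
    "Ca-CTV": "C.aurantifolia",
    "Cr-CTV": "C.reticulata",
    "Cs-CTV": "C.sinensis",
}


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence split into RNA codons."""

    id: str
    codons: tuple[str, ...]
    subgroup: str | None = None
    host: str | None = None
    had_terminal_stop: bool = False

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValidationError(f"record {self.id!r}: empty coding sequence")
        for i, codon in enumerate(self.codons):
            if len(codon) != 3 or any(b not in "ACGU" and b not in AMBIGUITY_CODES for b in codon):
                raise ValidationError(f"record {self.id!r}: bad codon {codon!r} at position {i}")
            if is_unambiguous(codon) and codon in STOP_CODONS:
                raise ValidationError(
                    f"record {self.id!r}: internal stop codon {codon} at codon position {i}"
                )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        """Unambiguous codons only (the ones every statistic sees)."""
        return tuple(c for c in self.codons if is_unambiguous(c))

    def with_labels(self, subgroup: str, host: str) -> "CodingSequence":
        return replace(self, subgroup=subgroup, host=host)


class SequenceSet:
    """An ordered collection of CodingSequence records with unique ids."""

    def __init__(self, records: Iterable[CodingSequence]):
        self.records: list[CodingSequence] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CodingSequence:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def subgroups(self) -> list[str]:
        return sorted({rec.subgroup for rec in self.records if rec.subgroup is not None})

    def by_subgroup(self) -> dict[str, "SequenceSet"]:
        out: dict[str, list[CodingSequence]] = {}
        for rec in self.records:
            out.setdefault(rec.subgroup or "(unassigned)", []).append(rec)
        return {k: SequenceSet(v) for k, v in out.items()}

    def with_group_map(self, mapping: Mapping[str, tuple[str, str]]) -> "SequenceSet":
        """Attach subgroup/host labels; error listing any unmapped ids."""
        missing = [rec.id for rec in self.records if rec.id not in mapping]
        if missing:
            raise ValidationError(
                "ids present in FASTA but absent from group map: " + ", ".join(missing)
            )
        return SequenceSet(
            rec.with_labels(*mapping[rec.id]) for rec in self.records
        )


def split_codons(seq: str, record_id: str = "?") -> tuple[tuple[str, ...], bool]:
    """Normalize a nucleotide string to RNA codons.

    Returns (codons, had_terminal_stop); the terminal stop is removed from
    the returned codon list.
    """
    s = seq.upper().replace("T", "U").replace("-", "")
    if not s:
        raise ValidationError(f"record {record_id!r}: empty sequence")
    if len(s) % 3 != 0:
        raise ValidationError(
            f"record {record_id!r}: length {len(s)} not a multiple of 3"
        )
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    had_stop = codons[-1] in STOP_CODONS
    if had_stop:
        codons = codons[:-1]
    if not codons:
        raise ValidationError(f"record {record_id!r}: sequence is a lone stop codon")
    return tuple(codons), had_stop


def read_fasta(path: str | Path, drop_invalid: bool = False) -> SequenceSet:
    """Read a multi-record FASTA of coding sequences.

    DNA or RNA accepted; T normalized to U; the terminal stop codon, when
    present, is stripped and flagged on the record. With ``drop_invalid``,
    records failing validation are excluded with a warning instead of
    raising.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    records: list[CodingSequence] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        try:
            codons, had_stop = split_codons(str(rec.seq), rec.id)
            records.append(
                CodingSequence(id=rec.id, codons=codons, had_terminal_stop=had_stop)
            )
        except ValidationError as exc:
            if drop_invalid:
                warnings.warn(f"dropping record {rec.id!r}: {exc}", stacklevel=2)
            else:
                raise
    if not records:
        raise ValidationError(f"no usable records in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write records back to FASTA (RNA alphabet, terminal stop restored)."""
    out = []
    for rec in seqs:
        seq = "".join(rec.codons) + ("UAA" if rec.had_terminal_stop else "")
        out.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    _BioSeqIO.write(out, str(Path(path)), "fasta")


def read_group_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV of ``id<TAB>subgroup[<TAB>host]`` into id -> (subgroup, host)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    mapping: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) not in (2, 3):
            raise ValidationError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
        rid, subgroup = fields[0].strip(), fields[1].strip()
        host = fields[2].strip() if len(fields) == 3 else ""
        if rid in mapping:
            raise ValidationError(f"{path}:{lineno}: duplicate id {rid!r} in group map")
        mapping[rid] = (subgroup, host)
    if not mapping:
        raise ValidationError(f"empty group map: {path}")
    return mapping


@dataclass(frozen=True)
class CodonCountTable:
    """Integer codon counts over all 64 codons.

    Ambiguous codons and (by policy) terminal stops never enter a table, so
    stop counts are normally zero, but the slots exist for completeness.
    """

    counts: Mapping[str, int]
    scope: str = "single-record"
    label: str | None = None

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in CODON_TO_AA}
        unknown = set(self.counts) - set(CODON_TO_AA)
        if unknown:
            raise ValidationError(f"unknown codon tokens: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValidationError("negative codon count")
        object.__setattr__(self, "counts", full)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in self.counts}
        return CodonCountTable(merged, scope="pooled-subgroup", label=self.label)

    def total(self) -> int:
        return sum(self.counts.values())

    def total_sense(self) -> int:
        return sum(self.counts[c] for c in SENSE_CODONS)

    def aa_counts(self) -> dict[str, int]:
        """Observed amino-acid frequencies f_j (stops excluded)."""
        out = {aa: 0 for aa in FAMILIES}
        for codon in SENSE_CODONS:
            out[CODON_TO_AA[codon]] += self.counts[codon]
        return out


def count_codons(
    seqs: SequenceSet | Iterable[CodingSequence],
    pooled: bool = False,
) -> dict[str, CodonCountTable]:
    """Codon count tables per record; with ``pooled``, one per subgroup.

    Terminal stops were already stripped on read; ambiguous codons are
    skipped. Pooled tables are element-wise sums of the member tables.
    """
    records = list(seqs)
    if not records:
        raise ValidationError("no records to count")
    per_record = {
        rec.id: CodonCountTable(
            _tally(rec.sense_codons), scope="single-record", label=rec.id
        )
        for rec in records
    }
    if not pooled:
        return per_record
    pools: dict[str, CodonCountTable] = {}
    for rec in records:
        key = rec.subgroup or "(unassigned)"
        table = per_record[rec.id]
        pools[key] = pools[key] + table if key in pools else CodonCountTable(
            table.counts, scope="pooled-subgroup", label=key
        )
    return pools


def _tally(codons: Sequence[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for c in codons:
        out[c] = out.get(c, 0) + 1
    return out


@dataclass(frozen=True)
class CodonUsageReference:
    """A host codon-usage table: counts, per-thousand frequencies, or RSCU.

    ``dialect`` records how the file was parsed: ``plain-tsv`` and
    ``kazusa-style`` store (pseudo-)counts; ``rscu-direct`` stores RSCU
    values as published.
    """

    source_label: str
    values: Mapping[str, float]
    dialect: str

    def __post_init__(self) -> None:
        full = dict(self.values)
        unknown = {
            c for c in full if c not in CODON_TO_AA or c in STOP_CODONS
        }
        if unknown:
            raise ValidationError(
                f"{self.source_label}: unknown or stop codon tokens: {sorted(unknown)}"
            )
        missing = [c for c in SENSE_CODONS if c not in full]
        if missing:
            if self.dialect == "rscu-direct":
                raise ValidationError(
                    f"{self.source_label}: rscu-direct table missing codons: {missing}"
                )
            warnings.warn(
                f"{self.source_label}: {len(missing)} sense codons missing, filled with 0",
                stacklevel=2,
            )
            for c in missing:
                full[c] = 0.0
        if any(v < 0 for v in full.values()):
            raise ValidationError(f"{self.source_label}: negative codon value")
        object.__setattr__(self, "values", {c: float(full[c]) for c in SENSE_CODONS})

    @property
    def is_rscu(self) -> bool:
        return self.dialect == "rscu-direct"


_KAZUSA_ENTRY = re.compile(r"([ACGUT]{3})\s+([0-9.]+)\s*(?:\(\s*([0-9]+)\s*\))?")

#: per-thousand frequencies are scaled by this factor into pseudo-counts
KAZUSA_FREQ_SCALE = 1000.0


def read_codon_usage_table(
    path: str | Path,
    dialect: str = "plain-tsv",
    source_label: str | None = None,
) -> CodonUsageReference:
    """Parse a host codon-usage table.

    Dialects:

    - ``plain-tsv``: lines of ``codon<TAB>count`` (count may be real).
    - ``kazusa-style``: free-form entries ``CODON freq( count)``; the
      parenthesised count is used when present, otherwise the per-thousand
      frequency is scaled by ``KAZUSA_FREQ_SCALE``.
    - ``rscu-direct``: lines of ``codon<TAB>rscu`` covering all 61 sense
      codons.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if dialect not in ("plain-tsv", "kazusa-style", "rscu-direct"):
        raise ValidationError(f"unknown codon-usage dialect {dialect!r}")
    label = source_label or path.stem
    text = path.read_text()
    values: dict[str, float] = {}

    def put(codon: str, value: float) -> None:
        codon = codon.upper().replace("T", "U")
        if codon in values:
            raise ValidationError(f"{path}: duplicate codon {codon}")
        values[codon] = value

    if dialect == "kazusa-style":
        for m in _KAZUSA_ENTRY.finditer(text):
            codon, freq, count = m.groups()
            put(codon, float(count) if count is not None else float(freq) * KAZUSA_FREQ_SCALE)
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected codon<TAB>value")
            token = fields[0].strip().upper().replace("T", "U")
            if token not in CODON_TO_AA:
                raise ValidationError(f"{path}:{lineno}: unknown codon token {fields[0]!r}")
            put(token, float(fields[1]))
    return CodonUsageReference(source_label=label, values=values, dialect=dialect)


def load_reference_rscu() -> pd.DataFrame:
    """The packaged published RSCU table (virus subgroups + citrus hosts).

    Returns a DataFrame indexed by codon with an ``aa`` column (one-letter)
    and one RSCU column per source, exactly as published (2 decimals).
    """
    with resources.files("codonuse.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["aa"] = df["aa"].map(AA_THREE_TO_ONE)
    return df.set_index("codon")


def fixture_rscu_reference(column: str) -> CodonUsageReference:
    """One column of the packaged table as an rscu-direct reference."""
    df = load_reference_rscu()
    if column not in df.columns:
        raise ValidationError(f"no such column in packaged RSCU table: {column!r}")
    return CodonUsageReference(
        source_label=column,
        values=df[column].to_dict(),
        dialect="rscu-direct",
    )
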