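"""Standard genetic code tables and amino-acid scales used across the package.

All codons are RNA triplets over {A, C, G, U}. The standard nuclear code
(translation table 1) is used throughout.
"""

from __future__ import annotations

from itertools import product

BASES = "UCAG"

#: codon -> one-letter amino acid, '*' for stop (standard code, RNA alphabet)
CODON_TO_AA: dict[str, str] = {}
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"  # U--
    "LLLLPPPPHHQQRRRR"  # C--
    "IIIMTTTTNNKKSSRR"  # A--
    "VVVVAAAADDEEGGGG"  # G--
)
for _i, (_b1, _b2, _b3) in enumerate(product(BASES, BASES, BASES)):
    CODON_TO_AA[_b1 + _b2 + _b3] = _AA_ORDER[_i]

ALL_CODONS: tuple[str, ...] = tuple(CODON_TO_AA)
STOP_CODONS: frozenset[str] = frozenset(c for c, a in CODON_TO_AA.items() if a == "*")
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (stops excluded)
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

FAMILY_SIZE: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: single-codon families: carry no synonymous-choice information
SINGLE_CODON_AAS: frozenset[str] = frozenset(a for a, n in FAMILY_SIZE.items() if n == 1)

#: the 59 codons informative for synonymous codon usage (Met/Trp excluded)
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: degeneracy class -> amino acids, as used by Wright's ENc estimator
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _n in FAMILY_SIZE.items():
    if _n > 1:
        DEGENERACY_CLASSES.setdefault(_n, ())
        DEGENERACY_CLASSES[_n] += (_aa,)

AA_ONE_TO_THREE: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA_THREE_TO_ONE: dict[str, str] = {v: k for k, v in AA_ONE_TO_THREE.items()}

#: Kyte-Doolittle hydropathy scale
HYDROPATHY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC_AAS: frozenset[str] = frozenset("FYW")

#: IUPAC ambiguity codes that may appear in public sequence data
AMBIGUITY_CODES: frozenset[str] = frozenset("RYSWKMBDHVN")


def is_unambiguous(codon: str) -> bool:
    """True if the codon is a clean triplet over {A, C, G, U}."""
    return len(codon) == 3 and all(b in "ACGU" for b in codon)


def translate(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop.

    Raises KeyError for codons containing ambiguity codes.
    """
    return CODON_TO_AA[codon]
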