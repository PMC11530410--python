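"""Grantham physicochemical distances between amino acids.

The Grantham distance combines three residue properties — atomic composition
``c``, polarity ``p`` and molecular volume ``v`` — into

    D_ij = rho * [alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2 + gamma*(v_i - v_j)^2]^(1/2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho chosen so that the
mean distance over the 190 unordered pairs of standard residues equals 100.
Distances are reported on the customary integer grid (identical residues
score 0; the most radical substitution, Cys–Trp, scores 215; the mildest,
Leu–Ile, scores 5).

The property table ships with the package as ``data/grantham_properties.tsv``;
the integer matrix is derived from it at import time.
"""

from __future__ import annotations

import itertools
from importlib import resources

import pandas as pd

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}


def _load_properties() -> dict[str, tuple[float, float, float]]:
    with resources.files("loadscape.data").joinpath("grantham_properties.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {
        row.aa: (float(row.composition), float(row.polarity), float(row.volume))
        for row in df.itertuples()
    }


PROPERTIES: dict[str, tuple[float, float, float]] = _load_properties()
STANDARD_AA = tuple(sorted(PROPERTIES))


def _raw_distance(a: str, b: str) -> float:
    ca, pa, va = PROPERTIES[a]
    cb, pb, vb = PROPERTIES[b]
    return (ALPHA * (ca - cb) ** 2 + BETA * (pa - pb) ** 2 + GAMMA * (va - vb) ** 2) ** 0.5


def _mean_normalizer() -> float:
    pairs = list(itertools.combinations(STANDARD_AA, 2))
    return 100.0 * len(pairs) / sum(_raw_distance(a, b) for a, b in pairs)


RHO = _mean_normalizer()

#: integer Grantham distance for every unordered residue pair
GRANTHAM_MATRIX: dict[frozenset[str], int] = {
    frozenset((a, b)): round(RHO * _raw_distance(a, b))
    for a, b in itertools.combinations(STANDARD_AA, 2)
}


def normalize_aa(aa: str) -> str:
    """Accept one-letter or three-letter residue codes; return one-letter."""
    aa = aa.strip()
    if len(aa) == 3:
        aa = AA3_TO_1.get(aa.capitalize(), aa)
    aa = aa.upper()
    if aa not in PROPERTIES:
        raise ValueError(f"{aa!r} is not a standard amino acid")
    return aa


def grantham_score(aa_i: str, aa_j: str) -> int:
    """Integer Grantham distance between two standard amino acids.

    Symmetric; identical residues score 0.
    """
    a, b = normalize_aa(aa_i), normalize_aa(aa_j)
    if a == b:
        return 0
    return GRANTHAM_MATRIX[frozenset((a, b))]
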