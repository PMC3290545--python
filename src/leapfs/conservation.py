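"""Residue conservation scores and the lumped site-conservation p-value.

Column conservation is the normalized Shannon entropy over a 22-letter
alphabet (20 amino acids, gap, wildcard):

    H      = -sum_i p_i ln p_i          (natural log; base cancels)
    H.norm = 1 - H / ln(22)

so a single-symbol column scores 1 (most conserved) and a maximally
diverse column 0.

Within a domain, residues are ranked by H.norm in descending order
(most conserved first, ties averaged).  Two rank conventions are used
downstream:

* *percentile rank* = rank / N in (0, 1], 1/N for the most conserved —
  the quantity whose product over a site's L residues forms the lumped
  score z;
* *fractional conservation* in [0, 1], 0 = least and 1 = most
  conserved, used for per-residue reporting.

Under a null in which site residues are drawn at random, z is a product
of L independent Uniform(0,1) variables, so

    P(z, L) = Pr(prod U_i <= z) = z * sum_{k=0}^{L-1} (-ln z)^k / k!

which equals the upper regularized incomplete gamma function
Q(L, -ln z) and is evaluated that way for numerical robustness.

Conservation is only computed from family alignments with at least
``MIN_CONSERVATION_SEQUENCES`` (default 10) sequences.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaincc
from scipy.stats import rankdata

from ._aa import THREE_TO_ONE

logger = logging.getLogger(__name__)

#: 22-symbol alphabet: 20 amino acids + gap + wildcard
ALPHABET = set(THREE_TO_ONE.values()) | {"-", "X"}
LN_ALPHABET = math.log(22)
MIN_CONSERVATION_SEQUENCES = 10


class AlignmentTooSmall(ValueError):
    """Raised when an alignment has too few sequences to score."""


def column_entropy(column: Iterable[str]) -> float:
    """H.norm of one alignment column (1 = fully conserved).

    Symbols outside the 22-letter alphabet are mapped to the wildcard
    with a warning; ``.`` counts as a gap.
    """
    symbols = []
    for ch in column:
        c = ch.upper()
        if c == ".":
            c = "-"
        if c not in ALPHABET:
            logger.warning("symbol %r outside the 22-letter alphabet; treated as wildcard", ch)
            c = "X"
        symbols.append(c)
    if not symbols:
        raise ValueError("empty column")
    counts = np.array(list(Counter(symbols).values()), dtype=float)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return 1.0 - h / LN_ALPHABET


def alignment_entropy(rows: Sequence[str]) -> np.ndarray:
    """H.norm per column of an aligned block of equal-length rows."""
    if not rows:
        raise ValueError("empty alignment")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValueError("rows have unequal lengths")
    return np.array([column_entropy(r[c] for r in rows) for c in range(ncol)])


def rank_residues(hnorm_values: Sequence[float]) -> np.ndarray:
    """Percentile rank per residue: rank/N descending, ties averaged.

    The most conserved residue of N gets 1/N; the least conserved 1.0.
    """
    v = np.asarray(hnorm_values, dtype=float)
    if v.size == 0:
        raise ValueError("no scored residues")
    ranks = rankdata(-v, method="average")
    return ranks / v.size


def fractional_conservation(hnorm_values: Sequence[float]) -> np.ndarray:
    """Fractional conservation in [0, 1]: 0 = least, 1 = most conserved.

    Ties are averaged; a run of all-equal scores maps to 0.5.
    """
    v = np.asarray(hnorm_values, dtype=float)
    if v.size == 0:
        raise ValueError("no scored residues")
    if v.size == 1:
        return np.array([0.5])
    ranks = rankdata(v, method="average")
    return (ranks - 1.0) / (v.size - 1.0)


@dataclass(frozen=True)
class LumpedScore:
    site_id: str
    L: int
    z: float
    p_value: float


def lumped_score(percentiles: Sequence[float], site_id: str = "") -> LumpedScore:
    """Product of a site's residue percentile ranks, with its p-value.

    Residues without conservation data must be excluded by the caller;
    they do not contribute to L.
    """
    pct = np.asarray(percentiles, dtype=float)
    if pct.size == 0:
        raise ValueError("no scored residues in site")
    if np.any(pct <= 0) or np.any(pct > 1):
        raise ValueError("percentile ranks must lie in (0, 1]")
    z = float(np.exp(np.sum(np.log(pct))))
    return LumpedScore(site_id, int(pct.size), z, lumped_pvalue(z, int(pct.size)))


def lumped_pvalue(z: float, L: int) -> float:
    """P(product of L iid Uniform(0,1) <= z) = Q(L, -ln z)."""
    if not 0.0 < z <= 1.0:
        raise ValueError(f"z must lie in (0, 1], got {z}")
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    return float(gammaincc(L, -math.log(z)))


def conservation_profile(
    family_rows: dict[str, str],
    min_sequences: int = MIN_CONSERVATION_SEQUENCES,
) -> np.ndarray:
    """Per-column H.norm of a family alignment.

    Raises :class:`AlignmentTooSmall` when fewer than ``min_sequences``
    rows are available (the alignment is then not usable for
    conservation scoring).
    """
    if len(family_rows) < min_sequences:
        raise AlignmentTooSmall(
            f"conservation needs >= {min_sequences} sequences, got {len(family_rows)}"
        )
    return alignment_entropy(list(family_rows.values()))
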