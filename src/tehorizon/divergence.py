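"""Kimura 2-parameter divergence, repeat landscapes, and the neutral clock.

Copy divergence from a subfamily consensus dates the insertion: under a
neutral clock with per-site rate ``r`` (substitutions/site/generation) and
``g`` generations per year, a K2P distance ``K`` converts to an insertion
age ``T = K / (2 r g)``. The default clock is the lepidopteran estimate
r = 2.9e-9 with one generation per year.

The landscape tabulates annotated bases (and copy counts) by divergence
bin per species and subfamily — the tabular equivalent of the classic
repeat-landscape plot, with a parallel age axis from the clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .formats_io import AnnotatedCopy

__all__ = [
    "SiteCounts", "ClockParameters", "DivergenceEstimate", "DEFAULT_CLOCK",
    "SaturationError", "k2p_from_counts", "k2p_from_alignment",
    "divergence_to_age", "age_to_divergence", "landscape",
]


class SaturationError(ValueError):
    """Distance undefined: substitutions have saturated the K2P correction."""


@dataclass(frozen=True)
class SiteCounts:
    """Tallied aligned sites: comparable columns, transitions, transversions."""

    compared_sites: int
    transitions: int
    transversions: int

    def __post_init__(self):
        if min(self.compared_sites, self.transitions, self.transversions) < 0:
            raise ValueError("negative site counts")
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("differences exceed compared sites")


@dataclass(frozen=True)
class ClockParameters:
    """Neutral molecular clock: rate per site per generation, generations/yr."""

    rate_r: float = 2.9e-9
    generations_per_year: float = 1.0

    def __post_init__(self):
        if self.rate_r <= 0 or self.generations_per_year <= 0:
            raise ValueError("clock parameters must be positive")


DEFAULT_CLOCK = ClockParameters()


@dataclass(frozen=True)
class DivergenceEstimate:
    K: float        # substitutions per site
    age_my: float   # insertion age under the clock, My

    def __post_init__(self):
        if self.K < 0 or self.age_my < 0:
            raise ValueError("negative divergence or age")


def divergence_to_age(K: float, clock: ClockParameters = DEFAULT_CLOCK
                      ) -> float:
    """Convert a divergence ``K`` to an age in My via ``T = K / 2r``."""
    if K < 0:
        raise ValueError("K must be >= 0")
    years = K / (2.0 * clock.rate_r * clock.generations_per_year)
    return years / 1e6


def age_to_divergence(age_my: float,
                      clock: ClockParameters = DEFAULT_CLOCK) -> float:
    """Inverse of :func:`divergence_to_age`."""
    return 2.0 * clock.rate_r * clock.generations_per_year * age_my * 1e6


def k2p_from_counts(counts: SiteCounts,
                    clock: ClockParameters = DEFAULT_CLOCK
                    ) -> DivergenceEstimate:
    """Kimura 2-parameter distance from site tallies.

    With P and Q the transition and transversion proportions,
    ``K = -(1/2) ln[(1 - 2P - Q) sqrt(1 - 2Q)]``. Raises
    :class:`SaturationError` when the logarithm's arguments are
    non-positive.
    """
    if counts.compared_sites == 0:
        raise ValueError("no comparable sites")
    P = counts.transitions / counts.compared_sites
    Q = counts.transversions / counts.compared_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4g}, Q={Q:.4g}")
    K = -0.5 * math.log(w1 * math.sqrt(w2))
    K = max(K, 0.0)
    return DivergenceEstimate(K=K, age_my=divergence_to_age(K, clock))


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


def tally_alignment(seq_a: str, seq_b: str) -> SiteCounts:
    """Column tallies for an aligned pair; gap/ambiguous columns excluded."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences differ in length")
    a = seq_a.upper()
    b = seq_b.upper()
    compared = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        compared += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return SiteCounts(compared_sites=compared, transitions=ts,
                      transversions=tv)


def k2p_from_alignment(seq_a: str, seq_b: str,
                       clock: ClockParameters = DEFAULT_CLOCK
                       ) -> DivergenceEstimate:
    """K2P distance from an aligned nucleotide pair.

    Columns containing a gap or non-ACGT symbol in either sequence are
    excluded from the compared sites. Raises ``ValueError`` when no
    comparable columns remain.
    """
    counts = tally_alignment(seq_a, seq_b)
    if counts.compared_sites == 0:
        raise ValueError("no comparable columns in alignment")
    return k2p_from_counts(counts, clock)


def landscape(copies: Iterable[AnnotatedCopy],
              bin_width: float = 0.01,
              clock: ClockParameters = DEFAULT_CLOCK) -> pd.DataFrame:
    """Per-(species, subfamily) histogram of TE bases by divergence bin.

    Bins are half-open ``[lo, hi)`` with the last bin closed at the top.
    Returns a DataFrame with columns species, subfamily, bin_lo, bin_hi,
    age_mid_my, bases, copies; bins are contiguous from 0 within each
    group, so per-group base totals equal the input totals.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    copies = list(copies)
    if not copies:
        return pd.DataFrame(columns=["species", "subfamily", "bin_lo",
                                     "bin_hi", "age_mid_my", "bases",
                                     "copies"])
    max_div = max(c.percent_divergence for c in copies)
    # a value exactly on an edge belongs to the bin it opens; the final
    # bin therefore covers max_div by construction
    n_bins = int(max_div / bin_width) + 1

    groups: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for c in copies:
        key = (c.species, c.subfamily)
        if key not in groups:
            groups[key] = (np.zeros(n_bins, dtype=np.int64),
                           np.zeros(n_bins, dtype=np.int64))
        idx = min(int(c.percent_divergence / bin_width), n_bins - 1)
        groups[key][0][idx] += c.length
        groups[key][1][idx] += 1

    rows = []
    for (species, subfam) in sorted(groups):
        bases, counts = groups[(species, subfam)]
        for i in range(n_bins):
            lo = i * bin_width
            mid = lo + bin_width / 2.0
            rows.append({
                "species": species, "subfamily": subfam,
                "bin_lo": lo, "bin_hi": lo + bin_width,
                "age_mid_my": divergence_to_age(mid, clock),
                "bases": int(bases[i]), "copies": int(counts[i]),
            })
    return pd.DataFrame(rows)
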