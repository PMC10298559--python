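"""Synonymous substitution rates (dS) for codon-aligned coding pairs.

dS is the quantity that separates horizontally transferred TE copies from
vertically inherited ones: synonymous sites are approximately neutral, so
ortholog dS tracks host divergence while a transferred TE pair shows a dS
far below it.

The estimator is Nei–Gojobori (1986) counting with a Jukes–Cantor
multiple-hit correction:

* per-codon synonymous site fractions, averaged over the two sequences;
* observed differences resolved by averaging over all minimal mutational
  pathways between the two codons (all orderings of the differing
  positions);
* single mutations that create a stop codon count as nonsynonymous;
* ``dS = -(3/4) ln(1 - (4/3) pS)`` with ``pS = Sd / S``.

The method choice is deliberately the simplest standard counting
estimator: the downstream horizontal-transfer test only uses dS through
ranks and quantiles, which are insensitive to the exact multiple-hit
model. The estimator entry point is pluggable should a
maximum-likelihood variant be added.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodingPair", "DsEstimate", "ng86_ds", "length_filter_pairs",
    "reciprocal_best_pairs",
]

_BASES = "ACGT"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = frozenset(standard_dna_table.stop_codons)
_AA = {c: standard_dna_table.forward_table.get(c, "*") for c in _CODONS}


def _step_synonymous(c1: str, c2: str) -> bool:
    # a mutation into (or between) stop codons is counted nonsynonymous
    return _AA[c1] == _AA[c2] and _AA[c1] != "*"


def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites in one codon (0..3), stop-mutations nonsynonymous."""
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _step_synonymous(codon, alt):
                syn += 1
        s += syn / 3.0
    return s


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over all minimal
    mutational pathways between the two codons."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _step_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        sd_total += sd
        nd_total += nd
        n_paths += 1
    return sd_total / n_paths, nd_total / n_paths


# precomputed lookup tables over the full codon alphabet
_SYN_SITES: dict[str, float] = {c: _syn_site_fraction(c) for c in _CODONS}
_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {
    (c1, c2): _pair_differences(c1, c2)
    for c1 in _CODONS for c2 in _CODONS
}

_VALID_CODON = frozenset(_CODONS)

# numpy mirrors of the tables, indexed by codon = 16*b1 + 4*b2 + b3
# with A,C,G,T -> 0..3
import numpy as np  # noqa: E402  (table construction above is pure python)

_SYN_ARR = np.array([_SYN_SITES[c] for c in _CODONS])
_SD_ARR = np.zeros((64, 64))
_ND_ARR = np.zeros((64, 64))
for _i, _c1 in enumerate(_CODONS):
    for _j, _c2 in enumerate(_CODONS):
        _SD_ARR[_i, _j], _ND_ARR[_i, _j] = _PAIR_DIFFS[(_c1, _c2)]
_STOP_IDX = np.array([c in _STOPS for c in _CODONS])

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _k, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _k
    _NT_CODE[ord(_b.lower())] = _k


def _encode_codons(seq: str) -> np.ndarray:
    """Codon indices (0..63) per codon column; 255 marks gap/ambiguity."""
    arr = _NT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    arr = arr.reshape(-1, 3).astype(np.int16)
    bad = np.any(arr > 3, axis=1)
    idx = arr[:, 0] * 16 + arr[:, 1] * 4 + arr[:, 2]
    idx[bad] = -1
    return idx


@dataclass(frozen=True)
class CodingPair:
    """A codon-aligned coding pair (TE–TE or ortholog–ortholog)."""

    id_a: str
    id_b: str
    species_a: str
    species_b: str
    aligned_cds_a: str
    aligned_cds_b: str
    kind: str  # "te_pair" | "ortholog_pair"

    def __post_init__(self):
        if self.kind not in ("te_pair", "ortholog_pair"):
            raise ValueError(f"bad pair kind {self.kind!r}")
        a, b = self.aligned_cds_a.upper(), self.aligned_cds_b.upper()
        if len(a) != len(b):
            raise ValueError(f"{self.id_a}/{self.id_b}: unequal lengths")
        if len(a) % 3 != 0:
            raise ValueError(f"{self.id_a}/{self.id_b}: length not codon-"
                             "multiple")
        for name, seq in (("a", a), ("b", b)):
            ungapped = seq.replace("-", "")
            for i in range(0, len(ungapped) - 2, 3):
                if ungapped[i:i + 3] in _STOPS and i + 3 < len(ungapped):
                    raise ValueError(
                        f"{self.id_a}/{self.id_b}: internal stop in "
                        f"sequence {name}")
        object.__setattr__(self, "aligned_cds_a", a)
        object.__setattr__(self, "aligned_cds_b", b)

    @property
    def aligned_nt(self) -> int:
        return len(self.aligned_cds_a)

    @property
    def aligned_aa(self) -> int:
        return self.aligned_nt // 3


@dataclass(frozen=True)
class DsEstimate:
    """Nei–Gojobori site/difference bookkeeping and the corrected dS."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    dS: float        # NaN when saturated
    saturated: bool

    def __post_init__(self):
        if self.S < 0 or self.N < 0 or self.Sd < 0 or self.Nd < 0:
            raise ValueError("negative NG86 counts")


def ng86_ds(pair: CodingPair) -> DsEstimate:
    """NG86 dS with Jukes–Cantor correction for one codon-aligned pair.

    Codons containing a gap or ambiguity symbol in either sequence are
    skipped. ``pS >= 3/4`` yields a saturated estimate (dS = NaN); zero
    synonymous sites raise ``ValueError``.
    """
    ia = _encode_codons(pair.aligned_cds_a)
    ib = _encode_codons(pair.aligned_cds_b)
    ok = (ia >= 0) & (ib >= 0)
    ok &= ~(_STOP_IDX[np.where(ia >= 0, ia, 0)]
            | _STOP_IDX[np.where(ib >= 0, ib, 0)])
    ia, ib = ia[ok], ib[ok]
    compared = int(ia.size)
    S = float(_SYN_ARR[ia].sum() + _SYN_ARR[ib].sum()) / 2.0
    Sd = float(_SD_ARR[ia, ib].sum())
    Nd = float(_ND_ARR[ia, ib].sum())
    N = 3.0 * compared - S
    if S <= 0.0:
        raise ValueError(f"{pair.id_a}/{pair.id_b}: zero synonymous sites")
    pS = Sd / S
    if pS >= 0.75:
        return DsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS,
                          dS=float("nan"), saturated=True)
    dS = -0.75 * math.log(1.0 - (4.0 / 3.0) * pS)
    return DsEstimate(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, dS=max(dS, 0.0),
                      saturated=False)


def length_filter_pairs(pairs: Iterable[CodingPair],
                        min_te_nt: int = 300,
                        min_orth_aa: int = 300) -> list[CodingPair]:
    """Keep TE pairs aligned over ``min_te_nt`` nucleotides and ortholog
    pairs aligned over ``min_orth_aa`` amino acids (both strict)."""
    out = []
    for p in pairs:
        if p.kind == "te_pair":
            if p.aligned_nt > min_te_nt:
                out.append(p)
        else:
            if p.aligned_aa > min_orth_aa:
                out.append(p)
    return out


def reciprocal_best_pairs(score_table) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs sharing a single-copy-ortholog identifier.

    ``score_table`` is a DataFrame (or records coercible to one) with
    columns ``query, subject, bitscore, shared_identifier``; each row is a
    directed protein hit. A pair (a, b) is kept iff b is a's best hit, a
    is b's best hit, and both best-hit rows carry the shared-identifier
    flag. Ties on bitscore break to the lexicographically smallest
    subject, so the result is deterministic.
    """
    df = pd.DataFrame(score_table)
    if df.empty:
        return []
    best: dict[str, tuple[str, bool]] = {}
    for query, grp in df.groupby("query"):
        grp = grp.sort_values(["bitscore", "subject"],
                              ascending=[False, True],
                              kind="mergesort")
        top = grp.iloc[0]
        best[query] = (top["subject"], bool(top["shared_identifier"]))
    pairs = set()
    for a, (b, flag_ab) in best.items():
        if a >= b or b not in best:
            continue
        back, flag_ba = best[b]
        if back == a and flag_ab and flag_ba:
            pairs.add((a, b))
    return sorted(pairs)
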