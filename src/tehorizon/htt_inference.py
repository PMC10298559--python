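"""Horizontal TE transfer (HTT) calling and minimal-event clustering.

A cross-species TE pair is called horizontally transferred when its dS
falls strictly below a low quantile (default 2.5%) of the ortholog dS
distribution for the same species pair: vertically inherited TEs cannot
be younger than their hosts' divergence, so an anomalously low TE dS
signals transfer.

Because a transfer predating a radiation leaves similar copies in every
descendant, raw hits overcount events. Species are first collapsed into
lineages (clades young enough, or sharing recent ortholog dS, to make
within-clade calls unreliable); within-lineage hits are discarded; the
remaining hits are clustered into the minimum number of independent
transfer events: two hits join when they connect the same unordered
lineage pair, involve the same subfamily, and on each side the copies
are similar enough to descend from a single transferred element (their
K2P nucleotide divergence is below ``2 r T_split`` for the lineage
pair's divergence time ``T_split`` — a single transfer between two
lineages must postdate their split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .divergence import ClockParameters, DEFAULT_CLOCK, age_to_divergence
from .timetree import TimeTree

__all__ = [
    "HttConfig", "TePairDs", "HttHit", "HitGroup", "LineagePartition",
    "ortholog_ds_threshold", "call_htt", "htt_frequency_per_thousand",
    "format_frequency", "collapse_lineages", "minimal_htt_events",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HttConfig:
    """Tunable thresholds of the HTT procedure."""

    quantile_q: float = 0.025       # ortholog dS quantile for the call
    min_copy_fraction: float = 0.8  # copy length / consensus length
    min_te_nt: int = 300            # TE pair alignment length, nt (strict >)
    min_orth_aa: int = 300          # ortholog alignment length, aa (strict >)
    lineage_ds_fraction: float = 0.003  # ">0.3%" ortholog overlap criterion
    lineage_age_my: float = 40.0        # "diverged in the last 40 My"
    min_orthologs_per_pair: int = 40    # below this, fall back to pooled

    def __post_init__(self):
        if not 0.0 <= self.quantile_q <= 1.0:
            raise ValueError("quantile_q outside [0,1]")
        if not 0.0 < self.min_copy_fraction <= 1.0:
            raise ValueError("min_copy_fraction outside (0,1]")
        if not 0.0 <= self.lineage_ds_fraction <= 1.0:
            raise ValueError("lineage_ds_fraction outside [0,1]")
        if self.lineage_age_my < 0:
            raise ValueError("negative lineage_age_my")


@dataclass(frozen=True)
class TePairDs:
    """A cross-species TE coding pair with its dS estimate."""

    copy_a: str
    copy_b: str
    species_a: str
    species_b: str
    subfamily: str
    ds: float

    @property
    def species_pair(self) -> frozenset:
        return frozenset((self.species_a, self.species_b))

    @property
    def te_class(self) -> str:
        return self.subfamily.split("/", 1)[0]


@dataclass(frozen=True)
class HttHit:
    """A TE pair called horizontal at its species pair's dS threshold."""

    copy_a: str
    copy_b: str
    species_a: str
    species_b: str
    subfamily: str
    ds: float
    threshold_used: float

    def __post_init__(self):
        if self.species_a == self.species_b:
            raise ValueError("HTT hit within a single species")
        if not self.ds < self.threshold_used:
            raise ValueError("hit dS not below its threshold")

    @property
    def species_pair(self) -> frozenset:
        return frozenset((self.species_a, self.species_b))


@dataclass(frozen=True)
class HitGroup:
    """A cluster of hits attributable to one independent transfer event."""

    group_id: str
    members: tuple[HttHit, ...]
    lineage_pair: frozenset
    subfamily: str


@dataclass(frozen=True)
class LineagePartition:
    """Partition of species into lineages (each lineage a guide-tree clade)."""

    assignment: dict            # species -> lineage id
    lineages: dict              # lineage id -> frozenset of species

    def lineage_of(self, species: str) -> str:
        return self.assignment[species]


# ----------------------------------------------------------------------

def ortholog_ds_threshold(orth_ds: Sequence[float], q: float) -> float:
    """Empirical q-quantile of ortholog dS, linear interpolation on (n-1)q.

    Non-finite (saturated) values are ignored; an empty input raises.
    """
    vals = np.asarray(list(orth_ds), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite ortholog dS values")
    return float(np.quantile(vals, q, method="linear"))


def call_htt(te_ds_pairs: Iterable[TePairDs],
             orth_ds_by_species_pair: Mapping[frozenset, Sequence[float]],
             config: HttConfig = HttConfig(),
             pooled: bool = False) -> list[HttHit]:
    """Call HTT hits: TE pairs with dS strictly below the per-species-pair
    ortholog quantile threshold.

    SINE-class pairs are excluded (no protein, no dS). Species pairs with
    fewer than ``config.min_orthologs_per_pair`` finite ortholog dS values
    fall back to the threshold from all ortholog pairs pooled (with a
    warning); ``pooled=True`` forces the pooled threshold everywhere.
    Species pairs lacking orthologs entirely are skipped with a warning.
    """
    pooled_values: list[float] = []
    for vals in orth_ds_by_species_pair.values():
        pooled_values.extend(v for v in vals if np.isfinite(v))
    pooled_threshold = None
    if pooled_values:
        pooled_threshold = ortholog_ds_threshold(pooled_values,
                                                 config.quantile_q)

    thresholds: dict[frozenset, float] = {}
    hits: list[HttHit] = []
    for pair in te_ds_pairs:
        if pair.te_class == "SINE":
            continue
        if not np.isfinite(pair.ds):
            continue
        sp = pair.species_pair
        if sp not in thresholds:
            vals = [v for v in orth_ds_by_species_pair.get(sp, [])
                    if np.isfinite(v)]
            if pooled and pooled_threshold is not None:
                thresholds[sp] = pooled_threshold
            elif len(vals) >= config.min_orthologs_per_pair:
                thresholds[sp] = ortholog_ds_threshold(vals,
                                                       config.quantile_q)
            elif vals or pooled_threshold is not None:
                logger.warning(
                    "species pair %s has %d ortholog dS values (<%d); "
                    "using pooled threshold", sorted(sp), len(vals),
                    config.min_orthologs_per_pair)
                thresholds[sp] = pooled_threshold
            else:
                logger.warning("species pair %s lacks orthologs; skipped",
                               sorted(sp))
                thresholds[sp] = float("nan")
        thr = thresholds[sp]
        if not np.isfinite(thr):
            continue
        if pair.ds < thr:
            hits.append(HttHit(copy_a=pair.copy_a, copy_b=pair.copy_b,
                               species_a=pair.species_a,
                               species_b=pair.species_b,
                               subfamily=pair.subfamily,
                               ds=pair.ds, threshold_used=thr))
    return hits


def htt_frequency_per_thousand(n_htt: int, copy_number: int) -> float:
    """HTT events per thousand TE copies."""
    if copy_number <= 0:
        raise ValueError("copy_number must be positive")
    return 1000.0 * n_htt / copy_number


def format_frequency(freq: float) -> str:
    """Render a per-thousand frequency: two decimals, scientific below 0.01."""
    if freq == 0:
        return "0"
    if freq < 0.01:
        return f"{freq:.1e}"
    return f"{freq:.2f}"


def max_te_nucleotide_divergence(copies, divergence_fn,
                                 max_per_group: int = 50) -> float:
    """Highest within-species, within-subfamily TE nucleotide divergence.

    The default value for ``max_te_divergence`` in
    :func:`collapse_lineages`: species pairs whose ortholog dS overlaps
    the range of within-genome TE divergence cannot separate vertical
    inheritance from transfer and must share a lineage. Groups larger
    than ``max_per_group`` copies are subsampled deterministically
    (first ``max_per_group`` in input order).
    """
    groups: dict[tuple[str, str], list] = {}
    for c in copies:
        groups.setdefault((c.species, c.subfamily), []).append(c)
    best = 0.0
    for group in groups.values():
        group = group[:max_per_group]
        for i, ca in enumerate(group):
            for cb in group[i + 1:]:
                d = divergence_fn(ca.copy_id, cb.copy_id)
                if d is not None and d > best:
                    best = float(d)
    return best


# ----------------------------------------------------------------------
# Lineage collapsing
# ----------------------------------------------------------------------

def collapse_lineages(guide_tree: TimeTree,
                      orth_ds_by_species_pair: Mapping[frozenset,
                                                       Sequence[float]],
                      max_te_divergence: float,
                      config: HttConfig = HttConfig()) -> LineagePartition:
    """Collapse clades of the guide tree into lineages.

    A clade becomes one lineage if every cross-species pair inside it has
    a fraction of ortholog dS below ``max_te_divergence`` exceeding
    ``config.lineage_ds_fraction``, OR the clade's crown age is below
    ``config.lineage_age_my``. Maximal qualifying clades form the
    partition; remaining species are singleton lineages.
    """

    def collapsible(tips: frozenset, age: float) -> bool:
        if len(tips) == 1:
            return True
        if age < config.lineage_age_my:
            return True
        for a in tips:
            for b in tips:
                if a >= b:
                    continue
                vals = np.asarray(
                    list(orth_ds_by_species_pair.get(frozenset((a, b)), [])),
                    dtype=float)
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    return False
                frac = float(np.mean(vals < max_te_divergence))
                if not frac > config.lineage_ds_fraction:
                    return False
        return True

    # maximal collapsible clades: sort clades by size descending and keep
    # those not contained in an already accepted lineage
    clades = sorted(guide_tree.clades(), key=lambda c: -len(c[0]))
    accepted: list[frozenset] = []
    for tips, age in clades:
        if any(tips <= acc for acc in accepted):
            continue
        if collapsible(tips, age):
            accepted.append(tips)
    covered = set().union(*accepted) if accepted else set()
    for sp in guide_tree.taxa:
        if sp not in covered:
            accepted.append(frozenset([sp]))

    assignment, lineages = {}, {}
    for tips in accepted:
        lid = "+".join(sorted(tips))
        lineages[lid] = tips
        for sp in tips:
            assignment[sp] = lid
    return LineagePartition(assignment=assignment, lineages=lineages)


# ----------------------------------------------------------------------
# Minimal-event clustering
# ----------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def minimal_htt_events(hits: Sequence[HttHit],
                       partition: LineagePartition,
                       te_nt_divergence_fn: Callable[[str, str],
                                                     float | None],
                       guide_tree: TimeTree,
                       clock: ClockParameters = DEFAULT_CLOCK
                       ) -> list[HitGroup]:
    """Cluster hits into the minimum number of independent transfer events.

    Within-lineage hits are discarded first. Two hits are connected when
    they join the same unordered lineage pair, share a subfamily, and on
    each side the involved copies' pairwise K2P nucleotide divergence is
    below the vertical-inheritance ceiling ``2 r T_split`` (``T_split`` =
    divergence time of the two lineages on the guide tree): copies
    descending from a single transfer postdate the lineages' split. When
    the divergence of a needed copy pair is unavailable the edge is not
    created (conservative: more groups). Connected components are the
    HitGroups.
    """
    cross = []
    for h in hits:
        la = partition.lineage_of(h.species_a)
        lb = partition.lineage_of(h.species_b)
        if la != lb:
            cross.append((h, frozenset((la, lb))))

    # ceilings per lineage pair
    ceilings: dict[frozenset, float] = {}
    for _, lp in cross:
        if lp in ceilings:
            continue
        la, lb = sorted(lp)
        species = set(partition.lineages[la]) | set(partition.lineages[lb])
        t_split = guide_tree.mrca_age(species)
        ceilings[lp] = age_to_divergence(t_split, clock)

    uf = _UnionFind(len(cross))

    def side_copies(h: HttHit, lineage: str) -> list[str]:
        out = []
        if partition.lineage_of(h.species_a) == lineage:
            out.append(h.copy_a)
        if partition.lineage_of(h.species_b) == lineage:
            out.append(h.copy_b)
        return out

    for i in range(len(cross)):
        hi, lpi = cross[i]
        for j in range(i + 1, len(cross)):
            hj, lpj = cross[j]
            if lpi != lpj or hi.subfamily != hj.subfamily:
                continue
            ceiling = ceilings[lpi]
            ok = True
            for lineage in lpi:
                ca = side_copies(hi, lineage)[0]
                cb = side_copies(hj, lineage)[0]
                if ca == cb:
                    continue
                div = te_nt_divergence_fn(ca, cb)
                if div is None or not div < ceiling:
                    ok = False
                    break
            if ok:
                uf.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(len(cross)):
        comps.setdefault(uf.find(i), []).append(i)

    groups = []
    for k, root in enumerate(sorted(comps)):
        members = tuple(cross[i][0] for i in comps[root])
        groups.append(HitGroup(group_id=f"g{k + 1}",
                               members=members,
                               lineage_pair=cross[comps[root][0]][1],
                               subfamily=members[0].subfamily))
    return groups
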