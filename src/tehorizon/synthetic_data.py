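"""Synthetic multi-species TE / ortholog datasets with known truth.

The generator produces everything the analysis pipeline consumes —
a timetree, per-species TE annotations (.out) with copy sequences,
consensus sequences, codon-aligned single-copy ortholog pairs, TE coding
pairs, and a genome-size/TE-load table — from an explicit genealogical
model, so every downstream estimate can be checked against the truth
that generated it.

Model
-----
* Orthologs: one gene tree per ortholog equals the species tree. Codons
  are drawn from the six fourfold-degenerate families (GGN, GCN, CCN,
  ACN, GTN, TCN); third positions substitute uniformly over the three
  alternatives at the neutral clock rate ``r`` per year, so the expected
  dS between two species separated ``T`` My is exactly ``2 r T`` and the
  NG86+Jukes–Cantor estimator is exactly calibrated to it. First/second
  positions change only under the optional ``omega`` knob (default 0).
* TE subfamilies: each has a nucleotide consensus (master) and a coding
  ORF built from the same fourfold alphabet. A copy observed in species
  ``s`` with insertion age ``a`` branches off the root-to-``s`` lineage
  at ``a`` My and then evolves on its own to the present; coding-side
  divergence between cross-species copies therefore equals the species
  divergence (vertical copies), exactly like orthologs. The copy's
  genomic nucleotide sequence diverges from the consensus by ``2 r a``
  under Kimura's two-parameter model (transition/transversion ratio 2),
  so repeat-landscape dating sees ``K = 2 r a``.
* Horizontal transfers: a transfer at age ``t`` branches the donor's
  ORF lineage at ``t`` and deposits copies in the recipient that have
  evolved only since ``t`` — cross-species dS ``≈ 2 r t``, far below the
  vertical expectation when ``t`` is recent.
* Insertion ages are drawn from Gaussian bursts around the configured
  burst ages (truncated at zero and the tree height).

The same seed yields byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_substitution import CodingPair, ng86_ds
from .divergence import (ClockParameters, DEFAULT_CLOCK, SaturationError,
                         k2p_from_counts, SiteCounts)
from .formats_io import (AnnotatedCopy, ConsensusRecord, write_fasta,
                         write_genome_table, write_repeatmasker_out)
from .htt_inference import TePairDs
from .phylo_comparative import eb_cov
from .timetree import TimeTree

__all__ = [
    "SubfamilySpec", "HttEventSpec", "SimScenario", "SimTruth", "SimResult",
    "simulate", "simulate_trait",
    "evolve_k2p", "evolve_uniform",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# fourfold-degenerate codon prefixes (distinct amino acids)
_PREFIXES = ("GG", "GC", "CC", "AC", "GT", "TC")

_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)   # A<->G, C<->T
_TV_PARTNER_1 = np.array([1, 0, 1, 0], dtype=np.uint8)
_TV_PARTNER_2 = np.array([3, 2, 3, 2], dtype=np.uint8)


# ----------------------------------------------------------------------
# elementary sequence evolution
# ----------------------------------------------------------------------

def _k2p_site_probs(d: float, ratio: float) -> tuple[float, float]:
    """Per-site transition and total transversion probabilities after an
    expected ``d`` substitutions/site with ts/tv ratio ``ratio``."""
    if d <= 0:
        return 0.0, 0.0
    beta = d / (2.0 * (ratio + 1.0))
    alpha = d * ratio / (ratio + 1.0)
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta) \
        - 0.5 * math.exp(-2 * (alpha + beta))
    p_tv = 0.5 - 0.5 * math.exp(-4 * beta)
    return p_ts, p_tv


def evolve_k2p(seq: np.ndarray, d: float, ratio: float,
               rng: np.random.Generator) -> np.ndarray:
    """Evolve an int-coded (A=0,C=1,G=2,T=3) sequence by an expected
    ``d`` substitutions/site under K2P with ts/tv ratio ``ratio``."""
    p_ts, p_tv = _k2p_site_probs(d, ratio)
    out = seq.copy()
    u = rng.random(seq.size)
    m_ts = u < p_ts
    m_tv1 = (u >= p_ts) & (u < p_ts + p_tv / 2)
    m_tv2 = (u >= p_ts + p_tv / 2) & (u < p_ts + p_tv)
    out[m_ts] = _TS_PARTNER[seq[m_ts]]
    out[m_tv1] = _TV_PARTNER_1[seq[m_tv1]]
    out[m_tv2] = _TV_PARTNER_2[seq[m_tv2]]
    return out


def evolve_uniform(seq: np.ndarray, d: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Evolve by an expected ``d`` substitutions/site with equal rates to
    the three alternative nucleotides (Jukes–Cantor)."""
    if d <= 0:
        return seq.copy()
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    out = seq.copy()
    m = rng.random(seq.size) < p_change
    shift = rng.integers(1, 4, size=int(m.sum()))
    out[m] = (out[m].astype(np.int64) + shift) % 4
    return out


def _k2p_estimate(a: np.ndarray, b: np.ndarray) -> float:
    """Realized K2P divergence between two equal-length int sequences
    (falls back to the raw mismatch proportion at saturation)."""
    diff = a != b
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    try:
        return k2p_from_counts(SiteCounts(a.size, ts, tv)).K
    except SaturationError:
        return float(np.count_nonzero(diff)) / a.size


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


# ----------------------------------------------------------------------
# scenario
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SubfamilySpec:
    """One TE subfamily: classification, burst structure, copy counts."""

    name: str                       # "Class/Family", e.g. "DNA/Maverick"
    copies_per_species: int = 20
    species: tuple[str, ...] | None = None   # None = all tree taxa
    burst_ages_my: tuple[float, ...] = (10.0,)
    burst_sd_my: float = 1.0
    consensus_length: int = 2000
    orf_codons: int = 150

    @property
    def te_class(self) -> str:
        return self.name.split("/", 1)[0]


@dataclass(frozen=True)
class HttEventSpec:
    """One injected horizontal transfer.

    ``recipient`` may be a single species or a tuple of species: a tuple
    models a transfer into the recipients' common ancestor (the event
    must predate none of the donor–recipient divergences), leaving
    copies of the transferred element in every descendant.
    """

    donor: str
    recipient: str | tuple[str, ...]
    age_my: float
    subfamily: str
    n_copies: int = 3       # copies deposited per recipient species

    @property
    def recipients(self) -> tuple[str, ...]:
        if isinstance(self.recipient, str):
            return (self.recipient,)
        return tuple(self.recipient)


@dataclass(frozen=True)
class SimScenario:
    """Full parameterisation of a synthetic multi-species dataset."""

    tree_newick: str
    clock: ClockParameters = DEFAULT_CLOCK
    n_orthologs: int = 100
    ortholog_length: int = 301       # codons
    omega: float = 0.0               # dN/dS knob for ortholog prefixes
    ts_tv_ratio: float = 2.0
    subfamilies: tuple[SubfamilySpec, ...] = ()
    htt_events: tuple[HttEventSpec, ...] = ()
    seed: int = 0
    nonte_baseline_mb: float = 200.0

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimScenario":
        d = dict(d)
        if "clock" in d and isinstance(d["clock"], Mapping):
            d["clock"] = ClockParameters(**d["clock"])
        d["subfamilies"] = tuple(
            SubfamilySpec(**s) if isinstance(s, Mapping) else s
            for s in d.get("subfamilies", ()))
        for s in d["subfamilies"]:
            pass
        d["htt_events"] = tuple(
            HttEventSpec(**e) if isinstance(e, Mapping) else e
            for e in d.get("htt_events", ()))
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the dataset."""

    copy_age_my: dict = field(default_factory=dict)      # copy id -> age
    copy_source: dict = field(default_factory=dict)      # copy id ->
    #                                                     "vertical"|event id
    expected_ortholog_ds: dict = field(default_factory=dict)  # pair -> 2rT
    htt_event_ids: list = field(default_factory=list)


@dataclass
class SimResult:
    """In-memory synthetic dataset plus writers and derived-pair helpers."""

    scenario: SimScenario
    tree: TimeTree
    consensus: dict                  # consensus id -> ConsensusRecord
    copies: list                     # list[AnnotatedCopy]
    copy_nt: dict                    # copy id -> int array
    copy_cds: dict                   # copy id -> str
    copy_subfamily: dict             # copy id -> subfamily name
    ortholog_cds: dict               # species -> list of CDS strings
    genome_table: pd.DataFrame
    truth: SimTruth

    # -- derived views -------------------------------------------------
    def ortholog_pairs(self) -> list[CodingPair]:
        species = sorted(self.ortholog_cds)
        pairs = []
        for g in range(self.scenario.n_orthologs):
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    pairs.append(CodingPair(
                        id_a=f"gene{g:04d}|{a}", id_b=f"gene{g:04d}|{b}",
                        species_a=a, species_b=b,
                        aligned_cds_a=self.ortholog_cds[a][g],
                        aligned_cds_b=self.ortholog_cds[b][g],
                        kind="ortholog_pair"))
        return pairs

    def ortholog_ds_by_species_pair(self) -> dict:
        out: dict = {}
        for p in self.ortholog_pairs():
            key = frozenset((p.species_a, p.species_b))
            out.setdefault(key, []).append(ng86_ds(p).dS)
        return out

    def te_coding_pairs(self) -> list[TePairDs]:
        """All cross-species same-subfamily TE coding pairs with NG86 dS."""
        by_subfam: dict[str, list[AnnotatedCopy]] = {}
        for c in self.copies:
            by_subfam.setdefault(self.copy_subfamily[c.copy_id], []).append(c)
        pairs = []
        for subfam in sorted(by_subfam):
            group = by_subfam[subfam]
            for i, ca in enumerate(group):
                for cb in group[i + 1:]:
                    if ca.species == cb.species:
                        continue
                    cp = CodingPair(
                        id_a=ca.copy_id, id_b=cb.copy_id,
                        species_a=ca.species, species_b=cb.species,
                        aligned_cds_a=self.copy_cds[ca.copy_id],
                        aligned_cds_b=self.copy_cds[cb.copy_id],
                        kind="te_pair")
                    pairs.append(TePairDs(
                        copy_a=ca.copy_id, copy_b=cb.copy_id,
                        species_a=ca.species, species_b=cb.species,
                        subfamily=subfam, ds=ng86_ds(cp).dS))
        return pairs

    def copy_nt_divergence_fn(self):
        """K2P nucleotide divergence between two copies of one subfamily
        (None when the copies are not comparable)."""
        def fn(copy_a: str, copy_b: str):
            if (self.copy_subfamily.get(copy_a)
                    != self.copy_subfamily.get(copy_b)):
                return None
            sa, sb = self.copy_nt.get(copy_a), self.copy_nt.get(copy_b)
            if sa is None or sb is None or sa.size != sb.size:
                return None
            return _k2p_estimate(sa, sb)
        return fn

    # -- emission ------------------------------------------------------
    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.newick().strip() + "\n")
        write_fasta(
            {f"{c.consensus_id}#{c.subfamily}": c.sequence
             for c in self.consensus.values()},
            out / "consensus.fasta")
        by_species: dict[str, list[AnnotatedCopy]] = {}
        for c in self.copies:
            by_species.setdefault(c.species, []).append(c)
        for sp in sorted(by_species):
            write_repeatmasker_out(by_species[sp], out / f"{sp}.out")
            write_fasta({c.copy_id: _decode(self.copy_nt[c.copy_id])
                         for c in by_species[sp]},
                        out / f"{sp}_copies.fasta")
        write_fasta(dict(sorted(self.copy_cds.items())),
                    out / "te_cds.fasta")
        ortho = {}
        for sp in sorted(self.ortholog_cds):
            for g, cds in enumerate(self.ortholog_cds[sp]):
                ortho[f"gene{g:04d}|{sp}"] = cds
        write_fasta(ortho, out / "orthologs.fasta")
        write_genome_table(self.genome_table, out / "genome_table.tsv")


# ----------------------------------------------------------------------
# tree-walking evolution with branch-off events
# ----------------------------------------------------------------------

def _tip_paths(tree: TimeTree) -> dict[str, list[int]]:
    nodes = tree._nodes
    paths = {}
    for n in nodes:
        if n.children:
            continue
        path = []
        cur = n
        while cur is not None:
            path.append(cur.index)
            cur = nodes[cur.parent] if cur.parent is not None else None
        paths[n.label] = list(reversed(path))
    return paths


def _assign_edge_events(tree: TimeTree, events: Sequence[tuple[str, float,
                                                               object]]
                        ) -> dict[int, list[tuple[float, object]]]:
    """Map (species, age, key) branch-off events onto tree edges.

    Returns child-node-index -> list of (depth_of_event, key), sorted by
    depth (root-ward first) within each edge.
    """
    nodes = tree._nodes
    paths = _tip_paths(tree)
    per_edge: dict[int, list[tuple[float, object]]] = {}
    for species, age, key in events:
        if species not in paths:
            raise ValueError(f"unknown species {species!r}")
        if not 0.0 <= age <= tree.height + 1e-9:
            raise ValueError(f"event age {age} outside [0, tree height]")
        ev_depth = tree.height - age
        for pidx, cidx in zip(paths[species], paths[species][1:]):
            if nodes[pidx].depth <= ev_depth <= nodes[cidx].depth:
                per_edge.setdefault(cidx, []).append((ev_depth, key))
                break
        else:
            raise ValueError(
                f"no edge on the {species} lineage spans age {age}")
    for lst in per_edge.values():
        lst.sort(key=lambda t: (t[0], str(t[1])))
    return per_edge


def _evolve_along_tree(tree: TimeTree, root_state: np.ndarray,
                       rate_per_my: float, rng: np.random.Generator,
                       evolve_fn,
                       edge_events: Mapping[int, list] | None = None
                       ) -> tuple[dict[str, np.ndarray],
                                  dict[object, np.ndarray]]:
    """Evolve a state down the tree; capture states at branch-off events.

    Returns (tip label -> state, event key -> state at its branch point).
    """
    edge_events = edge_events or {}
    nodes = tree._nodes
    states: dict[int, np.ndarray] = {0: root_state}
    tip_states: dict[str, np.ndarray] = {}
    event_states: dict[object, np.ndarray] = {}
    for n in nodes:
        if n.parent is None:
            cur = root_state
        else:
            cur = states[n.parent]
            cur_depth = nodes[n.parent].depth
            for ev_depth, key in edge_events.get(n.index, []):
                cur = evolve_fn(cur, rate_per_my * (ev_depth - cur_depth),
                                rng)
                event_states[key] = cur
                cur_depth = ev_depth
            cur = evolve_fn(cur, rate_per_my * (n.depth - cur_depth), rng)
        states[n.index] = cur
        if not n.children:
            tip_states[n.label] = cur
    return tip_states, event_states


# ----------------------------------------------------------------------
# the generator
# ----------------------------------------------------------------------

def simulate(scenario: SimScenario, out_dir=None) -> SimResult:
    """Generate a complete synthetic dataset (and optionally write it).

    Raises on inconsistent ages (burst or transfer ages beyond the tree,
    transfers at or after the donor–recipient divergence) before any file
    is written.
    """
    tree = TimeTree(scenario.tree_newick)
    clock = scenario.clock
    rate_my = clock.rate_r * clock.generations_per_year * 1e6  # subs/site/My

    # -- validation up front -------------------------------------------
    taxa = set(tree.taxa)
    for sf in scenario.subfamilies:
        for sp in (sf.species or tree.taxa):
            if sp not in taxa:
                raise ValueError(f"{sf.name}: unknown species {sp!r}")
        for b in sf.burst_ages_my:
            if not 0.0 <= b <= tree.height:
                raise ValueError(
                    f"{sf.name}: burst age {b} My outside the tree")
    subfam_names = {sf.name for sf in scenario.subfamilies}
    for ev in scenario.htt_events:
        if ev.donor not in taxa or any(r not in taxa
                                       for r in ev.recipients):
            raise ValueError(f"HTT event references unknown species: {ev}")
        if ev.subfamily not in subfam_names:
            raise ValueError(f"HTT event references unknown subfamily: {ev}")
        for r in ev.recipients:
            t_split = tree.divergence_time(ev.donor, r)
            if not 0.0 < ev.age_my < t_split:
                raise ValueError(
                    f"HTT age {ev.age_my} My not inside (0, donor-"
                    f"recipient divergence {t_split} My)")

    rng = np.random.default_rng(scenario.seed)
    truth = SimTruth()

    # -- orthologs ------------------------------------------------------
    n_orth, L = scenario.n_orthologs, scenario.ortholog_length
    prefix_root = rng.integers(0, len(_PREFIXES), size=(n_orth, L))
    thirds_root = rng.integers(0, 4, size=n_orth * L).astype(np.uint8)
    tip_thirds, _ = _evolve_along_tree(tree, thirds_root, rate_my, rng,
                                       evolve_uniform)
    if scenario.omega > 0:
        def evolve_prefix(state, d, rng_):
            p = 1.0 - math.exp(-scenario.omega * d)
            out = state.copy()
            m = rng_.random(state.size) < p
            shift = rng_.integers(1, len(_PREFIXES), size=int(m.sum()))
            out[m] = (out[m] + shift) % len(_PREFIXES)
            return out
        tip_prefix, _ = _evolve_along_tree(
            tree, prefix_root.ravel().copy(), rate_my, rng, evolve_prefix)
    else:
        tip_prefix = {sp: prefix_root.ravel() for sp in tree.taxa}

    def build_cds(prefix_flat: np.ndarray, thirds_flat: np.ndarray,
                  gene: int) -> str:
        lo, hi = gene * L, (gene + 1) * L
        pf = prefix_flat[lo:hi]
        th = thirds_flat[lo:hi]
        chars = np.empty((L, 3), dtype="U1")
        pref = np.array([list(p) for p in _PREFIXES])
        chars[:, 0] = pref[pf, 0]
        chars[:, 1] = pref[pf, 1]
        chars[:, 2] = np.array(list("ACGT"))[th]
        return "".join(chars.ravel())

    ortholog_cds = {
        sp: [build_cds(tip_prefix[sp], tip_thirds[sp], g)
             for g in range(n_orth)]
        for sp in tree.taxa
    }
    for i, a in enumerate(tree.taxa):
        for b in tree.taxa[i + 1:]:
            truth.expected_ortholog_ds[frozenset((a, b))] = \
                2.0 * rate_my * tree.divergence_time(a, b)

    # -- TE subfamilies -------------------------------------------------
    consensus: dict[str, ConsensusRecord] = {}
    copies: list[AnnotatedCopy] = []
    copy_nt: dict[str, np.ndarray] = {}
    copy_cds: dict[str, str] = {}
    copy_subfamily: dict[str, str] = {}
    cursor: dict[str, int] = {sp: 0 for sp in tree.taxa}
    pref_chars = np.array([list(p) for p in _PREFIXES])
    base_chars = np.array(list("ACGT"))

    def orf_to_str(pf: np.ndarray, th: np.ndarray) -> str:
        chars = np.empty((pf.size, 3), dtype="U1")
        chars[:, 0] = pref_chars[pf, 0]
        chars[:, 1] = pref_chars[pf, 1]
        chars[:, 2] = base_chars[th]
        return "".join(chars.ravel())

    for sf_i, sf in enumerate(scenario.subfamilies):
        cons_id = f"cons_{sf.name.replace('/', '_')}"
        cons_nt = rng.integers(0, 4, size=sf.consensus_length
                               ).astype(np.uint8)
        consensus[cons_id] = ConsensusRecord(
            consensus_id=cons_id, subfamily=sf.name,
            sequence=_decode(cons_nt))
        orf_prefix = rng.integers(0, len(_PREFIXES), size=sf.orf_codons)
        orf_thirds_root = rng.integers(0, 4, size=sf.orf_codons
                                       ).astype(np.uint8)

        species = list(sf.species or tree.taxa)
        sf_events = [ev for ev in scenario.htt_events
                     if ev.subfamily == sf.name]

        # sample vertical copy ages and register branch-off events
        events: list[tuple[str, float, object]] = []
        copy_meta: list[tuple[str, str, float, str]] = []  # id, sp, age, src
        for sp in species:
            bursts = np.asarray(sf.burst_ages_my, dtype=float)
            pick = rng.integers(0, bursts.size, size=sf.copies_per_species)
            ages = rng.normal(bursts[pick], sf.burst_sd_my)
            ages = np.clip(ages, 0.0, tree.height)
            for k, age in enumerate(sorted(ages)):
                cid_key = (sf.name, sp, k)
                events.append((sp, float(age), cid_key))
                copy_meta.append((cid_key, sp, float(age), "vertical"))
        for e_i, ev in enumerate(sf_events):
            key = ("htt", sf.name, e_i)
            events.append((ev.donor, ev.age_my, key))

        edge_events = _assign_edge_events(tree, events)
        _, event_states = _evolve_along_tree(
            tree, orf_thirds_root, rate_my, rng, evolve_uniform,
            edge_events)

        def register_copy(sp: str, age: float, thirds: np.ndarray,
                          source: str, nt: np.ndarray | None = None):
            start = cursor[sp] + 101
            end = start + sf.consensus_length - 1
            cursor[sp] = end
            copy_id = f"{sp}:scf1:{start}-{end}"
            if nt is None:
                nt = evolve_k2p(cons_nt, 2.0 * rate_my * age,
                                scenario.ts_tv_ratio, rng)
            copies.append(AnnotatedCopy(
                copy_id=copy_id, species=sp, query_seq="scf1",
                start=start, end=end, strand="+",
                subfamily=sf.name, consensus_id=cons_id,
                percent_divergence=min(_k2p_estimate(cons_nt, nt), 1.0)))
            copy_nt[copy_id] = nt
            copy_cds[copy_id] = orf_to_str(orf_prefix, thirds)
            copy_subfamily[copy_id] = sf.name
            truth.copy_age_my[copy_id] = age
            truth.copy_source[copy_id] = source

        for cid_key, sp, age, _src in copy_meta:
            thirds = evolve_uniform(event_states[cid_key], rate_my * age,
                                    rng)
            register_copy(sp, age, thirds, "vertical")
        for e_i, ev in enumerate(sf_events):
            event_id = f"htt_{sf.name.replace('/', '_')}_{e_i}"
            truth.htt_event_ids.append(event_id)
            master = event_states[("htt", sf.name, e_i)]
            # transferred element's genomic sequence at transfer time:
            # halfway between consensus and present so copy-vs-consensus
            # is still 2 r age while transferred copies share history
            master_nt = evolve_k2p(cons_nt, rate_my * ev.age_my,
                                   scenario.ts_tv_ratio, rng)
            for recipient in ev.recipients:
                for _c in range(ev.n_copies):
                    thirds = evolve_uniform(master, rate_my * ev.age_my,
                                            rng)
                    nt = evolve_k2p(master_nt, rate_my * ev.age_my,
                                    scenario.ts_tv_ratio, rng)
                    register_copy(recipient, ev.age_my, thirds, event_id,
                                  nt=nt)

    # -- genome table ---------------------------------------------------
    class_keys = {"DNA": "dte_pct", "LTR": "ltr_pct", "LINE": "line_pct",
                  "SINE": "sine_pct", "Unknown": "unc_pct"}
    rows = []
    for sp in tree.taxa:
        bases = {k: 0 for k in class_keys}
        for c in copies:
            if c.species == sp:
                bases[c.te_class] += c.length
        total_te = sum(bases.values())
        size_bp = scenario.nonte_baseline_mb * 1e6 + total_te
        row = {"species": sp}
        for cls, col in class_keys.items():
            row[col] = round(100.0 * bases[cls] / size_bp, 4)
        row["all_pct"] = round(sum(row[c] for c in class_keys.values()), 4)
        row["genome_size_mb"] = round(size_bp / 1e6, 4)
        rows.append(row)
    genome_table = pd.DataFrame(rows)[
        ["species", "dte_pct", "ltr_pct", "line_pct", "sine_pct",
         "unc_pct", "all_pct", "genome_size_mb"]]

    result = SimResult(scenario=scenario, tree=tree, consensus=consensus,
                       copies=copies, copy_nt=copy_nt, copy_cds=copy_cds,
                       copy_subfamily=copy_subfamily,
                       ortholog_cds=ortholog_cds,
                       genome_table=genome_table, truth=truth)
    if out_dir is not None:
        result.write(out_dir)
    return result


# ----------------------------------------------------------------------
# random trees and trait simulation for the comparative methods
# ----------------------------------------------------------------------

def random_ultrametric_newick(n_tips: int, height: float,
                              seed: int | None = None) -> str:
    """A random ultrametric bifurcating tree (coalescent-style joins).

    Node ages are uniform order statistics on (0, height) with the root
    pinned at ``height``; at each age two random active lineages merge.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(0.0, height, size=n_tips - 1))
    ages[-1] = height
    active: list[tuple[str, float]] = [(f"t{i}", 0.0)
                                       for i in range(n_tips)]
    for age in ages:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (na, aa), (nb, ab) = active[i], active[j]
        merged = (f"({na}:{age - aa:.8f},{nb}:{age - ab:.8f})", float(age))
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append(merged)
    return active[0][0] + ";"

def simulate_trait(tree: TimeTree, model: str, params: Mapping,
                   seed: int | None = None,
                   n_reps: int = 1) -> list[dict[str, float]]:
    """Exact MVN samples of a tip trait under BM, EB or WN.

    ``params``: sigma2 (rate), z0 (root state), and ``a`` for EB.
    Returns ``n_reps`` mappings tip -> value (deterministic under seed).
    """
    if model not in ("BM", "EB", "WN"):
        raise ValueError("model must be BM, EB or WN")
    sigma2 = float(params.get("sigma2", 1.0))
    z0 = float(params.get("z0", 0.0))
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    n = tree.n_tips
    if model == "WN":
        V = sigma2 * np.eye(n)
    elif model == "BM":
        V = sigma2 * tree.vcv()
    else:
        V = sigma2 * eb_cov(tree.vcv(), float(params["a"]))
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        draws = np.full((n_reps, n), z0)
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        draws = z0 + rng.standard_normal((n_reps, n)) @ L.T
    return [dict(zip(tree.taxa, map(float, row))) for row in draws]
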