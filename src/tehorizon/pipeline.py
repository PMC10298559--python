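"""End-to-end orchestration: simulate → filter → dS → HTT → landscapes →
comparative analyses, with a reproducibility manifest.

Stages communicate only through files in the run directory, so each
stage's output can be inspected and re-used independently. A
``manifest.json`` records the configuration snapshot, seeds, input
hashes and per-stage row counts; re-running with identical inputs
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .codon_substitution import length_filter_pairs, ng86_ds
from .divergence import ClockParameters, landscape
from .formats_io import (copy_length_filter, read_consensus_fasta,
                         read_newick_timetree,
                         read_repeatmasker_out, write_table)
from .htt_inference import (HttConfig, call_htt, collapse_lineages,
                            format_frequency, htt_frequency_per_thousand,
                            max_te_nucleotide_divergence, minimal_htt_events)
from .phylo_comparative import (TraitTree, ancestral_ml, blomberg_k,
                                fit_continuous, pagel_lambda,
                                pearson_correlation, MODELS)
from .synthetic_data import SimScenario, simulate

__all__ = ["run_pipeline", "table6_summary", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def table6_summary(hits, copy_numbers: Mapping[str, int]) -> pd.DataFrame:
    """Per-subfamily HTT summary with class subtotals and a grand total.

    ``hits`` is either a mapping subfamily -> HTT count or an iterable of
    hit objects with a ``subfamily`` attribute; ``copy_numbers`` maps
    subfamily -> total copy count. Rows: subfamily, freq_per_thousand
    (rendered), n_htt, copy_number; subtotal rows aggregate per TE class
    and the final row aggregates everything.
    """
    if isinstance(hits, Mapping):
        n_htt = dict(hits)
    else:
        n_htt = {}
        for h in hits:
            n_htt[h.subfamily] = n_htt.get(h.subfamily, 0) + 1
    subfams = sorted(set(n_htt) | set(copy_numbers))
    rows = []
    for sf in subfams:
        n = int(n_htt.get(sf, 0))
        c = int(copy_numbers.get(sf, 0))
        freq = htt_frequency_per_thousand(n, c) if c > 0 else 0.0
        rows.append({"subfamily": sf, "freq_per_thousand":
                     format_frequency(freq), "n_htt": n, "copy_number": c})
    by_class: dict[str, list[dict]] = {}
    for r in rows:
        by_class.setdefault(r["subfamily"].split("/", 1)[0], []).append(r)
    out = []
    for cls in sorted(by_class):
        out.extend(by_class[cls])
        n = sum(r["n_htt"] for r in by_class[cls])
        c = sum(r["copy_number"] for r in by_class[cls])
        freq = htt_frequency_per_thousand(n, c) if c > 0 else 0.0
        out.append({"subfamily": f"{cls} (subtotal)",
                    "freq_per_thousand": format_frequency(freq),
                    "n_htt": n, "copy_number": c})
    n = sum(r["n_htt"] for r in rows)
    c = sum(r["copy_number"] for r in rows)
    freq = htt_frequency_per_thousand(n, c) if c > 0 else 0.0
    out.append({"subfamily": "All", "freq_per_thousand":
                format_frequency(freq), "n_htt": n, "copy_number": c})
    return pd.DataFrame(out)


DEFAULT_CONFIG = {
    "seed": 0,
    "quantile_q": 0.025,
    "lineage_age_my": 40.0,
    "lineage_ds_fraction": 0.003,
    "min_copy_fraction": 0.8,
    "min_te_nt": 300,
    "min_orth_aa": 300,
    "bin_width": 0.01,
    "rate_r": 2.9e-9,
    "generations_per_year": 1.0,
}


def run_pipeline(config: Mapping, out_dir) -> Path:
    """Run the full synthetic-data pipeline under one configuration.

    ``config`` must contain a ``scenario`` section (see
    :class:`~tehorizon.synthetic_data.SimScenario`); thresholds default
    to :data:`DEFAULT_CONFIG`. All stage outputs plus ``manifest.json``
    are written under ``out_dir``; a failure aborts with the failing
    stage named.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update({k: v for k, v in config.items() if k != "scenario"})
    if "scenario" not in config:
        raise PipelineError("configure", "config lacks a 'scenario' section")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clock = ClockParameters(rate_r=cfg["rate_r"],
                            generations_per_year=cfg["generations_per_year"])
    manifest = {"tool_version": __version__, "config": _jsonable(cfg),
                "seed": cfg["seed"], "stages": {}, "input_hashes": {}}

    def record(stage: str, **counts):
        manifest["stages"][stage] = counts

    # 1. simulate ------------------------------------------------------
    try:
        scen = dict(config["scenario"])
        scen.setdefault("seed", cfg["seed"])
        scen["clock"] = {"rate_r": cfg["rate_r"],
                         "generations_per_year":
                             cfg["generations_per_year"]}
        scenario = SimScenario.from_dict(scen)
        sim_dir = out / "data"
        result = simulate(scenario, out_dir=sim_dir)
        for f in sorted(sim_dir.iterdir()):
            manifest["input_hashes"][f.name] = _sha256(f)
        record("simulate", copies=len(result.copies),
               orthologs=scenario.n_orthologs,
               species=result.tree.n_tips)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # 2. read back + copy filter --------------------------------------
    try:
        tree = read_newick_timetree(sim_dir / "tree.nwk")
        consensus = read_consensus_fasta(sim_dir / "consensus.fasta")
        copies = []
        for sp in tree.taxa:
            copies.extend(read_repeatmasker_out(sim_dir / f"{sp}.out",
                                                species=sp))
        kept = copy_length_filter(copies, consensus,
                                  min_fraction=cfg["min_copy_fraction"])
        record("filter", copies_in=len(copies), copies_kept=len(kept))
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc

    # 3. dS ------------------------------------------------------------
    try:
        orth_pairs = length_filter_pairs(result.ortholog_pairs(),
                                         min_te_nt=cfg["min_te_nt"],
                                         min_orth_aa=cfg["min_orth_aa"])
        orth_ds: dict = {}
        orth_rows = []
        for p in orth_pairs:
            est = ng86_ds(p)
            key = frozenset((p.species_a, p.species_b))
            orth_ds.setdefault(key, []).append(est.dS)
            orth_rows.append({"id_a": p.id_a, "id_b": p.id_b,
                              "kind": p.kind, "aligned_len": p.aligned_aa,
                              "S": est.S, "N": est.N, "Sd": est.Sd,
                              "Nd": est.Nd, "dS": est.dS,
                              "saturated": est.saturated})
        write_table(pd.DataFrame(orth_rows), out / "ortholog_ds.tsv")
        te_pairs = result.te_coding_pairs()
        kept_ids = {c.copy_id for c in kept}
        te_pairs = [t for t in te_pairs
                    if t.copy_a in kept_ids and t.copy_b in kept_ids
                    and len(result.copy_cds[t.copy_a]) > cfg["min_te_nt"]]
        write_table(pd.DataFrame([t.__dict__ for t in te_pairs]),
                    out / "te_ds.tsv")
        record("ds", ortholog_pairs=len(orth_rows), te_pairs=len(te_pairs))
    except Exception as exc:
        raise PipelineError("ds", str(exc)) from exc

    # 4. HTT detection + clustering ------------------------------------
    try:
        hconfig = HttConfig(quantile_q=cfg["quantile_q"],
                            min_copy_fraction=cfg["min_copy_fraction"],
                            min_te_nt=cfg["min_te_nt"],
                            min_orth_aa=cfg["min_orth_aa"],
                            lineage_ds_fraction=cfg["lineage_ds_fraction"],
                            lineage_age_my=cfg["lineage_age_my"])
        hits = call_htt(te_pairs, orth_ds, hconfig)
        write_table(pd.DataFrame([h.__dict__ for h in hits])
                    if hits else pd.DataFrame(
                        columns=["copy_a", "copy_b", "species_a",
                                 "species_b", "subfamily", "ds",
                                 "threshold_used"]),
                    out / "htt_hits.tsv")
        max_te_div = max_te_nucleotide_divergence(
            kept, result.copy_nt_divergence_fn())
        partition = collapse_lineages(tree, orth_ds, max_te_div, hconfig)
        groups = minimal_htt_events(hits, partition,
                                    result.copy_nt_divergence_fn(),
                                    tree, clock)
        write_table(pd.DataFrame(
            [{"group_id": g.group_id,
              "lineage_pair": "|".join(sorted(g.lineage_pair)),
              "subfamily": g.subfamily, "n_members": len(g.members)}
             for g in groups] or None,
            columns=["group_id", "lineage_pair", "subfamily", "n_members"]),
            out / "htt_groups.tsv")
        copy_counts: dict[str, int] = {}
        for c in copies:
            copy_counts[c.subfamily] = copy_counts.get(c.subfamily, 0) + 1
        write_table(table6_summary(hits, copy_counts),
                    out / "htt_summary.tsv")
        record("htt", hits=len(hits), groups=len(groups),
               lineages=len(partition.lineages))
    except Exception as exc:
        raise PipelineError("htt", str(exc)) from exc

    # 5. landscape ------------------------------------------------------
    try:
        land = landscape(copies, bin_width=cfg["bin_width"], clock=clock)
        write_table(land, out / "landscape.tsv")
        record("landscape", rows=len(land))
    except Exception as exc:
        raise PipelineError("landscape", str(exc)) from exc

    # 6. comparative analyses ------------------------------------------
    try:
        gt = result.genome_table.set_index("species")
        trait = gt["all_pct"].to_dict()
        tt = TraitTree(tree, trait)
        sig_rows = []
        if tree.n_tips >= 4:
            lam = pagel_lambda(tt)
            kk = blomberg_k(tt, n_perm=1000, seed=cfg["seed"])
            sig_rows = [
                {"statistic": "lambda", "estimate": lam.estimate,
                 "p_value": lam.p_value},
                {"statistic": "K", "estimate": kk.estimate,
                 "p_value": kk.p_value},
            ]
            if tree.n_tips >= 5:   # AICc needs n > k + 1 for OU/EB
                fits = {m: fit_continuous(tt, m) for m in MODELS}
                best = min(fits.values(), key=lambda f: f.aicc)
                anc_fit = (fits["EB"] if best.model not in ("BM", "EB")
                           else best)
            else:
                fits = {"BM": fit_continuous(tt, "BM")}
                anc_fit = fits["BM"]
            write_table(pd.DataFrame(
                [{"model": m, "logL": f.log_likelihood, "k": f.k_params,
                  "AICc": f.aicc} for m, f in fits.items()]),
                out / "model_fits.tsv")
            anc = ancestral_ml(tt, anc_fit)
            write_table(pd.DataFrame(
                [{"node": nid, "value": v,
                  "clade": "|".join(anc.clades[nid])}
                 for nid, v in anc.states.items()]),
                out / "ancestral_states.tsv")
            write_table(pd.DataFrame(
                anc.directions, columns=["parent", "child", "direction"]),
                out / "branch_directions.tsv")
        write_table(pd.DataFrame(sig_rows,
                                 columns=["statistic", "estimate",
                                          "p_value"]),
                    out / "phylo_signal.tsv")
        corr_rows = []
        for col in ("dte_pct", "ltr_pct", "line_pct", "sine_pct",
                    "all_pct"):
            x = gt[col].to_numpy()
            if np.ptp(x) == 0:   # class absent from the simulation
                continue
            res = pearson_correlation(x, gt["genome_size_mb"].to_numpy())
            corr_rows.append({"te_class": col, "r": res.r,
                              "p_value": res.p_value, "n": res.n})
        write_table(pd.DataFrame(corr_rows), out / "correlations.tsv")
        record("comparative", signals=len(sig_rows),
               correlations=len(corr_rows))
    except Exception as exc:
        raise PipelineError("comparative", str(exc)) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
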