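"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (simple
loops, exhaustive enumeration, generic numerical optimisation) and never
calls the implementation paths it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRR"
       "VVVVAAAADDEEGGGG")
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    GENETIC_CODE[_a + _b + _c] = _AA[_i]


def translate(codon: str) -> str:
    return GENETIC_CODE[codon]


def ng86_counts_oracle(seq_a: str, seq_b: str):
    """Exhaustive NG86 bookkeeping: (S, N, Sd, Nd).

    Per-codon synonymous-site fractions averaged over both sequences;
    observed differences averaged over every ordering of the differing
    positions; steps that create (or join) stop codons count as
    nonsynonymous; codons with non-ACGT symbols in either sequence are
    skipped, as are aligned stop codons.
    """
    def syn_step(c1, c2):
        return (translate(c1) == translate(c2)
                and translate(c1) != "*")

    def site_fraction(codon):
        total = 0.0
        for pos in range(3):
            syn = sum(
                1 for b in "ACGT"
                if b != codon[pos]
                and syn_step(codon, codon[:pos] + b + codon[pos + 1:]))
            total += syn / 3.0
        return total

    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        if translate(ca) == "*" or translate(cb) == "*":
            continue
        n_codons += 1
        S_a += site_fraction(ca)
        S_b += site_fraction(cb)
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if positions:
            path_sd = []
            path_nd = []
            for order in itertools.permutations(positions):
                cur, sd, nd = ca, 0, 0
                for p in order:
                    nxt = cur[:p] + cb[p] + cur[p + 1:]
                    if syn_step(cur, nxt):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                path_sd.append(sd)
                path_nd.append(nd)
            Sd += sum(path_sd) / len(path_sd)
            Nd += sum(path_nd) / len(path_nd)
    S = (S_a + S_b) / 2.0
    return S, 3.0 * n_codons - S, Sd, Nd


def k2p_tally_oracle(seq_a: str, seq_b: str):
    """Position-by-position (compared, transitions, transversions)."""
    purines = {"A", "G"}
    compared = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        compared += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    return compared, ts, tv


def library_filter_oracle(records, identity_min, evalue_max, coverage_min):
    """Triple-condition scan: returns (kept ids, removed ids)."""
    removed = set()
    seen = set()
    for r in records:
        seen.add(r.query_id)
        if (r.percent_identity > identity_min
                and r.e_value < evalue_max
                and r.query_coverage > coverage_min):
            removed.add(r.query_id)
    return seen - removed, removed


def rbh_oracle(rows):
    """Quadratic reciprocal-best-hit scan over (query, subject, bitscore,
    shared_identifier) dicts."""
    queries = sorted({r["query"] for r in rows})
    best = {}
    for q in queries:
        cand = [r for r in rows if r["query"] == q]
        cand.sort(key=lambda r: (-r["bitscore"], r["subject"]))
        best[q] = cand[0]
    out = set()
    for a in queries:
        b = best[a]["subject"]
        if b in best and best[b]["subject"] == a \
                and best[a]["shared_identifier"] \
                and best[b]["shared_identifier"]:
            out.add(tuple(sorted((a, b))))
    return sorted(out)


def collapse_oracle(tree, orth_ds, max_te_div, ds_fraction, age_my):
    """Exhaustive clade-checking partition (maximal collapsible clades)."""
    def qualifies(tips, age):
        if len(tips) == 1:
            return True
        if age < age_my:
            return True
        for a, b in itertools.combinations(sorted(tips), 2):
            vals = [v for v in orth_ds.get(frozenset((a, b)), [])
                    if math.isfinite(v)]
            if not vals:
                return False
            frac = sum(v < max_te_div for v in vals) / len(vals)
            if not frac > ds_fraction:
                return False
        return True

    clades = [(set(t), a) for t, a in tree.clades()]
    clades += [({sp}, 0.0) for sp in tree.taxa]
    ok = [(tips, a) for tips, a in clades if qualifies(tips, a)]
    ok.sort(key=lambda c: -len(c[0]))
    chosen = []
    for tips, _ in ok:
        if not any(tips <= c for c in chosen):
            chosen.append(tips)
    return sorted(frozenset(c) for c in chosen)


def ancestral_bm_oracle(tip_cov, node_tip_cov, node_cov, z):
    """ML ancestral states by direct numerical maximisation of the joint
    Brownian likelihood over the internal-node states and the root mean.

    The joint covariance of (tips, nodes) under BM with unit rate is
    assembled from the shared-depth blocks; sigma2 and the mean are
    profiled crudely by including them in the optimisation.
    """
    n = len(z)
    m = node_cov.shape[0]
    big = np.zeros((n + m, n + m))
    big[:n, :n] = tip_cov
    big[:n, n:] = node_tip_cov.T
    big[n:, :n] = node_tip_cov
    big[n:, n:] = node_cov
    big = big + 1e-9 * np.eye(n + m)
    prec = np.linalg.inv(big)

    def neg_joint(params):
        states = params[:m]
        z0 = params[m]
        sigma2 = math.exp(params[m + 1])
        full = np.concatenate([z, states]) - z0
        quad = full @ prec @ full / sigma2
        logdet = (n + m) * math.log(sigma2) \
            + np.linalg.slogdet(big)[1]
        return 0.5 * (quad + logdet + (n + m) * math.log(2 * math.pi))

    x0 = np.concatenate([np.full(m, np.mean(z)), [np.mean(z)], [0.0]])
    res = optimize.minimize(neg_joint, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 100000})
    return res.x[:m]
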