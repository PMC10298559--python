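# tehorizon

Comparative transposable-element (TE) dynamics and horizontal-transfer
inference for multi-species genome studies.

Genomes of related species — the motivating case is ten noctuid moths —
differ enormously in how much of them is mobile DNA. `tehorizon`
provides the statistical machinery to ask, from TE annotations, a
time-calibrated species tree and single-copy orthologs:

* **When was each TE subfamily active?** Copy divergence from the
  subfamily consensus, as a Kimura 2-parameter distance `K`, dates each
  insertion via the neutral clock `T = K/2r` (default
  `r = 2.9×10⁻⁹`/site/generation, one generation per year); divergence
  histograms ("repeat landscapes") expose propagation bursts.
* **Does TE load track genome size and phylogeny?** Pearson
  correlations of per-class TE load against assembly size; Pagel's λ
  and Blomberg's K for phylogenetic signal; BM / OU / Early-Burst /
  white-noise model selection by AICc; maximum-likelihood ancestral TE
  loads with per-branch expansion/reduction calls.
* **Which TE copies moved horizontally?** A cross-species TE pair whose
  synonymous divergence (dS, Nei–Gojobori with Jukes–Cantor correction)
  falls strictly below the 2.5% quantile of the species pair's ortholog
  dS is younger than its hosts' split — a horizontal transfer (HTT)
  candidate. Hits are then collapsed across lineages and clustered into
  the *minimum number of independent transfer events*, so one ancestral
  transfer into a radiation is not counted once per descendant pair.

A synthetic-data generator produces complete datasets (annotations,
sequences, ortholog pairs, genome tables) from an explicit genealogy
with known insertion ages and injected transfers, so every stage is
testable against ground truth without any downloads. See
`docs/methods.md` for models, conventions and limitations.

## Worked example

TE loads and genome sizes for the ten noctuid species ship with the
package:

```python
from tehorizon.datasets import noctuid_te_loads
from tehorizon.phylo_comparative import pearson_correlation
from tehorizon.divergence import divergence_to_age

df = noctuid_te_loads()
for col in ("dte_pct", "ltr_pct", "line_pct", "sine_pct", "all_pct"):
    r = pearson_correlation(df[col], df.genome_size_mb)
    print(col, round(r.r, 2), f"{r.p_value:.2g}")
print("10% divergence =", round(divergence_to_age(0.10), 2), "My")
```

prints

```
dte_pct 0.81 0.0042
ltr_pct 0.49 0.15
line_pct 0.83 0.0033
sine_pct 0.2 0.57
all_pct 0.87 0.0011
10% divergence = 17.24 My
```

— LINEs and DNA transposons correlate strongly with genome size
(r = 0.83 and 0.81, p < 0.005), LTR and SINE loads do not, and a copy
10% diverged from its consensus inserted ~17 My ago under the default
clock.

The full pipeline runs from a TOML config describing a synthetic
scenario (or from your own files, stage by stage):

```bash
tehorizon run --config conf.toml --out run/
# stage-wise:
tehorizon simulate --config scenario.toml --out data/ --seed 1
tehorizon landscape --out landscape.tsv data/*.out
tehorizon htt-detect --te-ds te_ds.tsv --orth-ds ortholog_ds.tsv \
    --q 0.025 --out hits.tsv
tehorizon phylosig --tree data/tree.nwk --trait load.tsv --out sig.tsv
```

Each run directory contains TSVs per stage (dS tables, HTT hits and
clustered events, landscapes, signal statistics, model fits, ancestral
states) plus a `manifest.json` with config, seeds and input hashes;
identical inputs reproduce byte-identical outputs.

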