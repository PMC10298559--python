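"""Bundled reference tables for the ten-species noctuid moth comparison.

Small published summary tables used as worked-example inputs: per-species
genome sizes with TE loads by class, and per-subfamily horizontal-transfer
counts with subfamily copy numbers. Values are percent of genome, Mb, and
raw counts as printed in the source annotation study.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["noctuid_te_loads", "noctuid_htt_counts"]

_TE_LOADS = [
    # species, dte_pct, ltr_pct, line_pct, sine_pct, unc_pct, all_pct, Mb
    ("Trichoplusia_ni",        4.59, 2.63,  4.99, 2.25, 1.40, 15.86, 367.20),
    ("Helicoverpa_armigera",   4.01, 0.74,  3.46, 2.06, 1.06, 11.33, 299.98),
    ("Helicoverpa_zea",        4.82, 1.07,  4.05, 2.63, 1.19, 13.76, 306.41),
    ("Spodoptera_exigua",      4.74, 4.22, 17.64, 2.56, 1.48, 30.64, 446.80),
    ("Spodoptera_litura",      5.87, 2.40, 14.81, 3.39, 2.51, 28.98, 428.03),
    ("Spodoptera_frugiperda",  9.12, 1.94, 12.54, 0.98, 2.17, 26.75, 486.23),
    ("Agrotis_ipsilon",       11.80, 2.08, 13.81, 3.16, 3.42, 34.27, 486.92),
    ("Mamestra_configurata",  11.24, 2.12, 15.59, 2.37, 3.40, 34.72, 559.39),
    ("Busseola_fusca",        12.10, 3.16, 20.16, 6.11, 3.57, 45.10, 490.17),
    ("Heliothis_virescens",    8.39, 1.30,  5.64, 2.92, 2.29, 20.54, 403.15),
]

_HTT_COUNTS = [
    # subfamily, n_htt, copy_number
    ("LTR/Gypsy", 1, 22547),
    ("LTR/Copia", 1, 3978),
    ("LINE/RTE-RTE", 10, 183155),
    ("LINE/RTE-BovB", 4, 130583),
    ("LINE/R1", 3, 485681),
    ("LINE/Proto2", 1, 21637),
    ("LINE/L2", 6, 209382),
    ("LINE/Dong-R4", 3, 22186),
    ("LINE/CR1-Zenon", 1, 380795),
    ("LINE/CR1", 4, 15874),
    ("DNA/Zator", 1, 5418),
    ("DNA/TcMar-Tc1", 12, 27452),
    ("DNA/TcMar-Mariner", 5, 13007),
    ("DNA/Helitron", 1, 774822),
    ("DNA/Maverick", 3, 1741),
]


def noctuid_te_loads() -> pd.DataFrame:
    """Genome size and TE load per class for ten noctuid species.

    Columns match the pipeline's genome-table schema: species, dte_pct,
    ltr_pct, line_pct, sine_pct, unc_pct, all_pct, genome_size_mb.
    """
    return pd.DataFrame(
        _TE_LOADS,
        columns=["species", "dte_pct", "ltr_pct", "line_pct", "sine_pct",
                 "unc_pct", "all_pct", "genome_size_mb"])


def noctuid_htt_counts() -> pd.DataFrame:
    """Published per-subfamily HTT counts and subfamily copy numbers for
    the ten-species comparison (columns subfamily, n_htt, copy_number)."""
    return pd.DataFrame(_HTT_COUNTS,
                        columns=["subfamily", "n_htt", "copy_number"])
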