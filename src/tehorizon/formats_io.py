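"""Readers, writers and record-level filters for the pipeline's file formats.

Covers the RepeatMasker ``.out`` annotation dialect, FASTA consensus/copy
sequences, Newick timetrees, the per-species genome-size / TE-load table,
and generic TSV result tables, plus the copy-level filters applied before
any downstream analysis:

* :func:`copy_length_filter` — keep copies at least a fraction (default
  80%) of their consensus length, the autonomous-copy criterion used for
  dS-based horizontal-transfer screening;
* :func:`library_filter` — drop consensus sequences whose best protein
  hits look like host (non-TE) proteins.

Coordinates are 1-based inclusive throughout, as in the ``.out`` dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .timetree import TimeTree

__all__ = [
    "AnnotatedCopy", "ConsensusRecord", "LibraryAlignmentRecord",
    "ParseError", "TE_CLASSES",
    "read_repeatmasker_out", "write_repeatmasker_out",
    "read_fasta", "write_fasta", "read_consensus_fasta",
    "read_newick_timetree",
    "copy_length_filter", "library_filter",
    "read_genome_table", "write_genome_table", "GENOME_TABLE_COLUMNS",
    "write_table", "read_table",
]

#: TE classes recognised by the pipeline (class component of "Class/Family").
TE_CLASSES = ("DNA", "LINE", "SINE", "LTR", "Unknown")

#: annotation classes that are not transposable elements and are dropped
#: at parse time.
NON_TE_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite",
                  "rRNA", "tRNA", "snRNA", "scRNA", "ARTEFACT")


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedCopy:
    """One annotated TE copy on a genome assembly."""

    copy_id: str
    species: str
    query_seq: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: str         # "+" or "-"
    subfamily: str      # "Class/Family"
    consensus_id: str
    percent_divergence: float  # fraction of sites diverged from consensus

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.copy_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.copy_id}: bad strand {self.strand!r}")
        if not 0.0 <= self.percent_divergence <= 1.0:
            raise ValueError(f"{self.copy_id}: divergence outside [0,1]")
        if self.te_class not in TE_CLASSES:
            raise ValueError(
                f"{self.copy_id}: unknown TE class {self.te_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def te_class(self) -> str:
        return self.subfamily.split("/", 1)[0]


@dataclass(frozen=True)
class ConsensusRecord:
    """A TE subfamily consensus (master) sequence."""

    consensus_id: str
    subfamily: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"{self.consensus_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LibraryAlignmentRecord:
    """One protein-database hit for a consensus library entry."""

    query_id: str
    subject_id: str
    percent_identity: float   # [0, 100]
    e_value: float
    query_coverage: float     # [0, 100]

    def __post_init__(self):
        for name in ("percent_identity", "query_coverage"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 100.0):
                raise ValueError(f"{self.query_id}: {name}={v!r} out of bounds")
        if not (math.isfinite(self.e_value) and self.e_value >= 0):
            raise ValueError(f"{self.query_id}: bad e-value {self.e_value!r}")


# ----------------------------------------------------------------------
# RepeatMasker .out
# ----------------------------------------------------------------------

def _normalise_subfamily(raw: str) -> str:
    """Map a .out class/family string onto the pipeline's Class/Family form."""
    if not raw or raw in (".", "-"):
        return "Unknown/Unknown"
    parts = raw.split("/", 1)
    cls = parts[0]
    fam = parts[1] if len(parts) > 1 else cls
    if cls not in TE_CLASSES:
        # e.g. RC/Helitron or novel labels: keep the family, class Unknown
        return f"Unknown/{fam}"
    return f"{cls}/{fam}"


def read_repeatmasker_out(path, species: str | None = None
                          ) -> list[AnnotatedCopy]:
    """Parse a 15-column RepeatMasker ``.out`` file into annotated copies.

    The three header lines are skipped; strand ``C`` is stored as ``-``;
    the percent-divergence column is stored as a fraction; rows annotated
    as simple repeats / low complexity (and other non-TE classes) are
    dropped; rows with a missing classification are kept as
    ``Unknown/Unknown``.
    """
    path = Path(path)
    if species is None:
        species = path.stem.split(".")[0]
    copies: list[AnnotatedCopy] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3 or not line.strip():
                continue
            fields = line.split()
            if len(fields) not in (14, 15, 16):
                raise ParseError(
                    f"{path.name}:{lineno}: expected 15 columns, "
                    f"got {len(fields)}")
            try:
                perc_div = float(fields[1])
                qbegin = int(fields[5])
                qend = int(fields[6])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric field: {exc}"
                ) from None
            strand = fields[8]
            if strand == "C":
                strand = "-"
            repeat_name = fields[9]
            raw_class = fields[10] if len(fields) >= 15 else ""
            if raw_class.split("/", 1)[0] in NON_TE_CLASSES:
                continue
            copies.append(AnnotatedCopy(
                copy_id=f"{species}:{fields[4]}:{qbegin}-{qend}",
                species=species,
                query_seq=fields[4],
                start=qbegin,
                end=qend,
                strand=strand,
                subfamily=_normalise_subfamily(raw_class),
                consensus_id=repeat_name,
                percent_divergence=perc_div / 100.0,
            ))
    return copies


_OUT_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "  repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end   (left)   repeat"
    "    class/family      begin end  (left) ID\n"
    "\n"
)


def write_repeatmasker_out(copies: Iterable[AnnotatedCopy], path) -> None:
    """Serialise copies back to the ``.out`` dialect (round-trip stable)."""
    with open(path, "w") as fh:
        fh.write(_OUT_HEADER)
        for i, c in enumerate(copies, start=1):
            strand = "C" if c.strand == "-" else "+"
            fh.write(
                f"{1000:>5} {c.percent_divergence * 100:.2f} 0.00 0.00 "
                f"{c.query_seq} {c.start} {c.end} (0) {strand} "
                f"{c.consensus_id} {c.subfamily} 1 {c.length} (0) {i}\n"
            )


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_consensus_fasta(path, subfamilies: Mapping[str, str] | None = None
                         ) -> dict[str, ConsensusRecord]:
    """Read consensus sequences; headers may be ``id#Class/Family``.

    ``subfamilies`` overrides/provides the classification per consensus id;
    ids without a classification become ``Unknown/Unknown``.
    """
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "#" in name:
            name, raw = name.split("#", 1)
            subfam = _normalise_subfamily(raw)
        else:
            subfam = "Unknown/Unknown"
        if subfamilies and name in subfamilies:
            subfam = subfamilies[name]
        out[name] = ConsensusRecord(consensus_id=name, subfamily=subfam,
                                    sequence=str(rec.seq).upper())
    return out


# ----------------------------------------------------------------------
# Newick timetree
# ----------------------------------------------------------------------

def read_newick_timetree(path, rel_tol: float = 1e-6) -> TimeTree:
    """Load a rooted ultrametric timetree (branch lengths in My).

    Ultrametricity is enforced within ``rel_tol * height``.
    """
    return TimeTree.from_file(path, rel_tol=rel_tol)


# ----------------------------------------------------------------------
# Copy-level filters
# ----------------------------------------------------------------------

def copy_length_filter(copies: Iterable[AnnotatedCopy],
                       consensus: Mapping[str, ConsensusRecord],
                       min_fraction: float = 0.8) -> list[AnnotatedCopy]:
    """Keep copies whose length is >= ``min_fraction`` of their consensus.

    The boundary is inclusive. Raises ``KeyError`` listing every copy whose
    ``consensus_id`` is not present in ``consensus``.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    copies = list(copies)
    missing = sorted({c.consensus_id for c in copies
                      if c.consensus_id not in consensus})
    if missing:
        raise KeyError(f"unresolvable consensus ids: {', '.join(missing)}")
    return [c for c in copies
            if c.length >= min_fraction * consensus[c.consensus_id].length]


def library_filter(records: Iterable[LibraryAlignmentRecord],
                   identity_min: float = 30.0,
                   evalue_max: float = 1e-5,
                   coverage_min: float = 50.0
                   ) -> tuple[set[str], set[str]]:
    """Split library queries into (kept, removed) by host-protein hits.

    A query is removed (treated as a non-TE protein) iff at least one of
    its records satisfies identity > ``identity_min`` AND
    e-value < ``evalue_max`` AND coverage > ``coverage_min``, all strict.
    """
    kept: set[str] = set()
    removed: set[str] = set()
    for r in records:
        if (r.percent_identity > identity_min
                and r.e_value < evalue_max
                and r.query_coverage > coverage_min):
            removed.add(r.query_id)
        else:
            kept.add(r.query_id)
    kept -= removed
    return kept, removed


# ----------------------------------------------------------------------
# Genome-size / TE-load table
# ----------------------------------------------------------------------

GENOME_TABLE_COLUMNS = ["species", "dte_pct", "ltr_pct", "line_pct",
                        "sine_pct", "unc_pct", "all_pct", "genome_size_mb"]

_PCT_COLUMNS = GENOME_TABLE_COLUMNS[1:7]


def _validate_genome_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"genome table missing columns: {missing}")
    df = df[GENOME_TABLE_COLUMNS].copy()
    pct = df[_PCT_COLUMNS].to_numpy(dtype=float)
    if np.any(pct < 0) or np.any(pct > 100):
        raise ParseError("genome table percentage outside [0, 100]")
    # each class column is printed rounded; allow +/-0.05 per class column
    class_sum = df[_PCT_COLUMNS[:-1]].sum(axis=1)
    if np.any(np.abs(class_sum - df["all_pct"]) > 0.05 * 5 + 1e-9):
        raise ParseError("total TE% inconsistent with class sum")
    return df


def read_genome_table(path) -> pd.DataFrame:
    """Read the per-species genome-size / TE-load TSV.

    Columns: species, dte_pct, ltr_pct, line_pct, sine_pct, unc_pct,
    all_pct, genome_size_mb.
    """
    return _validate_genome_table(pd.read_csv(path, sep="\t"))


def write_genome_table(df: pd.DataFrame, path) -> None:
    _validate_genome_table(df).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Generic result tables
# ----------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV; ``read_table(write_table(x)) == x``.

    Floats are written at full precision so round-trips are exact.
    """
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
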