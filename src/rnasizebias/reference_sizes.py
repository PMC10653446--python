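"""Transcript-size reference tables and log10 size binning.

Every size-resolved diagnostic in this package is anchored to a table mapping
each gene to a single transcript length in base pairs.  Genes with multiple
annotated variants are collapsed with the *variant-one* rule for mRNA (the
length of transcript variant 1 stands for the gene) and by arithmetic
averaging for lncRNA, whose variant annotation is less mature.  Lengths are
then profiled on a fixed 200-bin log10 grid spanning 1 to 360,000 bp.
"""

from __future__ import annotations


import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BiotypeConflictError,
    DomainError,
    EmptyInputError,
    InvalidRangeError,
    MissingVariantError,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 200
DEFAULT_LOG10_MAX = math.log10(360_000.0)


class Biotype(str, Enum):
    """Transcript class used throughout the size diagnostics."""

    MRNA = "mRNA"
    LNCRNA = "lncRNA"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: "Biotype | str") -> "Biotype":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            pass
        # common annotation synonyms
        low = str(value).lower()
        if low in {"mrna", "protein_coding", "protein-coding"}:
            return cls.MRNA
        if low in {"lncrna", "lincrna", "long_noncoding", "lnc_rna"}:
            return cls.LNCRNA
        return cls.OTHER


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript variant of a gene."""

    transcript_id: str
    gene_id: str
    biotype: Biotype
    length_bp: int
    variant_rank: int = 1

    def __post_init__(self):
        if not self.transcript_id or not self.gene_id:
            raise ValidationError("transcript_id and gene_id must be non-empty")
        object.__setattr__(self, "biotype", Biotype.coerce(self.biotype))
        if int(self.length_bp) < 1:
            raise ValidationError(f"length_bp must be >= 1, got {self.length_bp}")
        if int(self.variant_rank) < 1:
            raise ValidationError(f"variant_rank must be >= 1, got {self.variant_rank}")
        object.__setattr__(self, "length_bp", int(self.length_bp))
        object.__setattr__(self, "variant_rank", int(self.variant_rank))


@dataclass
class TranscriptSizeTable:
    """Unique gene id -> (length_bp, biotype).

    ``entries`` is a DataFrame indexed by gene_id with columns ``length_bp``
    (int) and ``biotype`` (str, one of the :class:`Biotype` values).
    """

    entries: pd.DataFrame
    source_label: str = ""

    def __post_init__(self):
        df = self.entries
        if list(df.columns) != ["length_bp", "biotype"]:
            df = df[["length_bp", "biotype"]]
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids in size table: {dupes[:5]}")
        if len(df) and (df["length_bp"] < 1).any():
            raise ValidationError("all lengths must be >= 1")
        df = df.assign(
            length_bp=df["length_bp"].astype(int),
            biotype=[Biotype.coerce(b).value for b in df["biotype"]],
        )
        self.entries = df

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.entries.index

    def length_of(self, gene_id: str) -> int:
        return int(self.entries.at[gene_id, "length_bp"])

    def lengths(self, biotype: Biotype | str | None = None) -> pd.Series:
        """Lengths in bp, optionally restricted to one biotype."""
        df = self.entries
        if biotype is not None:
            df = df[df["biotype"] == Biotype.coerce(biotype).value]
        return df["length_bp"]

    def subset(self, gene_ids: Iterable[str]) -> "TranscriptSizeTable":
        keep = self.entries.index.intersection(pd.Index(gene_ids))
        return TranscriptSizeTable(self.entries.loc[keep], source_label=self.source_label)


@dataclass(frozen=True)
class SizeBinning:
    """Half-open log10 binning of transcript lengths; last bin right-closed.

    The default grid partitions [0, log10(360000)) into 200 equal bins, a
    width of ~0.028 in log10 bp.
    """

    n_bins: int = DEFAULT_N_BINS
    log10_min: float = 0.0
    log10_max: float = DEFAULT_LOG10_MAX

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if not self.log10_max > self.log10_min:
            raise ValidationError("log10_max must exceed log10_min")

    @property
    def bin_width(self) -> float:
        return (self.log10_max - self.log10_min) / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.log10_min, self.log10_max, self.n_bins + 1)


def build_size_table(
    records: Sequence[TranscriptRecord],
    rule: str = "auto",
    source_label: str = "",
) -> TranscriptSizeTable:
    """Collapse per-variant records into one length per gene.

    Parameters
    ----------
    records
        Transcript variant records; a gene may appear many times.
    rule
        ``"auto"`` (default) applies variant-one to mRNA/other genes and
        arithmetic averaging to lncRNA genes; ``"variant_one"`` or
        ``"average"`` force a single rule for every biotype.
    """
    if rule not in {"auto", "variant_one", "average"}:
        raise ValidationError(f"unknown rule {rule!r}")
    if not records:
        raise EmptyInputError("no transcript records supplied")

    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)

    gene_ids, lengths, biotypes = [], [], []
    for gene_id, recs in by_gene.items():
        btypes = {r.biotype for r in recs}
        if len(btypes) > 1:
            raise BiotypeConflictError(gene_id, {b.value for b in btypes})
        biotype = recs[0].biotype
        if rule == "average" or (rule == "auto" and biotype is Biotype.LNCRNA):
            mean = sum(r.length_bp for r in recs) / len(recs)
            length = int(math.floor(mean + 0.5))  # round half-up: lengths are bp
        else:
            rank1 = [r for r in recs if r.variant_rank == 1]
            if not rank1:
                raise MissingVariantError(gene_id)
            if len(rank1) > 1:
                logger.warning(
                    "gene %s has %d rank-1 records; using the first", gene_id, len(rank1)
                )
            length = rank1[0].length_bp
        gene_ids.append(gene_id)
        lengths.append(length)
        biotypes.append(biotype.value)

    df = pd.DataFrame(
        {"length_bp": lengths, "biotype": biotypes}, index=pd.Index(gene_ids, name="gene_id")
    )
    return TranscriptSizeTable(df, source_label=source_label)


def count_in_size_range(
    table: TranscriptSizeTable,
    lo_bp: int,
    hi_bp: int,
    biotype: Biotype | str,
) -> int:
    """Number of genes of ``biotype`` with lo_bp <= length <= hi_bp (inclusive)."""
    if lo_bp > hi_bp:
        raise InvalidRangeError(f"lo_bp {lo_bp} > hi_bp {hi_bp}")
    lengths = table.lengths(biotype)
    return int(((lengths >= lo_bp) & (lengths <= hi_bp)).sum())


def assign_bins(
    lengths_bp: Sequence[int] | np.ndarray,
    binning: SizeBinning | None = None,
) -> np.ndarray:
    """Map lengths to bin indices on the log10 grid.

    Bin i covers [edges[i], edges[i+1]) with the last bin right-closed.
    Lengths above the grid clamp to the last bin with a logged warning.
    """
    binning = binning or SizeBinning()
    lengths = np.asarray(lengths_bp, dtype=float)
    if lengths.size and lengths.min() < 1:
        raise DomainError("all lengths must be >= 1 bp")
    log_l = np.log10(lengths)
    edges = binning.edges
    idx = np.searchsorted(edges, log_l, side="right") - 1
    over = log_l > binning.log10_max
    if over.any():
        logger.warning(
            "%d length(s) exceed %.0f bp; clamped to last bin",
            int(over.sum()),
            10.0**binning.log10_max,
        )
    # log10_max itself belongs to the (closed) last bin
    idx = np.clip(idx, 0, binning.n_bins - 1)
    return idx.astype(int)


def size_histogram(
    table: TranscriptSizeTable,
    binning: SizeBinning | None = None,
) -> pd.DataFrame:
    """Per-bin transcript counts by biotype.

    Returns a DataFrame with one row per bin: ``bin_index``, ``log10_left``,
    ``log10_right``, and a count column per biotype.  Counts per biotype sum
    exactly to the table's entry count.
    """
    if len(table) == 0:
        raise EmptyInputError("size table is empty")
    binning = binning or SizeBinning()
    edges = binning.edges
    out = pd.DataFrame(
        {
            "bin_index": np.arange(binning.n_bins),
            "log10_left": edges[:-1],
            "log10_right": edges[1:],
        }
    )
    for biotype in Biotype:
        lengths = table.lengths(biotype)
        counts = np.zeros(binning.n_bins, dtype=int)
        if len(lengths):
            np.add.at(counts, assign_bins(lengths.to_numpy(), binning), 1)
        out[f"count_{biotype.value}"] = counts
    return out


# -- I/O ---------------------------------------------------------------------

_RECORD_COLUMNS = ["gene_id", "transcript_id", "biotype", "variant_rank", "length_bp"]


def read_transcript_records_tsv(path) -> list[TranscriptRecord]:
    """Read per-variant records from a TSV with the standard header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"record TSV {path} missing columns: {missing}")
    return [
        TranscriptRecord(
            transcript_id=str(r.transcript_id),
            gene_id=str(r.gene_id),
            biotype=Biotype.coerce(r.biotype),
            length_bp=int(r.length_bp),
            variant_rank=int(r.variant_rank),
        )
        for r in df.itertuples(index=False)
    ]


def read_gtf_records(path) -> list[TranscriptRecord]:
    """Build transcript records from a GTF annotation.

    Transcript length is the sum of exon widths.  GTF carries no variant
    numbering, so variant ranks are assigned by order of first appearance of
    each transcript within its gene.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    exons = df[df["Feature"] == "exon"]
    if exons.empty:
        raise EmptyInputError(f"no exon features in {path}")
    biotype_col = next(
        (c for c in ("gene_biotype", "gene_type", "transcript_biotype") if c in exons.columns),
        None,
    )
    records: list[TranscriptRecord] = []
    rank_counter: dict[str, int] = {}
    # pyranges uses 0-based half-open coordinates, so width = End - Start
    grouped = exons.groupby("transcript_id", sort=False)
    for tx_id, sub in grouped:
        gene_id = str(sub["gene_id"].iloc[0])
        length = int((sub["End"] - sub["Start"]).sum())
        biotype = Biotype.coerce(sub[biotype_col].iloc[0]) if biotype_col else Biotype.OTHER
        rank = rank_counter.get(gene_id, 0) + 1
        rank_counter[gene_id] = rank
        records.append(
            TranscriptRecord(
                transcript_id=str(tx_id),
                gene_id=gene_id,
                biotype=biotype,
                length_bp=length,
                variant_rank=rank,
            )
        )
    return records


def read_size_table_tsv(path, source_label: str | None = None) -> TranscriptSizeTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length_bp", "biotype"):
        if col not in df.columns:
            raise ValidationError(f"size table TSV {path} missing column {col!r}")
    df = df.set_index("gene_id")[["length_bp", "biotype"]]
    return TranscriptSizeTable(df, source_label=source_label or str(path))


def write_size_table_tsv(table: TranscriptSizeTable, path) -> None:
    table.entries.reset_index().to_csv(path, sep="\t", index=False)


def write_histogram_tsv(histogram: pd.DataFrame, path) -> None:
    histogram.to_csv(path, sep="\t", index=False, float_format="%.6f")
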