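"""Data model and IO for molecule tables, genome layouts, interval sets and binned signal.

All genomic coordinates are 0-based, half-open internally. A molecule table is a
long-format pandas DataFrame with one row per deduplicated molecule (one NlaIII
site observed in one cell); it is the universal input of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of a molecule table
MOLECULE_COLUMNS = ["cell", "chrom", "pos", "strand"]
#: optional columns with defaults
MOLECULE_OPTIONAL = {"sample": "sample", "labeling": "single", "delta_t": np.nan}

MOLECULE_KEY = ["cell", "chrom", "pos", "strand"]


class SchemaError(ValueError):
    """A delimited input file is missing required columns."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp).

    Parameters
    ----------
    lengths : dict
        Mapping chromosome name -> length in bp. Lengths must be positive.
    """

    lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        for c, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {n}")
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate chromosome names")

    @property
    def chroms(self) -> list:
        return list(self.lengths)

    def __contains__(self, chrom) -> bool:
        return chrom in self.lengths

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return int(np.ceil(self.lengths[chrom] / bin_size))

    @classmethod
    def from_file(cls, path) -> "GenomeLayout":
        """Read a two-column chrom.sizes text file."""
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"])
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for c, n in self.lengths.items():
                fh.write(f"{c}\t{n}\n")


def read_molecule_table(path, layout: GenomeLayout, sep: str = "\t",
                        one_based: bool = False) -> pd.DataFrame:
    """Read and validate a long-format molecule table.

    Rows on chromosomes absent from ``layout`` are dropped with a warning;
    duplicate (cell, chrom, pos, strand) rows are collapsed to one. Positions
    may be declared 1-based with ``one_based=True`` and are converted.
    """
    df = pd.read_csv(path, sep=sep)
    return validate_molecule_table(df, layout, one_based=one_based)


def validate_molecule_table(df: pd.DataFrame, layout: GenomeLayout | None = None,
                            one_based: bool = False) -> pd.DataFrame:
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"molecule table is missing columns: {missing}")
    df = df.copy()
    for col, default in MOLECULE_OPTIONAL.items():
        if col not in df.columns:
            df[col] = default
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(np.int64)
    if one_based:
        df["pos"] -= 1
    if (df["pos"] < 0).any():
        raise ValueError("negative positions in molecule table")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError("strand must be '+' or '-'")
    if layout is not None:
        known = df["chrom"].isin(layout.lengths)
        n_dropped = int((~known).sum())
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} rows on chromosomes absent from layout",
                stacklevel=2,
            )
            df = df[known]
    n0 = len(df)
    df = df.drop_duplicates(subset=MOLECULE_KEY)
    if len(df) < n0:
        warnings.warn(f"collapsed {n0 - len(df)} duplicate molecule rows", stacklevel=2)
    return df.reset_index(drop=True)


def write_molecule_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# region sets

REGION_COLUMNS = ["chrom", "start", "end"]


def read_regions(path) -> pd.DataFrame:
    """Read a BED3+ file into a region table (chrom, start, end[, label[, score]])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = REGION_COLUMNS + ["label", "score"][: max(0, df.shape[1] - 3)]
    df = df.iloc[:, : len(names)]
    df.columns = names
    return validate_regions(df)


def validate_regions(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise ValueError("regions must satisfy start < end")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_regions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def overlap_length(starts_a, ends_a, start_b, end_b):
    """Vectorized overlap length of intervals [starts_a, ends_a) with [start_b, end_b)."""
    return np.maximum(
        0, np.minimum(ends_a, end_b) - np.maximum(starts_a, start_b)
    )


# ---------------------------------------------------------------------------
# binning

def bin_counts(df: pd.DataFrame, layout: GenomeLayout, bin_size: int,
               per_cell: bool = True) -> pd.DataFrame:
    """Count reads per fixed-width genomic bin.

    Returns a long DataFrame (cell, chrom, bin_start, value) where bins tile
    each chromosome from 0 with width ``bin_size``; empty bins are present with
    value 0. Bin index = floor(pos / bin_size). With ``per_cell=False`` reads of
    all cells are pooled (cell column omitted).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    cells = sorted(df["cell"].unique()) if per_cell else [None]
    if not cells:
        cells = [None]
    frames = []
    for chrom, length in layout.lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        edges = np.arange(n_bins + 1) * bin_size
        sub_chrom = df[df["chrom"] == chrom]
        for cell in cells:
            sub = sub_chrom if cell is None else sub_chrom[sub_chrom["cell"] == cell]
            counts, _ = np.histogram(sub["pos"].to_numpy(), bins=edges)
            frame = pd.DataFrame({
                "chrom": chrom,
                "bin_start": edges[:-1],
                "value": counts.astype(float),
            })
            if cell is not None:
                frame.insert(0, "cell", cell)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_bedgraph(binned: pd.DataFrame, path, bin_size: int,
                   layout: GenomeLayout | None = None) -> None:
    out = binned.copy()
    out["end"] = out["bin_start"] + bin_size
    if layout is not None:
        out["end"] = [
            min(e, layout.lengths.get(c, e)) for c, e in zip(out["chrom"], out["end"])
        ]
    out[["chrom", "bin_start", "end", "value"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def max_normalize_heatmap(df: pd.DataFrame, order: pd.DataFrame,
                          layout: GenomeLayout, chrom: str,
                          window: tuple[int, int] | None = None,
                          bin_size: int = 50_000) -> pd.DataFrame:
    """Per-cell max-normalized binned signal for replication-track heatmaps.

    Cells are arranged by their S-phase consensus position (``order`` must carry
    columns cell, consensus_position). Each cell's 50-kb binned counts on
    ``chrom`` are divided by the maximum bin value observed for that cell on
    that chromosome, so rows lie in [0, 1]; an all-zero row stays zero. The
    returned DataFrame is cells (rows, in S-phase order) x bin starts (columns),
    restricted to ``window`` if given.
    """
    if chrom not in layout:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if window is not None and window[0] >= window[1]:
        raise ValueError("empty window")
    sub = df[df["chrom"] == chrom]
    binned = bin_counts(sub, GenomeLayout({chrom: layout.lengths[chrom]}), bin_size)
    n_bins = layout.n_bins(chrom, bin_size)
    cols = np.arange(n_bins) * bin_size
    if len(binned) and "cell" in binned.columns:
        mat = binned.pivot_table(index="cell", columns="bin_start",
                                 values="value", fill_value=0.0)
        mat = mat.reindex(columns=cols, fill_value=0.0)
    else:
        mat = pd.DataFrame(np.zeros((0, n_bins)), columns=cols)
    # normalize before windowing: the divisor is the chromosome-wide maximum
    row_max = mat.max(axis=1)
    nonzero = row_max > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(row_max[nonzero], axis=0)
    # every cell of the ordering appears as a row; chrom-empty cells are zero
    ordered = [c for c in order.sort_values("consensus_position")["cell"]
               if c in set(df["cell"])]
    mat = mat.reindex(ordered).fillna(0.0)
    if window is not None:
        cols = [b for b in mat.columns if window[0] <= b < window[1]]
        if not cols:
            raise ValueError("window contains no bins")
        mat = mat[cols]
    return mat
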