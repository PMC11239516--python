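"""Replication-track calling, width correction and fork counting.

A cell's reads are segmented per chromosome by the fitted
:class:`~replifork.hsmm.ReplicationHSMM`: maximal runs of foreground gaps
define tracks; the reads flanking those gaps belong to the track. The raw
track width w (first to last read) underestimates the labeled stretch, so it
is corrected like the maximum of a sampled uniform distribution:

    corrected width = w + w / (n - 1)

with n the number of reads in the track. A single-pulse speed estimate is the
corrected width over the pulse length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hsmm import FOREGROUND, HSMMResults, ReplicationHSMM

MIN_GAPS_PER_CELL = 20


def correct_width(w: float, n: int) -> float:
    """Sampling-corrected track width, w + w/(n-1). Requires n >= 2."""
    if n < 2:
        raise ValueError("width correction needs at least 2 reads")
    if w < 0:
        raise ValueError("width must be nonnegative")
    return w + w / (n - 1)


def fit_cell_hsmm(df: pd.DataFrame, cell: str | None = None,
                  dmax: int = 300, **fit_kw) -> HSMMResults:
    """Fit the 2-state HSMM on one cell's per-chromosome gap sequences."""
    sub = df if cell is None else df[df["cell"] == cell]
    seqs = []
    for _, grp in sub.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        if len(pos) >= 2:
            seqs.append(np.diff(pos))
    total = sum(len(s) for s in seqs)
    if total < MIN_GAPS_PER_CELL:
        raise ValueError(
            f"cell has {total} inter-read distances; need >= {MIN_GAPS_PER_CELL}")
    return ReplicationHSMM(seqs, dmax=dmax).fit(**fit_kw)


def viterbi_tracks(result: HSMMResults, df: pd.DataFrame,
                   cell: str | None = None) -> pd.DataFrame:
    """Call replication tracks for one cell from the decoded state path.

    Returns a DataFrame (cell, chrom, start, end, n, w, corrected_width,
    posterior) with one row per maximal foreground run; tracks are disjoint
    and sorted within chromosomes. Chromosomes with < 2 reads yield no tracks.
    """
    sub = df if cell is None else df[df["cell"] == cell]
    rows = []
    for chrom, grp in sub.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        states = result.decode(gaps)
        post = result.state_posteriors(gaps)[FOREGROUND] if not result.collapsed \
            else (states == FOREGROUND).astype(float)
        fg = states == FOREGROUND
        if not fg.any():
            continue
        bounds = np.flatnonzero(np.diff(fg.astype(int)))
        starts = np.concatenate([[0] if fg[0] else [], bounds[~fg[bounds]] + 1]).astype(int)
        ends = np.concatenate([bounds[fg[bounds]], [len(gaps) - 1] if fg[-1] else []]).astype(int)
        for a, b in zip(starts, ends):
            # gaps a..b foreground -> reads a..b+1
            n = b - a + 2
            w = pos[b + 1] - pos[a]
            cw = correct_width(w, n) if n >= 2 and w > 0 else np.nan
            rows.append({
                "cell": grp["cell"].iloc[0], "chrom": chrom,
                "start": int(pos[a]), "end": int(pos[b + 1]),
                "n": n, "w": float(w), "corrected_width": cw,
                "posterior": float(post[a: b + 1].mean()),
            })
    cols = ["cell", "chrom", "start", "end", "n", "w", "corrected_width", "posterior"]
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def segment_cell(df: pd.DataFrame, cell: str | None = None,
                 dmax: int = 300, **fit_kw):
    """Fit + decode in one step. Returns (tracks, HSMMResults)."""
    res = fit_cell_hsmm(df, cell, dmax=dmax, **fit_kw)
    return viterbi_tracks(res, df, cell), res


def single_pulse_speed(tracks: pd.DataFrame, pulse_len: float = 15.0) -> pd.Series:
    """Per-track width-based speed (kb/min): corrected width / pulse length.

    Tracks without a defined corrected width (n < 2) are NaN.
    """
    return tracks["corrected_width"] / 1000 / pulse_len


def cell_speed_summary(tracks: pd.DataFrame, pulse_len: float = 15.0) -> pd.DataFrame:
    """Median width-based speed per cell over tracks with defined widths."""
    t = tracks.assign(speed=single_pulse_speed(tracks, pulse_len))
    return (t.dropna(subset=["speed"]).groupby("cell")["speed"]
            .median().rename("median_speed").reset_index())


def count_forks(tracks: pd.DataFrame, min_reads: int = 2) -> pd.DataFrame:
    """Fork counts per cell (tracks with >= min_reads reads), plus the >= 3-read
    subset that dominates real data."""
    t = tracks[tracks["n"] >= min_reads]
    rows = []
    for cell, grp in t.groupby("cell"):
        rows.append({
            "cell": cell,
            "forks_total": len(grp),
            "forks_3plus": int((grp["n"] >= 3).sum()),
            "mean_reads_per_fork": float(grp["n"].mean()),
        })
    return pd.DataFrame(rows, columns=["cell", "forks_total", "forks_3plus",
                                       "mean_reads_per_fork"])


def downsample_analysis(df: pd.DataFrame, fractions, seed: int | None = None,
                        min_reads: int = 2, dmax: int = 300) -> pd.DataFrame:
    """Detected forks per cell after downsampling unique reads.

    For each fraction the reads are subsampled without replacement and the
    HSMM refitted from scratch (a fresh segmentation per fraction). Returns a
    DataFrame (fraction, cell, forks_total, forks_3plus, n_reads).
    """
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        if frac == 1.0:
            sub = df
        else:
            keep = rng.random(len(df)) < frac
            sub = df[keep]
        for cell in sorted(sub["cell"].unique()):
            try:
                tracks, _ = segment_cell(sub, cell, dmax=dmax)
            except ValueError:
                continue
            counts = count_forks(tracks, min_reads)
            rows.append({
                "fraction": frac, "cell": cell,
                "forks_total": int(counts["forks_total"].iloc[0]) if len(counts) else 0,
                "forks_3plus": int(counts["forks_3plus"].iloc[0]) if len(counts) else 0,
                "n_reads": int((sub["cell"] == cell).sum()),
            })
    return pd.DataFrame(rows)


def write_tracks_bed(tracks: pd.DataFrame, path) -> None:
    """Export tracks as BED6+ (chrom, start, end, cell, n, corrected_width)."""
    out = tracks[["chrom", "start", "end", "cell", "n", "corrected_width"]]
    out.to_csv(path, sep="\t", index=False, header=False)
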