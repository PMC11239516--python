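"""Annotation-conditioned analyses: replication-timing scores, origin-track
correlation over S phase, expression transforms and region-weighted speed
densities."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import overlap_length


def rt_score(early, late):
    """Replication-timing score (early - late) / (early + late), in [-1, 1].

    Vectorized; bins with early + late = 0 yield NaN (excluded downstream).
    """
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    if (early < 0).any() or (late < 0).any():
        raise ValueError("read counts must be nonnegative")
    total = early + late
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(total > 0, (early - late) / np.where(total > 0, total, 1),
                         np.nan)
    return score if score.ndim else float(score)


def cumulative_origin_correlation(binned: pd.DataFrame, order: pd.DataFrame,
                                  origin: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between cumulative scEdU reads and an origin track.

    ``binned``: per-cell 100-kb bin counts (cell, chrom, bin_start, value);
    ``order``: cell, consensus_position; ``origin``: chrom, bin_start, value
    on the same bins. Cells are accumulated in S-phase order; after each cell
    the binwise Pearson correlation of the cumulative counts with the origin
    signal is computed.

    Returns (cell, s_phase_position, pearson); prefixes whose cumulative
    vector has zero variance yield NaN.
    """
    key = ["chrom", "bin_start"]
    origin = origin.sort_values(key).reset_index(drop=True)
    grid = origin[key]
    osig = origin["value"].to_numpy(dtype=float)
    mat = (binned.pivot_table(index=key, columns="cell", values="value",
                              fill_value=0.0)
           .reindex(pd.MultiIndex.from_frame(grid), fill_value=0.0))
    ordered = order.sort_values("consensus_position")
    rows = []
    cum = np.zeros(len(grid))
    for _, r in ordered.iterrows():
        cell = r["cell"]
        if cell in mat.columns:
            cum = cum + mat[cell].to_numpy(dtype=float)
        if cum.std() == 0 or osig.std() == 0:
            rho = np.nan
        else:
            rho = float(stats.pearsonr(cum, osig).statistic)
        rows.append({"cell": cell, "s_phase_position": r["consensus_position"],
                     "pearson": rho})
    return pd.DataFrame(rows)


def transform_expression(genes: pd.DataFrame) -> pd.DataFrame:
    """Transformed pseudo-bulk expression track: round(log10(counts + 1)).

    ``genes``: chrom, start, end, gene, counts. Overlapping genes are resolved
    by giving the overlapping portion to the gene with the higher raw count
    (ties: earlier interval start wins); the output intervals are disjoint.
    """
    if (genes["counts"] < 0).any():
        raise ValueError("counts must be nonnegative")
    g = genes.copy()
    g["transformed"] = np.round(np.log10(g["counts"] + 1)).astype(int)
    out = []
    for chrom, grp in g.groupby("chrom"):
        grp = grp.sort_values("start").reset_index(drop=True)
        edges = np.unique(np.concatenate([grp["start"].to_numpy(),
                                          grp["end"].to_numpy()]))
        for a, b in zip(edges[:-1], edges[1:]):
            cover = grp[(grp["start"] < b) & (grp["end"] > a)]
            if cover.empty:
                continue
            # higher raw count wins; ties to the earlier start
            best = cover.sort_values(["counts", "start"],
                                     ascending=[False, True]).iloc[0]
            out.append({"chrom": chrom, "start": int(a), "end": int(b),
                        "gene": best["gene"], "counts": int(best["counts"]),
                        "transformed": int(best["transformed"])})
    res = pd.DataFrame(out, columns=["chrom", "start", "end", "gene",
                                     "counts", "transformed"])
    # merge adjacent pieces of the same winner back together
    merged = []
    for _, row in res.iterrows():
        if merged and merged[-1]["chrom"] == row["chrom"] \
                and merged[-1]["end"] == row["start"] \
                and merged[-1]["gene"] == row["gene"]:
            merged[-1]["end"] = row["end"]
        else:
            merged.append(dict(row))
    return pd.DataFrame(merged, columns=res.columns)


def span_region_overlap(spans: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Fraction of each span [start, end) covered by the union of regions."""
    frac = np.zeros(len(spans))
    for chrom, grp in spans.groupby("chrom"):
        reg = regions[regions["chrom"] == chrom].sort_values("start")
        if reg.empty:
            continue
        # merge region union first
        starts, ends = [], []
        for _, r in reg.iterrows():
            if starts and r["start"] <= ends[-1]:
                ends[-1] = max(ends[-1], r["end"])
            else:
                starts.append(r["start"])
                ends.append(r["end"])
        starts = np.array(starts, dtype=float)
        ends = np.array(ends, dtype=float)
        for i, row in grp.iterrows():
            ov = overlap_length(starts, ends, row["start"], row["end"]).sum()
            width = row["end"] - row["start"]
            frac[spans.index.get_loc(i)] = ov / width if width > 0 else 0.0
    return frac


def weighted_speed_by_region(spans: pd.DataFrame, posteriors: np.ndarray,
                             regions: pd.DataFrame, delta_t: float,
                             grid: np.ndarray | None = None,
                             bandwidth: float | None = None):
    """Max-normalized speed densities inside vs outside a region class.

    Each pair distance, taken as the genomic span between its two reads, gets
    weight = (fraction of the span overlapping the regions) x (posterior of
    the mixture's normal/speed component); the complementary weight
    (1 - fraction) x posterior feeds the outside density. Densities are
    Gaussian-kernel weighted histograms over implied speed = distance / Δt,
    max-normalized.

    Returns a DataFrame (speed, inside, outside).
    """
    if regions.empty:
        warnings.warn("empty region set: no inside density", stacklevel=2)
    speeds = spans["distance"].to_numpy(dtype=float) / 1000 / delta_t
    frac = span_region_overlap(spans, regions)
    w_in = frac * posteriors
    w_out = (1 - frac) * posteriors
    if grid is None:
        grid = np.linspace(0, max(speeds.max() * 1.05, 1e-9), 200)
    if bandwidth is None:
        bandwidth = (grid[-1] - grid[0]) / 50 or 1.0

    def kde(w):
        if w.sum() <= 0:
            return np.zeros_like(grid)
        dens = np.exp(-0.5 * ((grid[:, None] - speeds[None, :]) / bandwidth) ** 2)
        dens = dens @ w
        mx = dens.max()
        return dens / mx if mx > 0 else dens

    return pd.DataFrame({"speed": grid, "inside": kde(w_in),
                         "outside": kde(w_out)}), (speeds, w_in, w_out)


def resampling_test(speeds: np.ndarray, w_a: np.ndarray, w_b: np.ndarray,
                    n_draws: int = 10_000, seed: int | None = None,
                    n_classes: int = 1) -> dict:
    """Two-sided resampling t-test between two weighted speed distributions.

    Draws ``n_draws`` samples from each weighted empirical distribution and
    applies Welch's t-test; the p-value is Bonferroni-scaled by ``n_classes``.
    """
    rng = np.random.default_rng(seed)
    pa = w_a / w_a.sum()
    pb = w_b / w_b.sum()
    a = rng.choice(speeds, size=n_draws, p=pa)
    b = rng.choice(speeds, size=n_draws, p=pb)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(min(p * n_classes, 1.0)),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}


def zscore_bulk_tracks(a: pd.DataFrame, b: pd.DataFrame) -> tuple:
    """Z-score two binned samples per sample and give their Spearman correlation.

    ``a`` and ``b``: BinnedSignal frames (chrom, bin_start, value) on identical
    bins. Returns (z-scored merged frame, spearman rho).
    """
    key = ["chrom", "bin_start"]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("samples must share identical bins")
    out = merged.copy()
    for col in ("value_a", "value_b"):
        sd = out[col].std(ddof=0)
        if sd == 0:
            raise ValueError(f"zero-variance sample in {col}")
        out[col.replace("value", "z")] = (out[col] - out[col].mean()) / sd
    rho = float(stats.spearmanr(out["z_a"], out["z_b"]).statistic)
    return out, rho
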