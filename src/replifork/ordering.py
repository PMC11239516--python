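"""S-phase ordering from pairwise overlap of kernel-smoothed replication profiles.

Each cell's foreground reads are smoothed with a Gaussian kernel
(sd 8,333.333 bp); the Szymkiewicz-Simpson overlap coefficient between two
cells' profiles, per chromosome, is converted to a distance

    Distance = min(1/score - 1, 1000)

and averaged over chromosomes. The distance matrix is embedded in one
dimension with UMAP, repeated with distinct seeds; each run's axis is
z-scored and sign-aligned, discordant runs (mean |Spearman rho| < 0.85) are
discarded, and a cell is kept only when at least 80% of the retained runs
place it in one cluster (successive-placement gaps < 0.1). The consensus
position is the mean of that cluster, ranked to S-phase progression in [0, 1].
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeLayout

KERNEL_SD = 8333.333      # bp
GRID_STEP = 2500          # bp, ~ sd / 3.3
DISTANCE_CAP = 1000.0
SPEARMAN_MIN = 0.85
CLUSTER_GAP = 0.1
CLUSTER_FRACTION = 0.8


class OrderingError(RuntimeError):
    """The consensus embedding failed (too few concordant runs)."""


def smooth_profile(df: pd.DataFrame, layout: GenomeLayout,
                   grid_step: int = GRID_STEP,
                   kernel_sd: float = KERNEL_SD) -> dict:
    """Gaussian-kernel smoothed read density per chromosome for one cell.

    Each read contributes a unit-mass Gaussian (sd ``kernel_sd`` bp) evaluated
    on a regular grid, so the profile sums to the read count up to edge
    truncation. Returns {chrom: ndarray of grid values}.
    """
    if df.empty:
        warnings.warn("empty cell: zero profile", stacklevel=2)
    profiles = {}
    halfwidth = int(np.ceil(5 * kernel_sd / grid_step))
    for chrom, length in layout.lengths.items():
        n_grid = int(np.ceil(length / grid_step))
        prof = np.zeros(n_grid)
        pos = df.loc[df["chrom"] == chrom, "pos"].to_numpy(dtype=float)
        if len(pos):
            centers = pos / grid_step
            offsets = np.arange(-halfwidth, halfwidth + 1)
            idx = np.floor(centers)[:, None].astype(int) + offsets[None, :]
            grid_pos = idx * grid_step
            dens = np.exp(-0.5 * ((grid_pos - pos[:, None]) / kernel_sd) ** 2)
            dens *= grid_step / (kernel_sd * np.sqrt(2 * np.pi))
            valid = (idx >= 0) & (idx < n_grid)
            np.add.at(prof, idx[valid], dens[valid])
        profiles[chrom] = prof
    return profiles


def score_to_distance(score) -> np.ndarray | float:
    """Convert an overlap coefficient to a distance, min(1/score - 1, 1000).

    A score of 0 (disjoint profiles) maps to the cap, 1000.
    """
    score = np.asarray(score, dtype=float)
    with np.errstate(divide="ignore"):
        d = np.where(score > 0, np.minimum(1.0 / np.maximum(score, 1e-300) - 1.0,
                                           DISTANCE_CAP), DISTANCE_CAP)
    return d if d.ndim else float(d)


def overlap_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Szymkiewicz-Simpson overlap of two nonnegative profiles:
    sum(min(a, b)) / min(sum(a), sum(b)); 0 when either profile is empty."""
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        return 0.0
    return float(np.minimum(a, b).sum() / min(sa, sb))


def overlap_distance(a: dict, b: dict) -> float:
    """Mean over chromosomes of the per-chromosome overlap distance."""
    dists = [score_to_distance(overlap_coefficient(a[c], b[c])) for c in a]
    return float(np.mean(dists))


def distance_matrix(profiles: list[dict]) -> np.ndarray:
    """Symmetric cell-by-cell overlap-distance matrix (diagonal 0).

    Vectorized over cells: per chromosome, profiles are stacked into a matrix
    and all pairwise Sum-min overlaps computed at once.
    """
    n = len(profiles)
    chroms = list(profiles[0])
    per_chrom = []
    for c in chroms:
        mat = np.stack([p[c] for p in profiles])         # n x grid
        sums = mat.sum(axis=1)
        ov = np.zeros((n, n))
        for i in range(n):
            ov[i] = np.minimum(mat[i][None, :], mat).sum(axis=1)
        denom = np.minimum(sums[:, None], sums[None, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(denom > 0, ov / denom, 0.0)
        d = score_to_distance(score)
        per_chrom.append(d)
    D = np.mean(per_chrom, axis=0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2


def _umap_1d(D: np.ndarray, seed: int, n_neighbors: int) -> np.ndarray:
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(
            n_components=1, metric="precomputed", n_neighbors=n_neighbors,
            min_dist=0.1, random_state=int(seed) % (2**31 - 1),
        ).fit_transform(D)
    return emb[:, 0]


def embed_order(D: np.ndarray, cells: list[str], n_runs: int = 100,
                seed: int | None = None, n_neighbors: int = 15,
                reference: np.ndarray | None = None) -> pd.DataFrame:
    """Consensus 1-D embedding of an overlap-distance matrix.

    Runs ``n_runs`` seeded UMAP embeddings to one dimension, z-scores each
    axis, discards runs whose mean |Spearman rho| against the other runs is
    below 0.85, sign-aligns the rest to the first retained run, and clusters
    each cell's placements (successive gap >= 0.1 starts a new cluster). A
    cell is kept when its largest cluster holds >= 80% of the retained runs;
    its consensus position is that cluster's mean, ranked across kept cells
    to S-phase progression in [0, 1].

    ``reference`` (optional, one value per cell, e.g. each cell's true or
    surrogate S-phase stage) orients the axis so progression correlates
    positively with it. Without it the orientation is arbitrary (reported in
    the 'oriented' attribute).

    Raises OrderingError when fewer than half the runs are concordant.
    """
    n = D.shape[0]
    if n < 10:
        raise ValueError("need at least 10 cells to order")
    n_neighbors = min(n_neighbors, n - 1)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_runs)
    runs = np.empty((n_runs, n))
    for r in range(n_runs):
        axis = _umap_1d(D, seeds[r], n_neighbors)
        sd = axis.std()
        runs[r] = (axis - axis.mean()) / sd if sd > 0 else axis * 0.0

    # run concordance on |Spearman| (sign-free)
    rho = stats.spearmanr(runs, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-run case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, np.nan)
    mean_abs = np.nanmean(np.abs(rho), axis=1)
    retained = mean_abs >= SPEARMAN_MIN
    n_ok = int(retained.sum())
    if n_ok < n_runs / 2:
        raise OrderingError(
            f"only {n_ok}/{n_runs} embedding runs concordant (need >= 50%)")
    kept_runs = np.flatnonzero(retained)
    anchor = kept_runs[0]
    placements = runs[kept_runs].copy()
    for j, r in enumerate(kept_runs):
        if r == anchor:
            continue
        if stats.spearmanr(runs[anchor], runs[r]).statistic < 0:
            placements[j] = -placements[j]

    rows = []
    for i in range(n):
        vals = np.sort(placements[:, i])
        splits = np.flatnonzero(np.diff(vals) >= CLUSTER_GAP) + 1
        clusters = np.split(vals, splits)
        largest = max(clusters, key=len)
        kept = len(largest) >= CLUSTER_FRACTION * n_ok
        rows.append({
            "cell": cells[i],
            "consensus_position": float(largest.mean()),
            "kept": bool(kept),
            "n_successful_runs": n_ok,
        })
    out = pd.DataFrame(rows)

    oriented = False
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        r = stats.spearmanr(out["consensus_position"], ref).statistic
        if np.isfinite(r) and r < 0:
            out["consensus_position"] = -out["consensus_position"]
        oriented = True

    # rank kept cells to [0, 1] progression
    kept_mask = out["kept"].to_numpy()
    if kept_mask.sum() >= 2:
        ranks = stats.rankdata(out.loc[kept_mask, "consensus_position"])
        out.loc[kept_mask, "consensus_position"] = (ranks - 1) / (len(ranks) - 1)
    out.attrs["oriented"] = oriented
    return out


def order_cells(df: pd.DataFrame, layout: GenomeLayout, n_runs: int = 100,
                seed: int | None = None, grid_step: int = GRID_STEP,
                reference: np.ndarray | None = None) -> pd.DataFrame:
    """Smoothed-profile overlap ordering of a (foreground-filtered) cohort."""
    cells = sorted(df["cell"].unique())
    profiles = [smooth_profile(df[df["cell"] == c], layout, grid_step)
                for c in cells]
    D = distance_matrix(profiles)
    return embed_order(D, cells, n_runs=n_runs, seed=seed, reference=reference)
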