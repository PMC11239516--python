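"""Per-cell quality filters and foreground-read selection.

Cells are filtered on the average count per 100-kb bin — lower/upper
thresholds of 0.37/2.72 reads per bin for single-pulse labeling and
0.08/12.18 for double-pulse — and on dispersion relative to Poisson. A pure
background cell has CV = 1/sqrt(mean), i.e. log(CV) = -0.5 * log(mean)
exactly; genuine pulse-labeled cells carry clustered replication tracks and
are over-dispersed. A cell therefore passes the dispersion criterion when

    log(CV) > -0.5 * log(mean) + 0.1        (natural logs)

— it deviates from Poisson behavior by the 0.1 margin — and is discarded as
signal-free otherwise.

Foreground reads are then selected per cell with a two-component exponential
mixture fitted by EM on the distances between successive reads; a read is
kept when the posterior of the short-distance component, evaluated at its
distance to the nearest flanking read, exceeds 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeLayout, bin_counts

QC_BIN_SIZE = 100_000

#: density thresholds (reads per 100-kb bin) per labeling mode
DENSITY_THRESHOLDS = {"single": (0.37, 2.72), "double": (0.08, 12.18)}
DISPERSION_THRESHOLD = 0.1


def compute_qc(df: pd.DataFrame, layout: GenomeLayout,
               thresholds: dict | None = None) -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail flags.

    Returns a DataFrame with columns cell, labeling, mean_per_100kb, cv,
    pass_density, pass_dispersion, pass_all. The mean and CV are taken over
    all 100-kb bins of the genome (zeros included).
    """
    thresholds = thresholds or DENSITY_THRESHOLDS
    binned = bin_counts(df, layout, QC_BIN_SIZE)
    labeling = df.groupby("cell")["labeling"].first()
    rows = []
    for cell, sub in binned.groupby("cell"):
        vals = sub["value"].to_numpy()
        mean = vals.mean()
        mode = labeling.get(cell, "single")
        lo, hi = thresholds[mode]
        pass_density = bool(lo <= mean <= hi)
        if (vals > 0).sum() < 2 or mean == 0:
            warnings.warn(f"cell {cell}: CV undefined, failing dispersion", stacklevel=2)
            cv, pass_dispersion = np.nan, False
        else:
            cv = vals.std(ddof=0) / mean
            pass_dispersion = bool(
                np.log(cv) > -0.5 * np.log(mean) + DISPERSION_THRESHOLD)
        rows.append({
            "cell": cell, "labeling": mode, "mean_per_100kb": mean, "cv": cv,
            "pass_density": pass_density, "pass_dispersion": pass_dispersion,
            "pass_all": pass_density and pass_dispersion,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-component exponential mixture

@dataclass
class ExpMixtureFit:
    means: np.ndarray     # component means, means[0] = foreground (smaller)
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def posterior_foreground(self, x) -> np.ndarray:
        """Posterior probability that distance x came from the short component."""
        x = np.asarray(x, dtype=float)
        log_p = (np.log(self.weights)[:, None]
                 - np.log(self.means)[:, None]
                 - x[None, :] / self.means[:, None])
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return p[0] / p.sum(axis=0)


def fit_exponential_mixture(x: np.ndarray, max_iter: int = 200,
                            rtol: float = 1e-8) -> ExpMixtureFit:
    """EM fit of a 2-component exponential mixture, initialized by a median split."""
    x = np.asarray(x, dtype=float)
    x = x[x > 0]
    if len(x) < 2:
        raise ValueError("need at least 2 positive distances")
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    means = np.array([max(lo.mean(), 1e-9), max(hi.mean() if len(hi) else med, 1e-9)])
    if means[0] == means[1]:
        means[1] *= 1.0 + 1e-6
    weights = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        log_p = (np.log(weights)[:, None] - np.log(means)[:, None]
                 - x[None, :] / means[:, None])
        m = log_p.max(axis=0)
        lse = m + np.log(np.exp(log_p - m).sum(axis=0))
        ll = lse.sum()
        resp = np.exp(log_p - lse)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        weights = nk / nk.sum()
        means = np.maximum(resp @ x / nk, 1e-9)
        if abs(ll - prev_ll) <= rtol * abs(ll):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(means)
    return ExpMixtureFit(means[order], weights[order], float(prev_ll), it, converged)


def select_foreground_reads(df: pd.DataFrame, cell: str | None = None,
                            threshold: float = 0.5) -> pd.DataFrame:
    """Assign per-read foreground posteriors for one cell.

    The mixture is fitted on successive-read distances pooled over
    chromosomes; each read's score is the posterior at its distance to the
    nearest flanking read (chromosome ends use their single gap). Returns the
    cell's rows with added columns posterior_fg and keep.

    If EM fails to converge, the cell is flagged and all reads kept.
    """
    sub = df if cell is None else df[df["cell"] == cell]
    sub = sub.sort_values(["chrom", "pos"]).reset_index(drop=True)
    gaps_all, nearest = [], np.full(len(sub), np.nan)
    for chrom, idx in sub.groupby("chrom").groups.items():
        pos = sub.loc[idx, "pos"].to_numpy(dtype=float)
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        gaps_all.append(gaps)
        left = np.concatenate([[np.inf], gaps])
        right = np.concatenate([gaps, [np.inf]])
        nearest[np.asarray(idx)] = np.minimum(left, right)
    if not gaps_all:
        raise ValueError("cell needs >= 2 reads on at least one chromosome")
    gaps_all = np.concatenate(gaps_all)
    fit = fit_exponential_mixture(np.maximum(gaps_all, 0.5))
    out = sub.copy()
    if not fit.converged:
        warnings.warn("exponential mixture EM did not converge; keeping all reads",
                      stacklevel=2)
        out["posterior_fg"] = 1.0
        out["keep"] = True
        return out
    has_gap = np.isfinite(nearest)
    post = np.zeros(len(out))
    post[has_gap] = fit.posterior_foreground(np.maximum(nearest[has_gap], 0.5))
    out["posterior_fg"] = post
    out["keep"] = post > threshold
    return out


def filter_cells(df: pd.DataFrame, layout: GenomeLayout,
                 thresholds: dict | None = None):
    """Apply density/dispersion QC then foreground selection to a cohort.

    Returns (foreground molecule table, qc metrics table).
    """
    metrics = compute_qc(df, layout, thresholds)
    keep_cells = set(metrics.loc[metrics["pass_all"], "cell"])
    frames = []
    for cell in sorted(keep_cells):
        scored = select_foreground_reads(df, cell)
        frames.append(scored[scored["keep"]])
    fg = (pd.concat(frames, ignore_index=True) if frames
          else df.iloc[0:0].assign(posterior_fg=[], keep=[]))
    return fg, metrics
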