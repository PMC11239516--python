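"""Synthetic-data generators for pulse-labeled replication reads.

Three generators are provided:

``simulate_pulse_tracks``
    The single- vs double-pulse estimator comparison: reads per pulse are
    Poisson, placed uniformly inside unit pulse windows (0-1 for the first
    pulse, 2-3 for the second), which fixes the ground-truth fork speed at
    1 unit per pulse length (1 kb/min with the 15-min pulse default).

``simulate_paircorr_cell``
    The pair-correlation weighting-bias experiment: candidate reads uniform
    on [-200, 200] kb (Poisson mean 80), retained only inside the two pulse
    windows (-45s, -30s) and (30s, 45s), where the window scaling s — the
    fork speed in kb/min — is truncated-normal (at 0). In the equal-intensity
    scenario read density per kb is constant so faster forks retain
    proportionally more reads (the bias the correction surface removes); in
    the unequal-intensity scenario the uniform support is scaled by s as
    well, so every fork retains the same expected number of reads.

``simulate_whole_cell``
    An end-to-end generator that drops bidirectional origins on a genome,
    labels fork windows according to a pulse scheme, and samples deduplicated
    reads plus uniform background — the integration fixture for QC, ordering,
    segmentation and speed estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeLayout

DEFAULT_PULSE_LEN = 15.0  # minutes


@dataclass(frozen=True)
class PulseScheme:
    """EdU pulse timing: two pulses of ``pulse_len`` minutes separated by ``gap``.

    ``delta_t`` is the center-to-center spacing, pulse_len + gap; the
    experimental values are 45, 75 and 105 min (15-min pulses with 30, 60 or
    90 min gaps).
    """

    pulse_len: float = DEFAULT_PULSE_LEN
    gap: float = 60.0

    def __post_init__(self):
        if self.pulse_len <= 0 or self.gap < 0:
            raise ValueError("pulse_len must be > 0 and gap >= 0")

    @property
    def delta_t(self) -> float:
        return self.pulse_len + self.gap


@dataclass(frozen=True)
class TrackSimConfig:
    read_intensity: float = 10.0     # Poisson mean reads per pulse
    n_tracks: int = 1000
    ground_truth_speed: float = 1.0  # kb/min
    pulse_len: float = DEFAULT_PULSE_LEN

    def __post_init__(self):
        if self.read_intensity <= 0:
            raise ValueError("read_intensity must be positive")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")


@dataclass(frozen=True)
class PairCorrSimConfig:
    window_lo: float = -200.0   # kb, uniform read support
    window_hi: float = 200.0
    reads_mean: float = 80.0    # Poisson mean candidate reads per fork
    speed_mu: float = 1.0       # kb/min, truncated-normal window scaling
    speed_sigma: float = 0.0
    n_rep: int = 2000
    mode: str = "equal_intensity"

    def __post_init__(self):
        if self.speed_sigma < 0:
            raise ValueError("speed_sigma must be >= 0")
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if self.mode not in ("equal_intensity", "unequal_intensity"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _truncnorm_positive(mu, sigma, size, rng):
    """Draw from N(mu, sigma) truncated to (0, inf)."""
    if sigma == 0:
        return np.full(size, float(mu))
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size,
                               random_state=rng)


def simulate_pulse_tracks(cfg: TrackSimConfig, scheme: str = "double",
                          seed: int | None = None):
    """Simulate reads on isolated pulse-labeled tracks.

    Reads per pulse ~ Poisson(cfg.read_intensity), placed uniformly inside
    the pulse window. Windows in physical coordinates: one unit =
    pulse_len * ground_truth_speed kb, first pulse [0, 1) units, second pulse
    [2, 3) units, so the center-to-center fork travel is 2 units in
    2 * pulse_len minutes — speed = ground_truth_speed by construction.

    Returns (reads, truth): reads has columns track, pulse (0/1), pos_kb;
    truth has one row per track with its true speed and window bounds.
    """
    if scheme not in ("single", "double"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    unit = cfg.pulse_len * cfg.ground_truth_speed  # kb per pulse window
    n_pulses = 1 if scheme == "single" else 2
    rows = []
    for pulse in range(n_pulses):
        lo = (0.0, 2.0)[pulse] * unit
        n = rng.poisson(cfg.read_intensity, size=cfg.n_tracks)
        track_ids = np.repeat(np.arange(cfg.n_tracks), n)
        pos = lo + rng.uniform(0.0, unit, size=n.sum())
        rows.append(pd.DataFrame({"track": track_ids, "pulse": pulse, "pos_kb": pos}))
    reads = pd.concat(rows, ignore_index=True).sort_values(
        ["track", "pos_kb"]).reset_index(drop=True)
    truth = pd.DataFrame({
        "track": np.arange(cfg.n_tracks),
        "speed": cfg.ground_truth_speed,
        "window0_lo": 0.0, "window0_hi": unit,
        "window1_lo": 2 * unit if n_pulses == 2 else np.nan,
        "window1_hi": 3 * unit if n_pulses == 2 else np.nan,
    })
    return reads, truth


def double_pulse_speed(reads: pd.DataFrame, pulse_len: float = DEFAULT_PULSE_LEN):
    """Per-track double-pulse speed: mean pairwise first-to-second pulse distance
    divided by the center-to-center time (2 * pulse_len min). kb/min.

    Tracks missing reads in either pulse yield NaN.
    """
    def one(track):
        a = track.loc[track["pulse"] == 0, "pos_kb"].to_numpy()
        b = track.loc[track["pulse"] == 1, "pos_kb"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            return np.nan
        return np.abs(b[None, :] - a[:, None]).mean() / (2 * pulse_len)

    return reads.groupby("track").apply(one, include_groups=False)


def single_pulse_track_speed(reads: pd.DataFrame,
                             pulse_len: float = DEFAULT_PULSE_LEN):
    """Per-track width-based speed from a single pulse's reads.

    Uses the sampling-corrected width w + w/(n-1) over the pulse length;
    tracks with fewer than two reads yield NaN.
    """
    def one(track):
        pos = track["pos_kb"].to_numpy()
        n = len(pos)
        if n < 2:
            return np.nan
        w = pos.max() - pos.min()
        return (w + w / (n - 1)) / pulse_len

    sub = reads[reads["pulse"] == 0]
    return sub.groupby("track").apply(one, include_groups=False)


def simulate_paircorr_cell(cfg: PairCorrSimConfig, seed: int | None = None):
    """Simulate retained reads of many independent double-pulse forks.

    Returns (reads, truth): reads has columns fork, pos_kb (retained reads
    only); truth has one row per fork with the drawn window scaling s.
    The two retained windows are (-45s, -30s) and (30s, 45s) kb, whose
    centers are 75 s kb apart — the interpulse distance of a fork moving at
    s kb/min probed with a 75-min center-to-center double pulse.
    """
    rng = np.random.default_rng(seed)
    s = _truncnorm_positive(cfg.speed_mu, cfg.speed_sigma, cfg.n_rep, rng)
    n = rng.poisson(cfg.reads_mean, size=cfg.n_rep)
    fork_ids = np.repeat(np.arange(cfg.n_rep), n)
    s_read = np.repeat(s, n)
    if cfg.mode == "equal_intensity":
        r = rng.uniform(cfg.window_lo, cfg.window_hi, size=n.sum())
    else:  # unequal: support scaled with the speed factor
        r = rng.uniform(cfg.window_lo * s_read, cfg.window_hi * s_read)
    keep = ((-45 * s_read < r) & (r < -30 * s_read)) | \
           ((30 * s_read < r) & (r < 45 * s_read))
    reads = pd.DataFrame({"fork": fork_ids[keep], "pos_kb": r[keep]})
    truth = pd.DataFrame({"fork": np.arange(cfg.n_rep), "s": s})
    return reads, truth


def paircorr_retained(r: np.ndarray, s: float) -> np.ndarray:
    """Retention rule for candidate reads r given window scaling s."""
    r = np.asarray(r, dtype=float)
    return ((-45 * s < r) & (r < -30 * s)) | ((30 * s < r) & (r < 45 * s))


TIMING_PERIOD = 4_000_000  # bp, size of one early->late->early timing domain


def _triangle_timing(pos, period: float = TIMING_PERIOD):
    """Replication-timing profile in [0, 1]: a triangular wave over the genome."""
    frac = np.mod(np.asarray(pos, dtype=float) / period, 1.0)
    return np.abs(2 * frac - 1.0)


def simulate_whole_cell(layout: GenomeLayout, n_forks: int,
                        speed_mu: float = 1.0, speed_sigma: float = 0.2,
                        scheme: PulseScheme | str = "double",
                        sampling_rate: float = 0.4,
                        background_rate: float = 0.0,
                        stage: float | None = None,
                        stage_bandwidth: float = 0.1,
                        cell: str = "cell0",
                        seed: int | None = None):
    """Simulate one cell's deduplicated molecule table on a genome.

    ``n_forks`` bidirectional origins are placed on the genome — uniformly,
    or, when ``stage`` in [0, 1] is given, restricted to positions whose
    triangular-wave replication-timing value lies within ``stage_bandwidth``
    of the stage, which gives cohorts of cells a shared S-phase trajectory
    with same-stage domains recurring across the genome. Each origin spawns two divergent forks with
    truncated-normal speeds (kb/min). Fork pulse windows follow ``scheme``
    ('single', 'double', or a PulseScheme); reads per pulse window are
    Poisson(``sampling_rate`` per kb of labeled DNA), placed uniformly inside
    the window, plus uniform background reads at ``background_rate`` per kb of
    genome. Read positions are deduplicated to unique integer coordinates.

    Returns (molecules, truth): a validated molecule-table DataFrame and a
    per-fork truth table (fork, chrom, origin, direction, speed, windows).
    """
    if n_forks < 1:
        raise ValueError("n_forks must be >= 1")
    if not 0 < sampling_rate:
        raise ValueError("sampling_rate must be positive")
    if isinstance(scheme, str):
        if scheme == "single":
            pulses, sch = 1, PulseScheme()
        elif scheme == "double":
            pulses, sch = 2, PulseScheme()
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    else:
        pulses, sch = 2, scheme
    rng = np.random.default_rng(seed)
    chroms = np.array(layout.chroms)
    lengths = np.array([layout.lengths[c] for c in chroms], dtype=float)
    genome = lengths.sum()
    # track extent per fork (bp): travel up to end of last pulse
    total_min = sch.pulse_len if pulses == 1 else sch.delta_t + sch.pulse_len
    max_extent = total_min * (speed_mu + 4 * speed_sigma) * 1000
    if n_forks * max_extent > 2 * genome:
        raise ValueError("n_forks exceeds genome capacity at this track length")

    # origin placement
    probs = lengths / genome
    ori_chrom_idx = rng.choice(len(chroms), size=n_forks, p=probs)
    if stage is None:
        ori_pos = rng.uniform(0, lengths[ori_chrom_idx])
    else:
        # triangular-wave timing profile (period timing_period): same-stage
        # domains recur across the genome like real early/late domains
        ori_pos = np.empty(n_forks)
        for k in range(n_forks):
            clen = lengths[ori_chrom_idx[k]]
            for _ in range(1000):
                x = rng.uniform(0, clen)
                t = _triangle_timing(x, TIMING_PERIOD)
                if abs(t - stage) <= stage_bandwidth:
                    ori_pos[k] = x
                    break
            else:  # pragma: no cover - bandwidth always admits some region
                ori_pos[k] = rng.uniform(0, clen)

    fork_rows, read_chrom, read_pos, read_fork = [], [], [], []
    fork_id = 0
    for k in range(n_forks):
        chrom = chroms[ori_chrom_idx[k]]
        clen = lengths[ori_chrom_idx[k]]
        for direction in (1, -1):
            v = _truncnorm_positive(speed_mu, speed_sigma, 1, rng)[0] * 1000  # bp/min
            windows = [(0.0, sch.pulse_len)]
            if pulses == 2:
                windows.append((sch.delta_t, sch.delta_t + sch.pulse_len))
            w_bounds = []
            for (t0, t1) in windows:
                a = ori_pos[k] + direction * v * t0
                b = ori_pos[k] + direction * v * t1
                lo_w, hi_w = min(a, b), max(a, b)
                lo_w, hi_w = max(0.0, lo_w), min(clen, hi_w)
                if hi_w <= lo_w:
                    w_bounds.append((np.nan, np.nan))
                    continue
                w_bounds.append((lo_w, hi_w))
                lam = sampling_rate * (hi_w - lo_w) / 1000
                m = rng.poisson(lam)
                if m:
                    p = rng.uniform(lo_w, hi_w, size=m)
                    read_chrom.extend([chrom] * m)
                    read_pos.extend(p)
                    read_fork.extend([fork_id] * m)
            fork_rows.append({
                "fork": fork_id, "chrom": chrom, "origin": ori_pos[k],
                "direction": direction, "speed": v / 1000,
                "pulse0_lo": w_bounds[0][0], "pulse0_hi": w_bounds[0][1],
                "pulse1_lo": w_bounds[1][0] if pulses == 2 else np.nan,
                "pulse1_hi": w_bounds[1][1] if pulses == 2 else np.nan,
            })
            fork_id += 1

    if background_rate > 0:
        m = rng.poisson(background_rate * genome / 1000)
        idx = rng.choice(len(chroms), size=m, p=probs)
        read_chrom.extend(chroms[idx])
        read_pos.extend(rng.uniform(0, lengths[idx]))
        read_fork.extend([-1] * m)

    molecules = pd.DataFrame({
        "cell": cell,
        "chrom": read_chrom,
        "pos": np.floor(read_pos).astype(np.int64),
        "strand": rng.choice(["+", "-"], size=len(read_pos)),
        "sample": "sim",
        "labeling": "single" if pulses == 1 else "double",
        "delta_t": np.nan if pulses == 1 else sch.delta_t,
        "fork": read_fork,
    })
    molecules = molecules.drop_duplicates(subset=["cell", "chrom", "pos"])
    molecules = molecules.sort_values(["chrom", "pos"]).reset_index(drop=True)
    truth = pd.DataFrame(fork_rows)
    return molecules, truth


def simulate_cohort(layout: GenomeLayout, n_cells: int, n_forks: int = 80,
                    speed_mu: float = 1.0, speed_sigma: float = 0.2,
                    scheme: PulseScheme | str = "double",
                    sampling_rate: float = 0.4, background_rate: float = 0.0,
                    stage_bandwidth: float = 0.2,
                    seed: int | None = None):
    """Simulate ``n_cells`` cells at equally spaced S-phase stages.

    Cell i is generated at stage i/(n_cells-1) with the linear timing profile
    of :func:`simulate_whole_cell`, so true S-phase order equals cell index.
    Returns (molecules, stages, truths).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_cells)
    stages = np.linspace(0, 1, n_cells)
    frames, truths = [], []
    for i in range(n_cells):
        mol, truth = simulate_whole_cell(
            layout, n_forks, speed_mu, speed_sigma, scheme,
            sampling_rate, background_rate, stage=stages[i],
            stage_bandwidth=stage_bandwidth, cell=f"cell{i:03d}",
            seed=child[i],
        )
        frames.append(mol)
        truth = truth.assign(cell=f"cell{i:03d}", stage=stages[i])
        truths.append(truth)
    molecules = pd.concat(frames, ignore_index=True)
    return molecules, stages, pd.concat(truths, ignore_index=True)
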