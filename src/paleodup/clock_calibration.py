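"""Per-species synonymous-clock calibration and Ks-to-time conversion.

A species' local clock ``C_Ks`` (substitutions per synonymous site per myr)
is calibrated from the kernel-density peaks of its ortholog-Ks
distributions against two outgroups whose divergence node ages are known:

    C_Ks = ( Ks_A / (2 T_A) + Ks_D / (2 T_D) ) / 2

where ``Ks_A`` / ``Ks_D`` are the ortholog-Ks peaks against the nearer
outgroup and the root outgroup, and ``T_A`` / ``T_D`` the ages of the
corresponding speciation nodes.  The factor 2 accounts for the substitution
paths accumulating along both lineages since divergence.  Paralog Ks values
are then converted to absolute ages by ``T = Ks / (2 C_Ks)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ClockCalibration:
    """A calibrated local synonymous clock for one species."""

    species: str
    ks_a: float
    ks_d: float
    t_a: float
    t_d: float
    c_ks: float

    def __post_init__(self):
        if self.c_ks <= 0:
            raise ValueError("calibrated clock must be positive")


@dataclass(frozen=True)
class AgeSample:
    """A paralog pair's age in myr together with its source Ks."""

    pair_id: str
    age: float
    ks: float


def nrd0_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (the classic nrd0 rule).

    0.9 * min(sd, IQR/1.349) * n^(-1/5); falls back to |x|-based scales when
    the data are (nearly) degenerate so the bandwidth stays positive.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        spread = sd if sd > 0 else (abs(float(x[0])) if n else 1.0)
    if spread <= 0:
        spread = 1.0
    return 0.9 * spread * n ** (-0.2)


def kde_peak(
    values,
    bandwidth: float | str = "nrd0",
    grid_size: int = 512,
) -> float:
    """Location of the mode of a Gaussian kernel density estimate.

    The density is evaluated on ``grid_size`` equally spaced points spanning
    [min - 3h, max + 3h] and the argmax is returned at grid resolution.
    A constant sample returns that constant with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 10:
        raise ValueError("kde_peak needs at least 10 values")
    if np.ptp(x) == 0:
        warnings.warn("all values identical; zero-bandwidth KDE peak")
        return float(x[0])
    h = nrd0_bandwidth(x) if bandwidth == "nrd0" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    # sum of kernels, chunked over the grid to bound memory on large samples
    dens = np.empty(grid_size)
    step = max(1, 10_000_000 // max(x.size, 1))
    for i in range(0, grid_size, step):
        g = grid[i : i + step]
        z = (g[:, None] - x[None, :]) / h
        dens[i : i + step] = np.exp(-0.5 * z * z).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def calibrate_clock(
    ks_a: float, ks_d: float, t_a: float, t_d: float, species: str = ""
) -> ClockCalibration:
    """Average the two outgroup-based rate estimates into one local clock."""
    if min(ks_a, ks_d, t_a, t_d) <= 0:
        raise ValueError("calibration inputs must all be positive")
    if t_d <= t_a:
        raise ValueError("root age t_d must exceed t_a")
    c = (ks_a / (2.0 * t_a) + ks_d / (2.0 * t_d)) / 2.0
    return ClockCalibration(species=species, ks_a=ks_a, ks_d=ks_d, t_a=t_a, t_d=t_d, c_ks=c)


def ks_to_time(ks, clock: ClockCalibration):
    """Convert Ks to absolute divergence time, T = Ks / (2 C_Ks)."""
    ks_arr = np.asarray(ks, dtype=float)
    if np.any(ks_arr < 0):
        raise ValueError("Ks must be non-negative")
    out = ks_arr / (2.0 * clock.c_ks)
    return float(out) if np.isscalar(ks) or out.ndim == 0 else out


def max_ks_for_window(clock: ClockCalibration, t_max: float = 200.0) -> float:
    """Largest Ks admitted into a dating window of [0, t_max] myr."""
    if t_max < 0:
        raise ValueError("t_max must be non-negative")
    return 2.0 * clock.c_ks * t_max


def ages_from_rate_table(ks_values, pair_ids, clock: ClockCalibration, t_max: float = 200.0):
    """Convert a batch of paralog Ks values to AgeSamples within the window."""
    out = []
    ceiling = max_ks_for_window(clock, t_max)
    for pid, ks in zip(pair_ids, ks_values):
        if not np.isfinite(ks) or ks < 0 or ks > ceiling:
            continue
        out.append(AgeSample(pair_id=pid, age=ks / (2.0 * clock.c_ks), ks=float(ks)))
    return out
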