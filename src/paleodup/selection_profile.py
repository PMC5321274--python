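"""Ka/Ks-through-time profiles of dated paralog pairs.

After converting paralog Ks to absolute age, the selective regime of the
retained duplicates is summarised by binning their Ka/Ks (omega) values in
half-open 5-myr age bins over [0, 200) myr.  A post-WGD increase of omega
with no delay is the signature of accelerated molecular evolution after
doubling; the shift report quantifies it descriptively (mean omega in the
bins before versus after the event age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OmegaBin", "bin_omega", "omega_shift_report", "bins_to_frame"]


@dataclass(frozen=True)
class OmegaBin:
    """Summary of omega for pairs whose age falls in [start, end) myr."""

    start: float
    end: float
    n_pairs: int
    mean_omega: float  # nan when the bin is empty
    median_omega: float
    fraction_omega_gt_1: float


def bin_omega(
    ages,
    omegas,
    window: tuple[float, float] = (0.0, 200.0),
    width: float = 5.0,
):
    """Bin omega by pair age in half-open bins of ``width`` myr.

    Pairs with non-finite omega (saturated Ks, or Ks = 0) or with ages
    outside [window) are excluded and counted.  Returns (list of OmegaBin,
    n_excluded).  Ages exactly on a boundary go to the bin starting there.
    """
    ages = np.asarray(list(ages), dtype=float)
    omegas = np.asarray(list(omegas), dtype=float)
    if ages.shape != omegas.shape:
        raise ValueError("ages and omegas must have equal length")
    lo, hi = window
    if hi <= lo or width <= 0:
        raise ValueError("window must be non-empty and width positive")

    ok = np.isfinite(ages) & np.isfinite(omegas) & (ages >= lo) & (ages < hi)
    excluded = int((~ok).sum())
    ages, omegas = ages[ok], omegas[ok]

    edges = np.arange(lo, hi + width / 2, width)
    idx = np.floor((ages - lo) / width).astype(int)
    bins = []
    for b in range(len(edges) - 1):
        sel = np.sort(omegas[idx == b])  # fixed order => order-invariant stats
        if sel.size:
            bins.append(
                OmegaBin(
                    start=float(edges[b]),
                    end=float(edges[b + 1]),
                    n_pairs=int(sel.size),
                    mean_omega=float(sel.mean()),
                    median_omega=float(np.median(sel)),
                    fraction_omega_gt_1=float((sel > 1.0).mean()),
                )
            )
        else:
            bins.append(
                OmegaBin(
                    start=float(edges[b]),
                    end=float(edges[b + 1]),
                    n_pairs=0,
                    mean_omega=math.nan,
                    median_omega=math.nan,
                    fraction_omega_gt_1=math.nan,
                )
            )
    return bins, excluded


def omega_shift_report(
    bins,
    wgd_age: float,
    n_flanking: int = 4,
    recent_age: float = 66.0,
) -> dict:
    """Descriptive before/after-WGD omega contrast.

    Averages ``mean_omega`` over the ``n_flanking`` non-empty bins on each
    side of ``wgd_age`` and reports the difference (after - before, where
    "after" means younger than the event), plus the number of omega > 1
    pairs younger than ``recent_age``.  No statistical test is attached.
    """
    if not bins:
        raise ValueError("no bins supplied")
    lo = min(b.start for b in bins)
    hi = max(b.end for b in bins)
    if not lo <= wgd_age <= hi:
        raise ValueError("wgd_age outside the binned window")

    younger = [b for b in bins if b.end <= wgd_age and b.n_pairs > 0]
    older = [b for b in bins if b.start >= wgd_age and b.n_pairs > 0]
    younger = sorted(younger, key=lambda b: wgd_age - b.end)[:n_flanking]
    older = sorted(older, key=lambda b: b.start - wgd_age)[:n_flanking]

    mean_after = float(np.mean([b.mean_omega for b in younger])) if younger else math.nan
    mean_before = float(np.mean([b.mean_omega for b in older])) if older else math.nan
    shift = mean_after - mean_before if younger and older else math.nan

    n_recent_gt1 = sum(
        int(round(b.fraction_omega_gt_1 * b.n_pairs))
        for b in bins
        if b.end <= recent_age and b.n_pairs > 0
    )
    return {
        "wgd_age": wgd_age,
        "mean_omega_after": mean_after,
        "mean_omega_before": mean_before,
        "shift": shift,
        "defined": bool(younger and older),
        "n_omega_gt_1_recent": n_recent_gt1,
    }


def bins_to_frame(bins) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": b.start,
                "end": b.end,
                "n_pairs": b.n_pairs,
                "mean_omega": b.mean_omega,
                "median_omega": b.median_omega,
                "fraction_omega_gt_1": b.fraction_omega_gt_1,
            }
            for b in bins
        ]
    )
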