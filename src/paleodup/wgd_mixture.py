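"""Gaussian mixture modelling of Ks / age distributions.

Bursts of paralog pairs left by whole-genome duplications appear as
approximately normal components sitting on the L-shaped background of
small-scale duplications.  This module fits univariate Gaussian mixtures by
EM with many restarts (random and k-means-seeded), selects the number of
components by BIC, applies the >20% retention rule, and converts component
parameters from Ks to absolute age with a calibrated local clock.

The multi-start schedule runs every start for a fixed number of burn-in EM
iterations, then polishes only the best few to full convergence -- the
short-run/long-run strategy of Biernacki, Celeux & Govaert (2003).  Setting
``short_iters=None`` iterates every start to convergence instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clock_calibration import ClockCalibration

_LOG2PI = float(np.log(2.0 * np.pi))

#: variance floors preventing singular components, per measurement scale
VAR_FLOOR = {"ks": 1e-6, "myr": 1e-2}

#: default age windows (myr) used to tag components in reports
DEFAULT_LABEL_WINDOWS = (
    (0.0, 25.0, "SSD-candidate"),
    (40.0, 120.0, "WGD-candidate"),
)


@dataclass(frozen=True)
class MixtureComponent:
    mean: float
    sd: float
    proportion: float
    scale: str = "ks"
    label: str = "unclassified"


@dataclass(frozen=True)
class MixtureFit:
    k: int
    components: tuple[MixtureComponent, ...]
    log_likelihood: float
    bic: float
    n: int
    seed: int
    n_starts_random: int
    n_starts_kmeans: int
    converged: bool
    scale: str = "ks"
    bic_table: dict[int, float] = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([c.proportion for c in self.components])


def bic_score(log_likelihood: float, k: int, n: int) -> float:
    """BIC = -2 logL + p ln n with p = 3k - 1 free parameters."""
    p = 3 * k - 1
    return -2.0 * log_likelihood + p * np.log(n)


# ---------------------------------------------------------------------------
# start generation


def _random_starts(x, k, n_starts, rng):
    n = x.size
    w = rng.dirichlet(np.ones(k), size=n_starts)
    mu = np.quantile(x, rng.uniform(0.0, 1.0, size=(n_starts, k)))
    sd = np.full((n_starts, k), max(np.std(x), 1e-6))
    return w, mu, sd * sd


def _kmeans_starts(x_sorted, k, n_starts, rng, n_lloyd=10):
    """k-means++ seeding plus a few Lloyd iterations on sorted 1-D data.

    In one dimension the assignment step is an interval partition, so each
    Lloyd iteration costs O(k log n) using prefix sums.
    """
    n = x_sorted.size
    cs1 = np.concatenate([[0.0], np.cumsum(x_sorted)])
    cs2 = np.concatenate([[0.0], np.cumsum(x_sorted * x_sorted)])
    global_var = max(float(np.var(x_sorted)), 1e-12)

    W = np.empty((n_starts, k))
    MU = np.empty((n_starts, k))
    VAR = np.empty((n_starts, k))
    for s in range(n_starts):
        centers = [x_sorted[rng.integers(n)]]
        for _ in range(1, k):
            d2 = np.min(
                (x_sorted[:, None] - np.array(centers)[None, :]) ** 2, axis=1
            )
            tot = d2.sum()
            if tot <= 0:
                centers.append(x_sorted[rng.integers(n)])
                continue
            centers.append(x_sorted[np.searchsorted(np.cumsum(d2), rng.uniform() * tot)])
        c = np.sort(np.array(centers))
        for _ in range(n_lloyd):
            bounds = np.searchsorted(x_sorted, (c[:-1] + c[1:]) / 2.0)
            lo = np.concatenate([[0], bounds])
            hi = np.concatenate([bounds, [n]])
            cnt = (hi - lo).astype(float)
            sums = cs1[hi] - cs1[lo]
            new_c = np.where(cnt > 0, sums / np.maximum(cnt, 1), c)
            if np.allclose(new_c, c):
                c = new_c
                break
            c = np.sort(new_c)
        bounds = np.searchsorted(x_sorted, (c[:-1] + c[1:]) / 2.0)
        lo = np.concatenate([[0], bounds])
        hi = np.concatenate([bounds, [n]])
        cnt = (hi - lo).astype(float)
        sums = cs1[hi] - cs1[lo]
        sq = cs2[hi] - cs2[lo]
        mu = np.where(cnt > 0, sums / np.maximum(cnt, 1), c)
        var = np.where(cnt > 1, sq / np.maximum(cnt, 1) - mu * mu, global_var)
        W[s] = np.maximum(cnt, 0.5) / np.maximum(cnt, 0.5).sum()
        MU[s] = mu
        VAR[s] = np.maximum(var, 1e-12)
    return W, MU, VAR


# ---------------------------------------------------------------------------
# EM core (vectorised across starts)


def _em_run(x, w, mu, var, tol, max_iter, var_floor, check_monotone=True,
            dtype=np.float64):
    """Iterate EM on a batch of starts until convergence or max_iter.

    Returns final (w, mu, var, logL, converged, n_iter) arrays.  The burn-in
    phase may run in float32 (``dtype``), which only affects which starts
    survive to the float64 polishing stage, not the final parameters.
    """
    x = np.asarray(x, dtype=dtype)
    slack = 1e-8 if dtype == np.float64 else 1e-5
    n = x.size
    S, k = w.shape
    w = w.astype(dtype)
    w /= w.sum(axis=1, keepdims=True)  # guard against rounding drift
    mu = mu.astype(dtype)
    var = np.maximum(var.astype(dtype), var_floor)
    logL = np.full(S, -np.inf, dtype=np.float64)
    converged = np.zeros(S, dtype=bool)
    iters = np.zeros(S, dtype=int)
    active = np.ones(S, dtype=bool)

    xb = x[None, :, None]
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        wa, mua, vara = w[idx], mu[idx], var[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            logc = (
                np.log(np.maximum(wa, 1e-300))[:, None, :]
                - 0.5 * (_LOG2PI + np.log(vara))[:, None, :]
                - (xb - mua[:, None, :]) ** 2 / (2.0 * vara[:, None, :])
            )
        m = logc.max(axis=2)
        with np.errstate(over="ignore"):
            resp = np.exp(logc - m[:, :, None])
        norm = resp.sum(axis=2)
        ll_pts = m + np.log(norm)
        new_logL = ll_pts.sum(axis=1)
        resp /= norm[:, :, None]

        if check_monotone:
            prev = logL[idx]
            ok = np.isneginf(prev) | (new_logL >= prev - slack * (np.abs(prev) + 1.0))
            assert ok.all(), "EM log-likelihood decreased"

        done = np.abs(new_logL - logL[idx]) <= tol * np.maximum(1.0, np.abs(new_logL))
        logL[idx] = new_logL
        iters[idx] += 1

        # M-step
        nk = resp.sum(axis=1)
        dead = nk < 1e-9
        nk_safe = np.maximum(nk, 1e-9)
        mu_new = np.einsum("snk,n->sk", resp, x) / nk_safe
        ex2 = np.einsum("snk,n->sk", resp, x * x) / nk_safe
        var_new = np.maximum(ex2 - mu_new * mu_new, var_floor)
        w_new = nk / nk.sum(axis=1, keepdims=True)
        # a dead component keeps its parameters; its weight decays to ~0
        mu_new = np.where(dead, mua, mu_new)
        var_new = np.where(dead, vara, var_new)
        w[idx], mu[idx], var[idx] = w_new, mu_new, var_new

        converged[idx] |= done
        active[idx] &= ~done
    return w, mu, var, logL, converged, iters


def fit_gmm(
    values,
    k: int,
    seed: int,
    n_random_starts: int = 100,
    n_kmeans_starts: int = 100,
    tol: float = 1e-8,
    max_iter: int = 1000,
    scale: str = "ks",
    var_floor: float | None = None,
    short_iters: int | None = 15,
    n_finalists: int = 8,
    start_block: int = 50,
) -> MixtureFit:
    """Best-of-many-starts EM fit of a k-component univariate Gaussian mixture."""
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} observations for k={k}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if var_floor is None:
        var_floor = VAR_FLOOR.get(scale, 1e-6)

    rng = np.random.default_rng(seed)
    w_r, mu_r, var_r = _random_starts(x, k, n_random_starts, rng)
    w_k, mu_k, var_k = _kmeans_starts(x, k, n_kmeans_starts, rng)
    w0 = np.vstack([w_r, w_k])
    mu0 = np.vstack([mu_r, mu_k])
    var0 = np.vstack([var_r, var_k])
    S = w0.shape[0]
    if S == 0:
        raise ValueError("at least one start is required")

    burn = max_iter if short_iters is None else min(short_iters, max_iter)
    # burn-in in float32: cheap triage of starts before float64 polishing
    burn_dtype = np.float64 if short_iters is None else np.float32
    W = np.empty_like(w0)
    MU = np.empty_like(mu0)
    VAR = np.empty_like(var0)
    LOGL = np.empty(S)
    CONV = np.empty(S, dtype=bool)
    for lo in range(0, S, start_block):
        hi = min(lo + start_block, S)
        w, mu, var, logL, conv, _ = _em_run(
            x, w0[lo:hi], mu0[lo:hi], var0[lo:hi], tol, burn, var_floor,
            dtype=burn_dtype,
        )
        W[lo:hi], MU[lo:hi], VAR[lo:hi] = w, mu, var
        LOGL[lo:hi], CONV[lo:hi] = logL, conv

    if short_iters is not None and burn < max_iter:
        # polish every finalist in float64: float32 convergence is only
        # approximate and the best start must satisfy the full tolerance
        todo = np.argsort(LOGL)[::-1][: max(1, n_finalists)]
        if todo.size:
            w, mu, var, logL, conv, _ = _em_run(
                x, W[todo], MU[todo], VAR[todo], tol, max_iter - burn, var_floor
            )
            W[todo], MU[todo], VAR[todo] = w, mu, var
            LOGL[todo], CONV[todo] = logL, conv
            # stale float32 burn scores must not outrank polished fits
            mask = np.full(S, -np.inf)
            mask[todo] = 0.0
            LOGL = LOGL + mask

    good = np.isfinite(LOGL)
    if not good.any():
        raise RuntimeError("all EM starts degenerate; no finite log-likelihood")
    best = int(np.argmax(np.where(good, LOGL, -np.inf)))
    order = np.argsort(MU[best])
    comps = tuple(
        MixtureComponent(
            mean=float(MU[best][j]),
            sd=float(np.sqrt(VAR[best][j])),
            proportion=float(W[best][j]),
            scale=scale,
        )
        for j in order
    )
    logl = float(LOGL[best])
    return MixtureFit(
        k=k,
        components=comps,
        log_likelihood=logl,
        bic=float(bic_score(logl, k, n)),
        n=n,
        seed=seed,
        n_starts_random=n_random_starts,
        n_starts_kmeans=n_kmeans_starts,
        converged=bool(CONV[best]),
        scale=scale,
    )


def select_model(values, k_range=(2, 5), seed: int = 0, **fit_kwargs) -> MixtureFit:
    """Fit k over a range and return the minimum-BIC model with its BIC table."""
    kmin, kmax = int(k_range[0]), int(k_range[-1])
    fits: dict[int, MixtureFit] = {}
    errors: dict[int, Exception] = {}
    for k in range(kmin, kmax + 1):
        try:
            fits[k] = fit_gmm(values, k, seed=seed, **fit_kwargs)
        except (ValueError, RuntimeError) as exc:  # propagate only if nothing fits
            errors[k] = exc
    if not fits:
        raise RuntimeError(f"no mixture model could be fitted: {errors}")
    table = {k: f.bic for k, f in fits.items()}
    best = fits[min(table, key=table.get)]
    return replace(best, bic_table=table)


def retain_components(fit: MixtureFit, min_proportion: float = 0.20):
    """Keep components holding strictly more than ``min_proportion`` of pairs."""
    kept = [c for c in fit.components if c.proportion > min_proportion]
    if not kept:
        import warnings

        warnings.warn("no mixture component exceeds the retention threshold")
    return kept


def date_components(
    components,
    clock: ClockCalibration,
    label_windows=DEFAULT_LABEL_WINDOWS,
):
    """Convert Ks-scale components to myr using T = Ks / (2 C_Ks).

    Both the mean and the spread divide by 2 C_Ks.  Components are tagged by
    which age window their mean falls into; pass ``label_windows=None`` to
    leave everything unclassified.
    """
    denom = 2.0 * clock.c_ks
    out = []
    for c in components:
        if c.scale != "ks":
            raise ValueError("date_components expects Ks-scale components")
        age = c.mean / denom
        label = "unclassified"
        if label_windows:
            for lo, hi, name in label_windows:
                if lo <= age <= hi:
                    label = name
                    break
        out.append(
            MixtureComponent(
                mean=age, sd=c.sd / denom, proportion=c.proportion, scale="myr", label=label
            )
        )
    return out


def label_by_age(components, label_windows=DEFAULT_LABEL_WINDOWS):
    """Tag myr-scale components with SSD/WGD-candidate age-window labels."""
    out = []
    for c in components:
        label = "unclassified"
        if label_windows:
            for lo, hi, name in label_windows:
                if lo <= c.mean <= hi:
                    label = name
                    break
        out.append(replace(c, label=label))
    return out


def pooled_analysis(age_samples_by_species: dict, k_range=(2, 5), seed: int = 0, **fit_kwargs) -> MixtureFit:
    """Mixture fit on ages pooled across species, directly on the myr scale.

    ``age_samples_by_species`` maps species code -> iterable of ages (myr) or
    of AgeSample objects.
    """
    if len(age_samples_by_species) < 1:
        raise ValueError("need at least one species with age samples")
    pooled: list[float] = []
    for _sp, samples in sorted(age_samples_by_species.items()):
        for s in samples:
            pooled.append(float(getattr(s, "age", s)))
    fit = select_model(pooled, k_range=k_range, seed=seed, scale="myr", **fit_kwargs)
    return replace(fit, components=tuple(label_by_age(fit.components)))
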