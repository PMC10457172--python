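"""Gamma-DFE estimation from paired folded SFSs under a two-epoch nuisance
demography.

The procedure mirrors the classic two-step folded-spectrum DFE analysis:

1. ``fit_neutral``: the 4-fold (putatively neutral) folded SFS fixes the
   demographic nuisance parameters -- post-change size N2 (relative to the
   ancestral reference size), epoch duration t2 -- and the per-site neutral
   mutation influx, by maximizing a Poisson/multinomial likelihood over the
   Wright-Fisher expected spectrum.
2. ``fit_selected``: with demography held fixed, the 0-fold folded SFS is fit
   by integrating the expected spectrum over a gamma distribution of
   deleterious effects (shape beta, mean effect Es) discretized on a
   log-spaced grid of scaled effects Nes in [1e-4, 1e4]; mass beyond the
   grid's top edge acts as an effectively lethal point class contributing no
   segregating sites. The selected-class mutation influx is tied to the
   neutral per-site estimate, so the diversity reduction at 0-fold sites is
   part of the selection signal; a per-class free scale is available as an
   option.

Optimization is derivative-free simplex from the conventional initial values
(t2 = 50 generations, s = -0.1, beta = 0.5) with jittered restarts from a
fixed seed, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .config import N_REF
from .sfs import FoldedSFS
from .wright_fisher import expected_folded_sfs

NES_CLASS_EDGES = (1.0, 10.0, 100.0)
NES_CLASS_LABELS = ("0-1", "1-10", "10-100", ">100")


@dataclass
class FitOptions:
    """Search-space and optimizer settings shared by both fits."""

    n2_grid: tuple[float, ...] = (0.5, 1.0, 2.0)
    t2_grid: tuple[float, ...] = (0.0, 25.0, 50.0, 100.0)
    n2_bounds: tuple[float, float] = (0.2, 4.0)
    t2_max: float = 250.0
    # demography is snapped to this lattice: keeps the expected-SFS cache
    # hot across optimizer steps and across replicate fits
    n2_step: float = 0.05
    t2_step: float = 5.0
    init_t2: float = 50.0
    init_s: float = -0.1
    init_beta: float = 0.5
    # adopt the two-epoch demography only when it beats the ancestral
    # equilibrium by this likelihood-ratio margin (chi2, 2 df, 5% level);
    # the neutral folded shape is size-invariant, so without this gate the
    # weakly identified (N2, t2) ridge absorbs sampling noise and distorts
    # the selected-class expectations
    lrt_threshold: float = 5.99
    restarts: int = 5
    jitter_seed: int = 2718
    jitter_sd: float = 0.4
    nes_grid_size: int = 64
    nes_grid_lo: float = 1e-4
    nes_grid_hi: float = 1e4
    maxiter: int = 120
    maxiter_neutral: int = 80
    xatol: float = 1e-3
    fatol: float = 1e-5

    def snap(self, n2: float, t2: float) -> tuple[float, float]:
        n2 = float(np.clip(round(n2 / self.n2_step) * self.n2_step, *self.n2_bounds))
        t2 = float(np.clip(round(t2 / self.t2_step) * self.t2_step, 0.0, self.t2_max))
        return round(n2, 6), round(t2, 3)


@dataclass
class DemographyFit:
    n2_ratio: float
    t2: float
    mu_site: float               # per-site mutation influx per generation
    loglik: float
    n: int
    total_sites: int
    converged: bool = True
    message: str = ""


@dataclass
class GammaDFE:
    beta: float
    es: float                    # mean deleterious effect, per-copy magnitude
    mu_site: float
    loglik: float
    demography: DemographyFit
    converged: bool = True
    message: str = ""

    @property
    def mean_nes(self) -> float:
        """Mean scaled effect using the most recent epoch's size."""
        return N_REF * self.demography.n2_ratio * self.es

    def class_proportions(self) -> dict[str, float]:
        return nes_class_proportions(self, N_REF * self.demography.n2_ratio)


def nes_grid(size: int = 64, lo: float = 1e-4, hi: float = 1e4) -> np.ndarray:
    return np.exp(np.linspace(np.log(lo), np.log(hi), size))


def gamma_weights(beta: float, mean: float, grid: np.ndarray) -> np.ndarray:
    """Gamma(shape=beta, mean) probability mass per log-spaced grid class.

    Class boundaries are geometric midpoints; mass below the lowest edge is
    assigned to the first (effectively neutral) class and mass above the
    highest edge to the last (effectively lethal) class.
    """
    edges = np.concatenate([[0.0], np.sqrt(grid[:-1] * grid[1:]), [np.inf]])
    cdf = gamma_dist.cdf(edges, a=beta, scale=mean / beta)
    return np.diff(cdf)


def nes_class_proportions(dfe: GammaDFE | tuple, ne_scale: float) -> dict[str, float]:
    """Gamma mass in the scaled-selection classes {0-1, 1-10, 10-100, >100}.

    ``ne_scale`` converts the fitted per-copy mean effect to Nes (the
    default uses the most recent epoch's size, N_REF * n2_ratio).
    """
    if isinstance(dfe, GammaDFE):
        beta, es = dfe.beta, dfe.es
    else:
        beta, es = dfe
    mean_nes = ne_scale * es
    if mean_nes <= 0:
        return dict(zip(NES_CLASS_LABELS, (1.0, 0.0, 0.0, 0.0)))
    cdf = gamma_dist.cdf(NES_CLASS_EDGES, a=beta, scale=mean_nes / beta)
    props = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    return dict(zip(NES_CLASS_LABELS, props.tolist()))


def _loglik(seg_obs: np.ndarray, n0_obs: int, e_seg: np.ndarray, u: float, T: int) -> float:
    """Multinomial log-likelihood over folded bins: each of T sites
    segregates at class i with probability u*e_i, else stays invariant."""
    q = u * e_seg
    q0 = 1.0 - q.sum()
    if q0 <= 0 or np.any(q[seg_obs > 0] <= 0):
        return -np.inf
    ll = float(n0_obs * np.log(q0))
    nz = seg_obs > 0
    ll += float((seg_obs[nz] * np.log(q[nz])).sum())
    return ll


def _profile_u(seg_obs: np.ndarray, T: int, e_seg: np.ndarray) -> float:
    """Closed-form MLE of the influx scale: u* = S / (T * sum(e))."""
    S = seg_obs.sum()
    E = e_seg.sum()
    if E <= 0 or T == 0:
        return 0.0
    return float(S / (T * E))


def fit_neutral(fsfs4: FoldedSFS, options: FitOptions | None = None) -> DemographyFit:
    """Two-epoch demography + mutation scale from the neutral folded SFS.

    Coarse grid over (N2 ratio, t2) followed by Nelder-Mead refinement; the
    influx scale is profiled out in closed form at every evaluation. With
    no segregating sites the demography is unidentifiable and the ancestral
    equilibrium is returned flagged as non-converged.
    """
    opt = options or FitOptions()
    n = fsfs4.n
    T = fsfs4.total_sites
    seg = fsfs4.bins[1:].astype(float)
    if seg.sum() == 0:
        return DemographyFit(1.0, 0.0, 0.0, 0.0, n, T, converged=False,
                             message="no segregating sites: demography unidentifiable")

    def nll(params: np.ndarray) -> float:
        log_n2, t2 = params
        n2 = float(np.exp(log_n2))
        if not (opt.n2_bounds[0] <= n2 <= opt.n2_bounds[1]) or not (0.0 <= t2 <= opt.t2_max):
            return 1e12
        n2, t2 = opt.snap(n2, t2)
        e = expected_folded_sfs(n, 0.0, n2, t2)[1:]
        u = _profile_u(seg, T, e)
        if u <= 0:
            return 1e12
        ll = _loglik(seg, T - int(seg.sum()), e, u, T)
        return -ll if np.isfinite(ll) else 1e12

    best_p, best_f = None, np.inf
    for n2 in opt.n2_grid:
        for t2 in opt.t2_grid:
            f = nll(np.array([np.log(n2), t2]))
            if f < best_f:
                best_p, best_f = np.array([np.log(n2), t2]), f
    start = best_p if best_p is not None else np.array([0.0, opt.init_t2])
    res = minimize(
        nll, start, method="Nelder-Mead",
        options=dict(maxiter=opt.maxiter_neutral, xatol=opt.xatol, fatol=opt.fatol,
                     initial_simplex=_simplex(start, steps=(0.3, 20.0))),
    )
    p = res.x if res.fun <= best_f else start
    fun = min(res.fun, best_f)
    n2, t2 = opt.snap(float(np.exp(p[0])), max(float(p[1]), 0.0))
    # likelihood-ratio gate against the ancestral equilibrium null
    fun_eq = nll(np.array([0.0, 0.0]))
    if 2.0 * (fun_eq - fun) < opt.lrt_threshold:
        n2, t2, fun = 1.0, 0.0, fun_eq
    e = expected_folded_sfs(n, 0.0, n2, t2)[1:]
    u = _profile_u(seg, T, e)
    boundary = (
        n2 <= opt.n2_bounds[0] * 1.01 or n2 >= opt.n2_bounds[1] * 0.99
        or t2 >= opt.t2_max * 0.99
    )
    return DemographyFit(
        n2_ratio=n2, t2=t2, mu_site=u, loglik=-fun, n=n, total_sites=T,
        converged=not boundary,
        message="boundary fit" if boundary else "",
    )


def _simplex(start: np.ndarray, steps) -> np.ndarray:
    pts = [np.array(start, dtype=float)]
    for i, st in enumerate(steps):
        p = np.array(start, dtype=float)
        p[i] += st
        pts.append(p)
    return np.array(pts)


def _selected_expectations(
    demography: DemographyFit, n: int, grid: np.ndarray
) -> np.ndarray:
    """Expected folded seg spectra, one row per Nes grid class, at the
    fixed demography (per unit influx)."""
    rows = []
    for nes in grid:
        rows.append(
            expected_folded_sfs(
                n, -nes / N_REF, demography.n2_ratio, demography.t2
            )[1:]
        )
    return np.array(rows)


def fit_selected(
    fsfs0: FoldedSFS,
    demography: DemographyFit,
    options: FitOptions | None = None,
    mutation_scale: str = "tied",
) -> GammaDFE:
    """Gamma DFE (beta, Es) of the selected class, demography held fixed.

    ``mutation_scale="tied"`` (default) fixes the 0-fold per-site influx to
    the neutral estimate, so the overall deficit of segregating 0-fold
    sites informs the fit; ``"free"`` profiles a per-class scale and uses
    spectrum shape only.
    """
    opt = options or FitOptions()
    n = fsfs0.n
    T = fsfs0.total_sites
    seg = fsfs0.bins[1:].astype(float)
    grid = nes_grid(opt.nes_grid_size, opt.nes_grid_lo, opt.nes_grid_hi)
    E = _selected_expectations(demography, n, grid)
    tied = mutation_scale == "tied"
    if tied and demography.mu_site <= 0:
        raise ValueError("tied mutation scale requires a positive neutral mu_site")

    def nll(params: np.ndarray) -> float:
        beta, es = np.exp(params)
        if not (1e-3 <= beta <= 50.0) or not (1e-8 <= es <= 100.0):
            return 1e12
        w = gamma_weights(beta, N_REF * es, grid)
        e = w @ E
        u = demography.mu_site if tied else _profile_u(seg, T, e)
        if u <= 0:
            return 1e12
        ll = _loglik(seg, T - int(seg.sum()), e, u, T)
        return -ll if np.isfinite(ll) else 1e12

    start = np.log([opt.init_beta, abs(opt.init_s)])
    jit = np.random.default_rng(opt.jitter_seed)
    best = None
    for r in range(opt.restarts):
        p0 = start if r == 0 else start + jit.normal(0.0, opt.jitter_sd, size=2)
        res = minimize(
            nll, p0, method="Nelder-Mead",
            options=dict(maxiter=opt.maxiter, xatol=opt.xatol, fatol=opt.fatol),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("selected-class fit failed from all starts")
    beta, es = np.exp(best.x)
    w = gamma_weights(beta, N_REF * es, grid)
    e = w @ E
    u = demography.mu_site if tied else _profile_u(seg, T, e)
    return GammaDFE(
        beta=float(beta), es=float(es), mu_site=float(u),
        loglik=-float(best.fun), demography=demography,
        converged=bool(best.success or best.fun < 1e11),
        message="" if best.success else str(best.message),
    )


def run_replicates(
    pairs: list[tuple[FoldedSFS, FoldedSFS]],
    options: FitOptions | None = None,
    mutation_scale: str = "tied",
    gene_set: str | None = None,
) -> pd.DataFrame:
    """One (demography, gamma DFE) fit per replicate fSFS pair.

    ``pairs`` holds (0-fold, 4-fold) spectra per replicate, e.g. the 200
    downsampling replicates. Failed replicates are recorded with
    ``converged=False`` and excluded from summaries downstream.
    """
    rows = []
    for rep, (f0, f4) in enumerate(pairs):
        rec = {"gene_set": gene_set, "replicate": rep}
        try:
            dem = fit_neutral(f4, options)
            dfe = fit_selected(f0, dem, options, mutation_scale)
            props = dfe.class_proportions()
            rec.update(
                beta=dfe.beta, es=dfe.es, mean_nes=dfe.mean_nes,
                n2_ratio=dem.n2_ratio, t2=dem.t2, mu_site=dem.mu_site,
                loglik_neutral=dem.loglik, loglik_selected=dfe.loglik,
                converged=bool(dem.converged and dfe.converged),
                **{f"p_{k}": v for k, v in props.items()},
            )
        except (RuntimeError, ValueError) as exc:
            rec.update(converged=False, error=str(exc))
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_replicates(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE of the Nes class proportions and beta over converged
    replicates, per gene set."""
    ok = fits[fits.get("converged", False) == True]  # noqa: E712
    rows = []
    for gene_set, g in ok.groupby("gene_set", dropna=False):
        rec = {"gene_set": gene_set, "n_converged": len(g),
               "n_failed": int((fits["gene_set"] == gene_set).sum() - len(g))}
        for col in ["beta", "es"] + [f"p_{k}" for k in NES_CLASS_LABELS]:
            vals = g[col].to_numpy(dtype=float)
            rec[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{col}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)
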