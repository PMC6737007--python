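"""Three-state fast-exchange binding model for a toxin partitioning between
solution, micellar sites and receptor (VSD) sites.

Model
-----
The ligand L (toxin) exchanges fast on the NMR timescale between three
states: free in solution, bound to a micellar site M, and bound to the
receptor R embedded in a micelle.  Micellar sites follow a Langmuir
bookkeeping: every ``n_site`` detergent molecules form one equivalent toxin
site, so ``[M]_0 = [detergent]_0 / n_site``.  The two equilibria are

    K_M [LM] = [L]_free [M]_free                       (micellar site)
    K_V [LR] = s [L]_free [R]_free                     (receptor site)

with ``s`` the statistical factor (2 by default: a receptor carries two
equivalent sites, only single occupancy is modeled).  Detergent consumed by
receptor-containing micelles is not subtracted from the site pool —
detergent is in vast excess in the experiments this model describes.

Observables in fast exchange are population-weighted averages: in
receptor-detected titrations ``dd_obs = ([LR]/[R]_0) * dd_max``; in
ligand-detected ones ``d_obs = sum_state p_state * d_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BindingSystem",
    "TitrationPoint",
    "SpeciesSolution",
    "solve_species",
    "predict_observable",
    "fit_KV",
    "fit_KM",
    "delta_G",
    "molar_ratio",
    "TITRATION_COLUMNS",
]

#: Gas constant in kcal / (mol K).
GAS_CONSTANT_KCAL = 1.987204e-3

TITRATION_COLUMNS = ["VSD0_M", "Hm3_0_M", "Detergent0_M", "reporter", "dd_obs_ppm"]


@dataclass(frozen=True)
class BindingSystem:
    """Equilibrium constants and site bookkeeping.

    Parameters are molar dissociation constants; ``n_site`` is the number of
    detergent molecules forming one micellar toxin site and ``n_mic`` the
    detergent count per receptor-containing micelle (bookkeeping only, it
    does not enter the equations).  ``T`` is the temperature in kelvin
    (default 318.15 K = 45 C).
    """

    K_M: float = 90e-6
    K_V: float = 11e-6
    n_site: float = 35.0
    n_mic: float = 70.0
    statistical_factor: float = 2.0
    T: float = 318.15

    def __post_init__(self):
        for name in ("K_M", "K_V", "n_site", "n_mic", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.statistical_factor < 1:
            raise ValueError("statistical_factor must be >= 1")

    def with_(self, **kwargs) -> "BindingSystem":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TitrationPoint:
    """Total concentrations (mol/L) at one titration point."""

    vsd0: float
    hm3_0: float
    detergent0: float

    def __post_init__(self):
        if min(self.vsd0, self.hm3_0, self.detergent0) < 0:
            raise ValueError("total concentrations must be non-negative")


@dataclass(frozen=True)
class SpeciesSolution:
    """Equilibrium species concentrations (mol/L)."""

    hm3_free: float
    hm3_mic: float
    hm3_vsd: float
    micsite_free: float
    vsd_free: float

    def as_dict(self) -> dict:
        return {
            "hm3_free": self.hm3_free,
            "hm3_mic": self.hm3_mic,
            "hm3_vsd": self.hm3_vsd,
            "micsite_free": self.micsite_free,
            "vsd_free": self.vsd_free,
        }


class ConvergenceError(RuntimeError):
    def __init__(self, msg, bracket=None):
        super().__init__(msg)
        self.bracket = bracket


def _complexes(x: float, point: TitrationPoint, system: BindingSystem):
    """Bound species as functions of the free-ligand concentration x."""
    m0 = point.detergent0 / system.n_site
    lm = m0 * x / (system.K_M + x)
    s = system.statistical_factor
    lr = s * x * point.vsd0 / (system.K_V + s * x)
    return lm, lr


def solve_species(point: TitrationPoint, system: BindingSystem) -> SpeciesSolution:
    """Solve the coupled equilibria at one titration point.

    The ligand mass balance reduces to a single scalar equation in the free
    ligand concentration x in [0, L0]; its residual is strictly increasing,
    so a safeguarded bracketing root-finder (Brent) yields the unique root.
    Both equilibrium relations hold exactly at the returned concentrations
    and all mass balances close to ~1e-10 relative.
    """
    L0 = point.hm3_0
    m0 = point.detergent0 / system.n_site
    if L0 == 0.0:
        return SpeciesSolution(0.0, 0.0, 0.0, m0, point.vsd0)

    def residual(x):
        lm, lr = _complexes(x, point, system)
        return x + lm + lr - L0

    try:
        x = optimize.brentq(residual, 0.0, L0, xtol=1e-16 * max(L0, 1e-12),
                            rtol=8.9e-16, maxiter=200)
    except RuntimeError as err:  # pragma: no cover - brentq rarely fails here
        raise ConvergenceError(str(err), bracket=(0.0, L0)) from err
    lm, lr = _complexes(x, point, system)
    return SpeciesSolution(
        hm3_free=x,
        hm3_mic=lm,
        hm3_vsd=lr,
        micsite_free=m0 - lm,
        vsd_free=point.vsd0 - lr,
    )


def predict_observable(
    solution: SpeciesSolution,
    mode: str,
    shifts,
    vsd0: float | None = None,
) -> float:
    """Fast-exchange observable from an equilibrium solution.

    * ``mode="ligand-detected"``: ``shifts`` is a (free, micelle, receptor)
      triple of state shifts (ppm); returns the population-weighted average
      over the three ligand states.
    * ``mode="receptor-detected"``: ``shifts`` is the limiting shift change
      dd_max (ppm); returns ``(bound/[R]_0) * dd_max``; requires ``vsd0 > 0``.
    """
    if mode == "ligand-detected":
        conc = np.array([solution.hm3_free, solution.hm3_mic, solution.hm3_vsd])
        total = conc.sum()
        if total == 0:
            return 0.0
        return float(np.dot(conc / total, np.asarray(shifts, dtype=float)))
    if mode == "receptor-detected":
        if vsd0 is None or vsd0 <= 0:
            raise ValueError("receptor-detected mode requires vsd0 > 0")
        return float(solution.hm3_vsd / vsd0 * shifts)
    raise ValueError(f"unknown mode {mode!r}")


def _bound_fractions_kv(log10_kv: float, pts: list, system: BindingSystem) -> np.ndarray:
    sys_k = system.with_(K_V=10.0**log10_kv)
    return np.array(
        [solve_species(p, sys_k).hm3_vsd / p.vsd0 for p in pts]
    )


@dataclass
class FitResult:
    """Least-squares estimate for one dissociation constant."""

    K: float
    dd_max: dict
    sse: float
    residuals: pd.DataFrame
    ci95: tuple | None = None
    bootstrap_K: np.ndarray | None = None
    flags: list = field(default_factory=list)


def _check_series(series: pd.DataFrame) -> None:
    missing = [c for c in TITRATION_COLUMNS if c not in series.columns]
    if missing:
        raise ValueError(f"titration table lacks columns {missing}")


def _profiled_sse(fb_by_rep: dict, data_by_rep: dict):
    """Given bound fractions per reporter, solve dd_max linearly and return
    (sse, dd_max dict, residuals)."""
    sse = 0.0
    ddmax = {}
    resids = {}
    for rep, fb in fb_by_rep.items():
        y = data_by_rep[rep]
        denom = float(np.dot(fb, fb))
        a = float(np.dot(fb, y) / denom) if denom > 0 else 0.0
        r = y - a * fb
        ddmax[rep] = a
        resids[rep] = r
        sse += float(np.dot(r, r))
    return sse, ddmax, resids


def fit_KV(
    series: pd.DataFrame,
    system: BindingSystem,
    reporters=None,
    n_boot: int = 0,
    seed: int = 0,
    log10_bounds: tuple = (-9.0, -2.0),
    n_starts: int = 15,
) -> FitResult:
    """Fit the receptor-site dissociation constant K_V (K_M held fixed).

    One K_V is shared across the given reporters; each reporter gets its own
    limiting shift dd_max, which is profiled out linearly, reducing the
    nonlinear search to one dimension.  A deterministic multi-start over a
    log-spaced K_V grid guards against local minima; uncertainty comes from
    a seeded residual bootstrap (``n_boot`` refits, 95% percentile interval).

    A flat response (non-identifiable series) is flagged rather than raised.
    """
    _check_series(series)
    series = series[series.VSD0_M > 0]
    if reporters is not None:
        series = series[series.reporter.isin(reporters)]
    if len(series) < 3:
        raise ValueError("need at least 3 titration points")
    data_by_rep = {}
    pts_by_rep = {}
    for rep, grp in series.groupby("reporter"):
        pts_by_rep[rep] = [
            TitrationPoint(r.VSD0_M, r.Hm3_0_M, r.Detergent0_M)
            for r in grp.itertuples()
        ]
        data_by_rep[rep] = grp.dd_obs_ppm.to_numpy(dtype=float)

    flags = []
    max_dd = max(np.ptp(y) for y in data_by_rep.values())
    if max_dd <= 0:
        flags.append("flat response: K_V not identifiable")

    def sse_of(log10_kv: float) -> float:
        fb = {
            rep: _bound_fractions_kv(log10_kv, pts, system)
            for rep, pts in pts_by_rep.items()
        }
        return _profiled_sse(fb, data_by_rep)[0]

    grid = np.linspace(*log10_bounds, n_starts)
    sse_grid = [sse_of(g) for g in grid]
    i0 = int(np.argmin(sse_grid))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    log10_kv = float(res.x)
    fb = {
        rep: _bound_fractions_kv(log10_kv, pts, system)
        for rep, pts in pts_by_rep.items()
    }
    sse, ddmax, resids = _profiled_sse(fb, data_by_rep)

    ci = None
    boot = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = {rep: ddmax[rep] * fb[rep] for rep in fb}
        boot_vals = []
        for _ in range(n_boot):
            data_b = {
                rep: fitted[rep] + rng.choice(resids[rep], size=len(resids[rep]))
                for rep in fb
            }

            def sse_b(lk, data_b=data_b):
                fb_b = {
                    rep: _bound_fractions_kv(lk, pts, system)
                    for rep, pts in pts_by_rep.items()
                }
                return _profiled_sse(fb_b, data_b)[0]

            sse_bg = [sse_b(g) for g in grid]
            j0 = int(np.argmin(sse_bg))
            res_b = optimize.minimize_scalar(
                sse_b,
                bounds=(grid[max(j0 - 1, 0)], grid[min(j0 + 1, len(grid) - 1)]),
                method="bounded",
                options={"xatol": 1e-8},
            )
            boot_vals.append(10.0 ** float(res_b.x))
        boot = np.array(boot_vals)
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))

    resid_df = pd.DataFrame(
        [
            {"reporter": rep, "point": i, "residual": r}
            for rep, rs in resids.items()
            for i, r in enumerate(rs)
        ]
    )
    return FitResult(K=10.0**log10_kv, dd_max=ddmax, sse=sse,
                     residuals=resid_df, ci95=ci, bootstrap_K=boot, flags=flags)


def fit_KM(
    series: pd.DataFrame,
    system: BindingSystem | None = None,
    n_boot: int = 0,
    seed: int = 0,
    log10_bounds: tuple = (-8.0, -1.0),
    n_starts: int = 15,
) -> FitResult:
    """Fit the micellar-site constant K_M from a micelle-only titration.

    All points must have ``VSD0_M == 0``; the observable is ligand-detected,
    ``dd_obs = p_mic * dd_max`` with ``p_mic`` the micelle-bound ligand
    fraction and site count ``detergent_0 / n_site``.  Same profiled
    one-dimensional search as :func:`fit_KV`.
    """
    _check_series(series)
    if (series.VSD0_M != 0).any():
        raise ValueError("micelle-only series must have VSD0_M = 0 throughout")
    if len(series) < 3:
        raise ValueError("need at least 3 titration points")
    if system is None:
        system = BindingSystem()
    pts_by_rep = {}
    data_by_rep = {}
    for rep, grp in series.groupby("reporter"):
        pts_by_rep[rep] = [
            TitrationPoint(0.0, r.Hm3_0_M, r.Detergent0_M) for r in grp.itertuples()
        ]
        data_by_rep[rep] = grp.dd_obs_ppm.to_numpy(dtype=float)

    flags = []
    if max(np.ptp(y) for y in data_by_rep.values()) <= 0:
        flags.append("flat response: K_M not identifiable")

    def fractions(log10_km: float) -> dict:
        sys_k = system.with_(K_M=10.0**log10_km)
        return {
            rep: np.array(
                [
                    solve_species(p, sys_k).hm3_mic / p.hm3_0 if p.hm3_0 > 0 else 0.0
                    for p in pts
                ]
            )
            for rep, pts in pts_by_rep.items()
        }

    def sse_of(log10_km: float) -> float:
        return _profiled_sse(fractions(log10_km), data_by_rep)[0]

    grid = np.linspace(*log10_bounds, n_starts)
    sse_grid = [sse_of(g) for g in grid]
    i0 = int(np.argmin(sse_grid))
    res = optimize.minimize_scalar(
        sse_of,
        bounds=(grid[max(i0 - 1, 0)], grid[min(i0 + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log10_km = float(res.x)
    sse, ddmax, resids = _profiled_sse(fractions(log10_km), data_by_rep)
    resid_df = pd.DataFrame(
        [
            {"reporter": rep, "point": i, "residual": r}
            for rep, rs in resids.items()
            for i, r in enumerate(rs)
        ]
    )
    return FitResult(K=10.0**log10_km, dd_max=ddmax, sse=sse,
                     residuals=resid_df, flags=flags)


def delta_G(k_d: float, T: float = 318.15) -> float:
    """Standard free energy of complex formation, ``RT ln(K_d / c0)``.

    ``c0`` is the 1 mol/L standard state; the result is in kcal/mol and is
    negative for sub-molar dissociation constants.
    """
    if k_d <= 0 or T <= 0:
        raise ValueError("K_d and T must be positive")
    return GAS_CONSTANT_KCAL * T * float(np.log(k_d))


def molar_ratio(detergent_totals, ligand_total: float) -> float:
    """Total-detergent to ligand molar ratio (e.g. 57+57 mM vs 20 uM -> 5700)."""
    if ligand_total <= 0:
        raise ValueError("ligand total must be positive")
    return float(np.sum(np.asarray(detergent_totals, dtype=float)) / ligand_total)
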