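"""Dead-time-aware maximum-likelihood estimation of C-O-B rate constants.

The likelihood treats the dwell durations observed at each conductance level
(open-channel count) as independent draws from that level's apparent-dwell
density — a histogram-style fit, not a sequence-conditional aggregated-Markov
likelihood.  Every transition of the N-channel aggregated chain changes the
open count, so the exact sub-generator of a level class is diagonal and each
level density is a mixture of exponentials weighted by the stationary entry
distribution into the class.

A fixed dead time t_d is handled two ways, consistently with how sub-t_d
events are removed from idealized records:

* truncation-renormalization of each density over [t_d, inf), and
* a first-order bridged-excursion correction to the within-class generator:
  a sortie to an adjacent level that lasts < t_d and returns is invisible, so
  it re-enters the class as an effective within-class transition instead of
  terminating the dwell.  At t_d = 0 the correction vanishes and the exact
  mixture-of-exponentials density is recovered.

The exact Hawkes-Jalali-Colquhoun missed-event likelihood is deliberately not
implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .idealize import AnalysisWindow, EventTable
from .scheme import (
    GatingScheme,
    aggregated_generator,
    aggregated_stationary,
)

__all__ = [
    "DwellSet",
    "extract_dwells",
    "window_events",
    "time_average_po",
    "level_dwell_density",
    "cob_loglik",
    "CobModel",
    "CobResults",
    "fit_cob",
]

MAX_SUPERIMPOSED = 7  # records with more simultaneous openings are rejected

_RATE_NAMES = ("r_CO", "r_OC", "r_OB", "r_BO")


@dataclass
class DwellSet:
    """Dwell durations grouped by conductance level, dead time imposed."""

    dwells: dict[int, np.ndarray]
    n_channels: int
    td: float
    patch_id: str = ""

    def __post_init__(self) -> None:
        self.dwells = {int(k): np.asarray(v, dtype=float) for k, v in self.dwells.items()}
        for k, v in self.dwells.items():
            if k < 0 or k > self.n_channels:
                raise ValueError(f"level {k} outside [0, {self.n_channels}]")
            if v.size and v.min() < self.td - 1e-12:
                raise ValueError(f"level {k} contains dwells shorter than the dead time")

    @property
    def n_events(self) -> int:
        return int(sum(v.size for v in self.dwells.values()))

    def counts(self) -> dict[int, int]:
        return {k: int(v.size) for k, v in self.dwells.items()}


def window_events(
    events: EventTable, window: AnalysisWindow, drop_censored: bool = True
) -> EventTable:
    """Restrict an event table to an analysis window.

    Boundary events are clipped to the window; with ``drop_censored`` the
    first and last (boundary-truncated) events are excluded, as their true
    durations are unknown.
    """
    starts = events.start_times
    ends = starts + events.dwells
    sel = (ends > window.t_start) & (starts < window.t_end)
    idx = np.nonzero(sel)[0]
    if idx.size == 0:
        raise ValueError("no events inside the analysis window")
    lv = events.levels[idx]
    dw = np.minimum(ends[idx], window.t_end) - np.maximum(starts[idx], window.t_start)
    if drop_censored:
        lo = 1 if starts[idx[0]] < window.t_start else 0
        hi = -1 if ends[idx[-1]] > window.t_end else None
        lv, dw = lv[lo:hi], dw[lo:hi]
        if lv.size == 0:
            raise ValueError("window too short: all events censored")
    return EventTable(
        lv, dw, patch_id=events.patch_id, n_channels=events.n_channels,
        dead_time=events.dead_time, dt=events.dt,
    )


def extract_dwells(
    events: EventTable,
    window: AnalysisWindow | None = None,
    n_channels: int | None = None,
    allow_many_channels: bool = False,
) -> DwellSet:
    """Group the window's dwell durations by conductance level.

    Records with more than seven superimposed openings are rejected (the
    study's inclusion rule) unless ``allow_many_channels``.
    """
    if events.dead_time is None:
        raise ValueError("impose the dead time before extracting dwells")
    n = n_channels if n_channels is not None else events.n_channels
    if n is None:
        raise ValueError("channel count unknown; run count_channels first")
    if n > MAX_SUPERIMPOSED and not allow_many_channels:
        raise ValueError(
            f"record with {n} superimposed channels rejected (limit {MAX_SUPERIMPOSED})"
        )
    ev = window_events(events, window, drop_censored=True) if window else events
    groups = {
        int(k): ev.dwells[ev.levels == k] for k in np.unique(ev.levels)
    }
    return DwellSet(groups, n_channels=n, td=events.dead_time, patch_id=events.patch_id)


def time_average_po(
    events: EventTable, window: AnalysisWindow | None, n_channels: int
) -> float:
    """Open probability as the time-average of the fraction of open channels."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    ev = window_events(events, window, drop_censored=False) if window else events
    total = ev.dwells.sum()
    if total <= 0:
        raise ValueError("zero-length window")
    return float(np.dot(ev.levels, ev.dwells) / (n_channels * total))


# ---------------------------------------------------------------------------
# level-class apparent-dwell densities


def _class_matrices(
    rates: np.ndarray, n_channels: int, td: float, missed_events: bool = True
):
    """Per-level entry distribution, apparent generator and visible exit rates.

    Returns {k: (phi, A, v)} where the apparent dwell density of level class
    k is phi @ expm(A t) @ v (before dead-time renormalization).
    """
    scheme = GatingScheme(*rates, i_unit=-1.0)
    q, states = aggregated_generator(scheme, n_channels)
    pi = aggregated_stationary(scheme, n_channels)
    level_of = np.array([s[1] for s in states])
    lam = -np.diag(q)

    out = {}
    for k in range(n_channels + 1):
        members = np.nonzero(level_of == k)[0]
        outside = np.nonzero(level_of != k)[0]
        # stationary entry distribution into the class
        phi = pi[outside] @ q[np.ix_(outside, members)]
        tot = phi.sum()
        phi = phi / tot if tot > 0 else np.full(members.size, 1.0 / members.size)

        m = np.zeros((members.size, members.size))
        if missed_events and td > 0:
            for ci, c in enumerate(members):
                for b in outside:
                    if q[c, b] <= 0:
                        continue
                    p_short = -np.expm1(-lam[b] * td)
                    ret = q[b, members] / lam[b]
                    m[ci] += q[c, b] * p_short * ret
        a = m.copy()
        np.fill_diagonal(a, 0.0)
        np.fill_diagonal(a, -(lam[members] - np.diag(m)))
        v = -a.sum(axis=1)
        out[k] = (phi, a, v)
    return out


def _mixture_weights(phi: np.ndarray, a: np.ndarray, v: np.ndarray):
    """Spectral decomposition: density(t) = sum_i w_i exp(alpha_i t)."""
    if a.shape[0] == 1:
        return np.array([phi[0] * v[0]]), np.array([a[0, 0]])
    vals, vecs = linalg.eig(a)
    w = (phi @ vecs) * (linalg.solve(vecs, v))
    return w, vals


def _density_from_mixture(w, alpha, t, td):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        f = np.real(np.exp(np.multiply.outer(t, alpha)) @ w)
        # renormalize over [td, inf): integral of w exp(alpha t) from td
        z = np.real(np.sum(-w / alpha * np.exp(alpha * td)))
        return f / z, z


def level_dwell_density(
    rates,
    n_channels: int,
    level: int,
    t,
    td: float = 0.0,
    missed_events: bool = True,
) -> np.ndarray:
    """Apparent dwell-time density of level class ``level``, normalized on [td, inf).

    ``rates`` is (r_CO, r_OC, r_OB, r_BO) or a GatingScheme.
    """
    if isinstance(rates, GatingScheme):
        rates = rates.rates
    if not 0 <= level <= n_channels:
        raise ValueError(f"level {level} outside [0, {n_channels}]")
    t = np.asarray(t, dtype=float)
    if np.any(t < td):
        raise ValueError("dwell durations below the dead time have zero density")
    phi, a, v = _class_matrices(np.asarray(rates, float), n_channels, td, missed_events)[level]
    w, alpha = _mixture_weights(phi, a, v)
    f, _ = _density_from_mixture(w, alpha, t, td)
    return f


def cob_loglik(
    rates,
    dwellset: DwellSet,
    missed_events: bool = True,
) -> float:
    """Log-likelihood (nats) of a DwellSet under the C-O-B scheme."""
    if isinstance(rates, GatingScheme):
        rates = rates.rates
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0) or not np.all(np.isfinite(rates)):
        return -np.inf
    try:
        mats = _class_matrices(rates, dwellset.n_channels, dwellset.td, missed_events)
    except linalg.LinAlgError:
        return -np.inf
    ll = 0.0
    for k, dwells in dwellset.dwells.items():
        if dwells.size == 0:
            continue
        w, alpha = _mixture_weights(*mats[k])
        f, _ = _density_from_mixture(w, alpha, dwells, dwellset.td)
        if np.any(~np.isfinite(f)) or np.any(f <= 0):
            return -np.inf
        ll += float(np.log(f).sum())
    return ll


# ---------------------------------------------------------------------------
# model / results


class CobModel:
    """Maximum-likelihood C-O-B kinetic model for one patch's dwell set.

    Parameters are the four transition rates, optimized in log-rate space
    within box bounds.  ``fit`` uses method-of-moments starting values plus
    random multi-starts and returns a :class:`CobResults`.
    """

    def __init__(
        self,
        dwellset: DwellSet,
        missed_events: bool = True,
        bounds: tuple[float, float] = (1e-4, 1e4),
        min_events: int = 10,
    ):
        self.dwellset = dwellset
        self.missed_events = missed_events
        self.bounds = bounds
        counts = dwellset.counts()
        if counts:
            top = max(counts)
            for lev in (0, top):
                if counts.get(lev, 0) < min_events:
                    warnings.warn(
                        f"only {counts.get(lev, 0)} events at level {lev} "
                        f"(minimum {min_events}); fit may be unreliable"
                    )
        if len([k for k, c in counts.items() if c > 0]) < 2:
            raise ValueError("degenerate data: dwells observed at a single level only")

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at log-rate parameters."""
        return cob_loglik(np.exp(params), self.dwellset, self.missed_events)

    def _start_params(self) -> np.ndarray:
        """Method-of-moments starting rates from dwell means."""
        ds = self.dwellset
        td = ds.td
        shut = ds.dwells.get(0, np.empty(0))
        split = max(5 * td, 0.05)
        slow = shut[shut > split]
        fast = shut[shut <= split]
        r_co = 1.0 / max(ds.n_channels * slow.mean(), 1e-3) if slow.size else 0.1
        r_bo = 1.0 / max(fast.mean() - td, 1e-3) if fast.size else 50.0
        open_means = [
            (k, v.mean()) for k, v in ds.dwells.items() if k >= 1 and v.size
        ]
        if open_means:
            k, m = max(open_means, key=lambda km: ds.dwells[km[0]].size)
            r_total = 1.0 / max(k * (m - td), 1e-3)
        else:
            r_total = 1.0
        # split total open exit between burst closure and flicker entry
        n_fast, n_open = fast.size, sum(v.size for k, v in ds.dwells.items() if k >= 1)
        frac = min(max(n_fast / max(n_open, 1), 0.1), 0.9)
        rates = np.array([r_co, (1 - frac) * r_total, frac * r_total, r_bo])
        return np.log(np.clip(rates, *self.bounds))

    def fit(self, start_params=None, n_starts: int = 5, seed: int = 0) -> "CobResults":
        """Maximize the likelihood with multi-start L-BFGS-B; best-of selection."""
        rng = np.random.default_rng(seed)
        log_bounds = [(np.log(self.bounds[0]), np.log(self.bounds[1]))] * 4
        base = (
            np.log(np.asarray(start_params, float))
            if start_params is not None
            else self._start_params()
        )
        starts = [base] + [
            np.clip(base + rng.normal(0, 1.0, 4), log_bounds[0][0], log_bounds[0][1])
            for _ in range(n_starts - 1)
        ]
        def objective(p):
            ll = self.loglike(p)
            return -ll if np.isfinite(ll) else 1e12

        def polish(x0, obj):
            res = optimize.minimize(
                obj, x0, method="L-BFGS-B",
                bounds=[(log_bounds[0][0], log_bounds[0][1])] * len(x0),
            )
            # derivative-free polish; mixture spectra make the numerical
            # gradient noisy near the optimum
            res2 = optimize.minimize(
                obj, res.x, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            return res2 if res2.fun <= res.fun else res

        best, best_ll = None, -np.inf
        for x0 in starts:
            cand = polish(x0, objective)
            if np.isfinite(cand.fun) and -cand.fun > best_ll and cand.fun < 1e11:
                best, best_ll = cand, -cand.fun
        if best is None:
            raise RuntimeError("C-O-B fit failed to converge from any start")

        # Guard against label switching on flicker-poor data: with no real
        # flickers the blocked state can impersonate the interburst state.
        # Compare against the reduced C-O submodel (flicker entry pinned at
        # the lower bound) and keep the extra two parameters only when they
        # earn their keep (AIC: delta-loglik > number of extra parameters).
        lb = np.log(self.bounds[0])
        r_bo_fixed = np.log(1.0 / self.dwellset.td) if self.dwellset.td > 0 else np.log(100.0)

        def reduced_objective(p2):
            return objective(np.array([p2[0], p2[1], lb, r_bo_fixed]))

        red = polish(base[:2], reduced_objective)
        if np.isfinite(red.fun) and (best_ll - (-red.fun)) < 2.0:
            full_x = np.array([red.x[0], red.x[1], lb, r_bo_fixed])
            best = optimize.OptimizeResult(
                x=full_x, fun=red.fun, success=getattr(red, "success", True)
            )
            return CobResults(self, best, seed, reduced=True)
        return CobResults(self, best, seed)


class CobResults:
    """Fitted C-O-B rates with derived gating parameters.

    Attributes
    ----------
    rates : dict
        r_CO, r_OC, r_OB, r_BO (s^-1).
    tau_b, tau_ib : float
        Mean burst / interburst durations, s.
    opening_rate, closing_rate : float
        1/tau_ib and 1/tau_b, s^-1.
    p_open : float
        Stationary open probability of the fitted scheme.
    bse : dict
        Asymptotic standard errors from the observed information
        (delta method from log-rate space).
    flicker_resolved : bool
        False when fitted r_BO > 1/t_d, i.e. mean flicker duration below the
        dead time so most flickers are missed; r_OB and r_BO are then poorly
        identified individually although tau_b remains meaningful.
    reduced : bool
        True when the data did not support distinguishable flickers and the
        flicker-free C-O submodel was selected; r_OB sits at its lower bound
        and r_BO is nominal.
    """

    def __init__(self, model: CobModel, opt_result, seed: int, reduced: bool = False):
        self.model = model
        self._opt = opt_result
        self.reduced = reduced
        self.params = np.exp(opt_result.x)
        self.rates = dict(zip(_RATE_NAMES, self.params))
        self.llf = float(-opt_result.fun)
        self.converged = bool(opt_result.success)
        self.n_events = model.dwellset.n_events
        scheme = GatingScheme(*self.params, i_unit=-1.0)
        self.tau_b = scheme.tau_b
        self.tau_ib = scheme.tau_ib
        self.opening_rate = 1.0 / self.tau_ib
        self.closing_rate = 1.0 / self.tau_b
        self.p_open = scheme.p_open
        td = model.dwellset.td
        self.flicker_resolved = not (td > 0 and self.rates["r_BO"] > 1.0 / td)
        self.bse = self._compute_bse()

    def _compute_bse(self) -> dict[str, float]:
        x = self._opt.x
        h = 1e-4
        free = [0, 1] if self.reduced else [0, 1, 2, 3]
        n = len(free)
        hess = np.zeros((n, n))
        for ii, i in enumerate(free):
            for jj, j in enumerate(free[ii:], start=ii):
                ei, ej = np.zeros(x.size), np.zeros(x.size)
                ei[i], ej[j] = h, h
                fpp = self.model.loglike(x + ei + ej)
                fpm = self.model.loglike(x + ei - ej)
                fmp = self.model.loglike(x - ei + ej)
                fmm = self.model.loglike(x - ei - ej)
                hess[ii, jj] = hess[jj, ii] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        se_log = np.full(4, np.nan)
        try:
            cov = np.linalg.inv(-hess)
            se_log[free] = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
        return {name: float(r * s) for name, r, s in zip(_RATE_NAMES, self.params, se_log)}

    def to_dict(self) -> dict:
        return {
            **{k: float(v) for k, v in self.rates.items()},
            "tau_b": self.tau_b,
            "tau_ib": self.tau_ib,
            "opening_rate": self.opening_rate,
            "closing_rate": self.closing_rate,
            "p_open": self.p_open,
            "loglik": self.llf,
            "converged": self.converged,
            "n_events": self.n_events,
            "flicker_resolved": self.flicker_resolved,
            "reduced": self.reduced,
        }

    def summary(self) -> str:
        ds = self.model.dwellset
        lines = [
            "C-O-B maximum-likelihood fit",
            "=" * 46,
            f"patch: {ds.patch_id or '<unnamed>'}   channels: {ds.n_channels}   "
            f"dead time: {ds.td * 1e3:.1f} ms",
            f"events: {self.n_events}   log-likelihood: {self.llf:.2f}   "
            f"converged: {self.converged}",
            "-" * 46,
            f"{'rate':>8} {'estimate (s^-1)':>16} {'std err':>10}",
        ]
        for name in _RATE_NAMES:
            lines.append(
                f"{name:>8} {self.rates[name]:>16.4g} {self.bse[name]:>10.3g}"
            )
        lines += [
            "-" * 46,
            f"tau_b  = {self.tau_b * 1e3:10.1f} ms   closing rate = {self.closing_rate:.4g} /s",
            f"tau_ib = {self.tau_ib * 1e3:10.1f} ms   opening rate = {self.opening_rate:.4g} /s",
            f"P_o (stationary) = {self.p_open:.4g}",
        ]
        if self.reduced:
            lines.append("note: no distinguishable flickers; flicker-free C-O submodel selected")
        elif not self.flicker_resolved:
            lines.append("warning: mean flicker duration below the dead time; r_OB, r_BO poorly identified")
        return "\n".join(lines)


def fit_cob(
    dwellset: DwellSet,
    init=None,
    bounds: tuple[float, float] = (1e-4, 1e4),
    n_starts: int = 5,
    seed: int = 0,
    missed_events: bool = True,
) -> CobResults:
    """Convenience wrapper: build a :class:`CobModel` and fit it."""
    model = CobModel(dwellset, missed_events=missed_events, bounds=bounds)
    return model.fit(start_params=init, n_starts=n_starts, seed=seed)
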