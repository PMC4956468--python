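"""Thermodynamic double-mutant-cycle analysis of gating parameters.

A mutant cycle compares a background construct (XY), the two single mutants
(X'Y, XY') and the double mutant (X'Y').  For a transition from ground state
A to state B the mutation-induced change in relative stability along one side
is ΔΔG°(B-A) = -kT ln(u/v) with u, v the gating parameter (K_eq for ground
states, a transition rate for barriers) of the two constructs; the coupling
free energy is the difference of two parallel sides,

    ΔΔG_int = ΔΔG°(X'Y -> X'Y') - ΔΔG°(XY -> XY')
            = ΔΔG°(XY' -> X'Y') - ΔΔG°(XY -> X'Y),

an algebraic identity on the corner means.  A nonzero ΔΔG_int signals a
state-dependent interaction between the two mutated side chains.  All
energies are in kT units (kT = 1).

Uncertainties use the second-order power-series approximation of
var(ln(u/v)) for independent normal u, v, with standard errors formed by
dividing by the mean corner count n̄ (counts per corner being similar).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConstructStats",
    "MutantCycle",
    "CouplingResult",
    "keq_from_po",
    "ddg_ground",
    "ddg_barrier",
    "var_log_ratio",
    "sem_ddg",
    "sem_coupling",
    "mc_var_oracle",
    "t_test_vs_zero",
]

CORNERS = ("XY", "X'Y", "XY'", "X'Y'")


def keq_from_po(po: float) -> float:
    """Closed-open equilibrium constant K_eq = P_o/(1-P_o)."""
    if not 0.0 < po < 1.0:
        raise ValueError(f"P_o must lie strictly in (0, 1), got {po}")
    return po / (1.0 - po)


def ddg_ground(keq_b: float, keq_a: float) -> float:
    """Ground-state stability change ΔΔG° = -kT ln(K_eq,B / K_eq,A), kT units.

    Negative when the perturbation stabilizes the open state (K_eq increases).
    """
    if keq_b <= 0 or keq_a <= 0:
        raise ValueError("equilibrium constants must be positive")
    return -float(np.log(keq_b / keq_a))


def ddg_barrier(rate_b: float, rate_a: float) -> float:
    """Barrier change ΔΔG°(T-A) = -kT ln(r_B / r_A) from fractional rate change.

    For opening rates (A = C) this is ΔΔG°(T-C); for closing rates (A = O)
    it is ΔΔG°(T-O).
    """
    if rate_b <= 0 or rate_a <= 0:
        raise ValueError("rates must be positive")
    return -float(np.log(rate_b / rate_a))


def var_log_ratio(m_u: float, s_u: float, m_v: float, s_v: float) -> float:
    """Second-order approximation of var(ln(u/v)) for independent normal u, v.

        var ≈ su²/mu² + sv²/mv² + (1/2)(su²/mu²)(sv²/mv²)
              - (1/4)(su⁴/mu⁴ + sv⁴/mv⁴)

    Valid for s << m; still accurate at s = 0.2 m.  A warning is issued when
    either coefficient of variation exceeds 0.2.
    """
    if m_u <= 0 or m_v <= 0:
        raise ValueError("means must be positive")
    cu2 = (s_u / m_u) ** 2
    cv2 = (s_v / m_v) ** 2
    if cu2 > 0.04 + 1e-12 or cv2 > 0.04 + 1e-12:
        warnings.warn(
            "coefficient of variation exceeds 0.2; the second-order variance "
            "approximation degrades"
        )
    return cu2 + cv2 + 0.5 * cu2 * cv2 - 0.25 * (cu2**2 + cv2**2)


def sem_ddg(var: float, n_pair: tuple[int, int]) -> float:
    """SEM of one ΔΔG° leg: sqrt(var / n̄) with n̄ the mean of the two counts."""
    if var < 0:
        raise ValueError("variance must be non-negative")
    if min(n_pair) < 2:
        raise ValueError("need at least two patches per construct")
    n_bar = 0.5 * (n_pair[0] + n_pair[1])
    return float(np.sqrt(var / n_bar))


def sem_coupling(var_leg1: float, var_leg2: float, four_counts) -> float:
    """SEM of ΔΔG_int: sqrt((var1 + var2)/n̄) with n̄ the four-corner mean count."""
    if var_leg1 < 0 or var_leg2 < 0:
        raise ValueError("variances must be non-negative")
    n_bar = float(np.mean(four_counts))
    return float(np.sqrt((var_leg1 + var_leg2) / n_bar))


def mc_var_oracle(
    m_u: float,
    s_u: float,
    m_v: float,
    s_v: float,
    n_draws: int = 10**6,
    seed: int = 0,
) -> float:
    """Monte-Carlo variance of ln(u/v) over independent normal draws.

    Validation oracle for :func:`var_log_ratio` (the underlying double
    integral has no closed form).  Non-positive draws are rejected; if more
    than 1% of draws are rejected the approximation domain is exceeded and a
    warning is issued.
    """
    if n_draws < 10**4:
        raise ValueError("use at least 10^4 draws")
    rng = np.random.default_rng(seed)
    u = rng.normal(m_u, s_u, n_draws)
    v = rng.normal(m_v, s_v, n_draws)
    ok = (u > 0) & (v > 0)
    frac_rejected = 1.0 - ok.mean()
    if frac_rejected > 0.01:
        warnings.warn(
            f"{frac_rejected:.1%} of draws non-positive; log-ratio variance "
            "approximation domain exceeded"
        )
    return float(np.var(np.log(u[ok] / v[ok])))


def t_test_vs_zero(ddg_int: float, sem: float, n_bar: float) -> float:
    """Two-tailed Student's t p-value for ΔΔG_int against zero, df = n̄ - 1."""
    if sem <= 0:
        raise ValueError("SEM must be positive")
    df = n_bar - 1.0
    if df < 1:
        raise ValueError("degrees of freedom below 1")
    t = ddg_int / sem
    return float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class ConstructStats:
    """Across-patch statistics of one gating parameter for one corner.

    ``values`` are per-patch estimates (K_eq, opening rate, or closing
    rate); mean/SD/n may instead be supplied directly, e.g. when working
    from published summary numbers.
    """

    label: str
    parameter: str = "K_eq"
    values: np.ndarray | None = None
    mean: float | None = None
    sd: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.mean is None:
                self.mean = float(self.values.mean())
            if self.sd is None:
                self.sd = float(self.values.std(ddof=1))
            if self.n is None:
                self.n = int(self.values.size)
        if self.n is None or self.n < 2:
            raise ValueError("need n >= 2 patches per construct")
        if self.mean is None or self.mean <= 0:
            raise ValueError("construct mean must be positive for log-ratio energetics")
        if self.sd is None or self.sd < 0:
            raise ValueError("SD must be non-negative")

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)


class MutantCycle:
    """One thermodynamic mutant cycle over four construct corners.

    Corners follow the XY / X'Y / XY' / X'Y' convention (background, the two
    single mutants, double mutant), all carrying the same gating parameter.
    ``fit()`` evaluates the four legs, the coupling energy with its SEM and a
    Student's t test against zero, returning a :class:`CouplingResult`.
    """

    def __init__(
        self,
        xy: ConstructStats,
        xpy: ConstructStats,
        xyp: ConstructStats,
        xpyp: ConstructStats,
    ):
        corners = (xy, xpy, xyp, xpyp)
        params = {c.parameter for c in corners}
        if len(params) != 1:
            raise ValueError(f"corners carry mixed parameters: {sorted(params)}")
        self.corners = dict(zip(CORNERS, corners))
        self.parameter = corners[0].parameter

    def fit(self) -> "CouplingResult":
        c = self.corners
        m = {k: v.mean for k, v in c.items()}
        legs = {
            "XY->X'Y": ddg_ground(m["X'Y"], m["XY"]),
            "XY->XY'": ddg_ground(m["XY'"], m["XY"]),
            "X'Y->X'Y'": ddg_ground(m["X'Y'"], m["X'Y"]),
            "XY'->X'Y'": ddg_ground(m["X'Y'"], m["XY'"]),
        }
        ddg_int_1 = legs["X'Y->X'Y'"] - legs["XY->XY'"]
        ddg_int_2 = legs["XY'->X'Y'"] - legs["XY->X'Y"]
        assert abs(ddg_int_1 - ddg_int_2) < 1e-9 * max(1.0, abs(ddg_int_1)), (
            "parallel-side evaluations must agree (algebraic identity)"
        )
        var_leg1 = var_log_ratio(m["X'Y'"], c["X'Y'"].sd, m["X'Y"], c["X'Y"].sd)
        var_leg2 = var_log_ratio(m["XY'"], c["XY'"].sd, m["XY"], c["XY"].sd)
        counts = [c[k].n for k in CORNERS]
        sem_int = sem_coupling(var_leg1, var_leg2, counts)
        n_bar = float(np.mean(counts))
        p = t_test_vs_zero(ddg_int_1, sem_int, n_bar) if sem_int > 0 else np.nan
        leg_sems = {
            "XY->X'Y": sem_ddg(
                var_log_ratio(m["X'Y"], c["X'Y"].sd, m["XY"], c["XY"].sd),
                (c["XY"].n, c["X'Y"].n),
            ),
            "XY->XY'": sem_ddg(var_leg2, (c["XY"].n, c["XY'"].n)),
            "X'Y->X'Y'": sem_ddg(var_leg1, (c["X'Y"].n, c["X'Y'"].n)),
            "XY'->X'Y'": sem_ddg(
                var_log_ratio(m["X'Y'"], c["X'Y'"].sd, m["XY'"], c["XY'"].sd),
                (c["XY'"].n, c["X'Y'"].n),
            ),
        }
        return CouplingResult(
            parameter=self.parameter,
            legs=legs,
            leg_sems=leg_sems,
            ddg_int=float(ddg_int_1),
            sem=float(sem_int),
            n_bar=n_bar,
            p_value=float(p),
            corners={k: v for k, v in c.items()},
        )


@dataclass
class CouplingResult:
    """Coupling free energy of one mutant cycle, kT units.

    Note: if the native interaction is *restored* in the double mutant
    (rather than absent in all three mutant corners), ΔΔG_int reports the sum
    of the interaction-strength changes of the XY and X'Y' pairs — a signal
    amplification, not a single-pair energy.  Carried here as the
    ``restored_interaction_caveat`` flag, not as a numeric correction.
    """

    parameter: str
    legs: dict[str, float]
    leg_sems: dict[str, float]
    ddg_int: float
    sem: float
    n_bar: float
    p_value: float
    corners: dict[str, ConstructStats] = field(default_factory=dict)
    restored_interaction_caveat: bool = True

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "legs_kT": {k: float(v) for k, v in self.legs.items()},
            "leg_sems_kT": {k: float(v) for k, v in self.leg_sems.items()},
            "ddg_int_kT": self.ddg_int,
            "sem_kT": self.sem,
            "n_bar": self.n_bar,
            "p_value": self.p_value,
            "restored_interaction_caveat": self.restored_interaction_caveat,
        }

    def summary(self) -> str:
        kind = "ΔΔG°(O-C)" if self.parameter == "K_eq" else (
            "ΔΔG°(T-C)" if "open" in self.parameter else "ΔΔG°(T-O)"
        )
        lines = [
            f"Mutant cycle — parameter: {self.parameter}  ({kind} legs, kT units)",
            "=" * 60,
        ]
        for k in ("XY->X'Y", "XY->XY'", "X'Y->X'Y'", "XY'->X'Y'"):
            lines.append(f"  {k:<12} {self.legs[k]:+7.2f} ± {self.leg_sems[k]:.2f} kT")
        lines += [
            "-" * 60,
            f"  ΔΔG_int = {self.ddg_int:+.2f} ± {self.sem:.2f} kT   "
            f"(n̄ = {self.n_bar:.1f}, p = {self.p_value:.2g})",
        ]
        if self.restored_interaction_caveat:
            lines.append(
                "  note: with an interaction restored in the double mutant, ΔΔG_int"
            )
            lines.append(
                "  sums the XY and X'Y' interaction changes (signal amplification)."
            )
        return "\n".join(lines)
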