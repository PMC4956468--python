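"""Closed-Open-Blocked (C-O-B) gating scheme and its Markov generators.

The linear three-state scheme

    C  <--r_CO/r_OC-->  O  <--r_OB/r_BO-->  B

separates long interburst closures (state C) from brief "flickery" closures
(state B) interrupting a burst of openings.  Only the open state conducts.
All energies downstream are expressed in kT units, so the scheme carries
rates (s^-1) and the unit current only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

STATES = ("C", "O", "B")

__all__ = [
    "GatingScheme",
    "stationary_distribution",
    "aggregated_states",
    "aggregated_generator",
    "aggregated_stationary",
]


class InvalidSchemeError(ValueError):
    """Raised when rate constants violate the C-O-B scheme invariants."""


@dataclass(frozen=True)
class GatingScheme:
    """Rate constants of one construct's C-O-B scheme.

    Parameters
    ----------
    r_CO : float
        Opening rate (interburst closed -> open), s^-1.
    r_OC : float
        Burst-terminating closing rate (open -> interburst closed), s^-1.
    r_OB : float
        Flicker-block entry rate (open -> blocked), s^-1.
    r_BO : float
        Flicker-block exit rate (blocked -> open), s^-1.
    i_unit : float
        Unitary current, pA; negative at -80 mV.
    """

    r_CO: float
    r_OC: float
    r_OB: float
    r_BO: float
    i_unit: float = -0.64

    def __post_init__(self) -> None:
        rates = (self.r_CO, self.r_OC, self.r_OB, self.r_BO)
        if not all(np.isfinite(r) and r > 0 for r in rates):
            raise InvalidSchemeError(
                f"all four rates must be strictly positive and finite, got {rates}"
            )
        if self.i_unit == 0 or not np.isfinite(self.i_unit):
            raise InvalidSchemeError("i_unit must be nonzero and finite")

    @property
    def rates(self) -> np.ndarray:
        """Rate vector (r_CO, r_OC, r_OB, r_BO)."""
        return np.array([self.r_CO, self.r_OC, self.r_OB, self.r_BO])

    @property
    def generator(self) -> np.ndarray:
        """Single-channel generator matrix Q over states (C, O, B)."""
        return np.array(
            [
                [-self.r_CO, self.r_CO, 0.0],
                [self.r_OC, -(self.r_OC + self.r_OB), self.r_OB],
                [0.0, self.r_BO, -self.r_BO],
            ]
        )

    @property
    def tau_b(self) -> float:
        """Mean burst duration (1/r_OC)(1 + r_OB/r_BO), s."""
        return (1.0 / self.r_OC) * (1.0 + self.r_OB / self.r_BO)

    @property
    def tau_ib(self) -> float:
        """Mean interburst duration 1/r_CO, s."""
        return 1.0 / self.r_CO

    @property
    def p_open(self) -> float:
        """Stationary open probability pi_O."""
        return float(stationary_distribution(self)[1])

    @property
    def k_eq(self) -> float:
        """Closed-open equilibrium constant P_o/(1-P_o)."""
        po = self.p_open
        return po / (1.0 - po)


def stationary_distribution(scheme: GatingScheme) -> np.ndarray:
    """Stationary probabilities (pi_C, pi_O, pi_B) of the C-O-B chain.

    The linear chain is reversible, so detailed balance gives the
    closed form pi_O/pi_C = r_CO/r_OC and pi_B/pi_O = r_OB/r_BO.
    """
    w_c = scheme.r_OC / scheme.r_CO
    w_b = scheme.r_OB / scheme.r_BO
    pi = np.array([w_c, 1.0, w_b])
    return pi / pi.sum()


def aggregated_states(n_channels: int) -> list[tuple[int, int, int]]:
    """Enumerate occupation states (n_C, n_O, n_B) of N independent channels.

    Ordered by level (n_O) then by n_B, so level classes are contiguous.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    states = [
        (n_channels - n_o - n_b, n_o, n_b)
        for n_o, n_b in itertools.product(range(n_channels + 1), repeat=2)
        if n_o + n_b <= n_channels
    ]
    states.sort(key=lambda s: (s[1], s[2]))
    return states


def aggregated_generator(
    scheme: GatingScheme, n_channels: int
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Generator of N superimposed independent C-O-B channels.

    Returns (Q, states) where states[i] = (n_C, n_O, n_B) and the level class
    of state i is its n_O.  Off-diagonal rates are occupancy-weighted
    single-channel rates; rows sum to zero.
    """
    states = aggregated_states(n_channels)
    index = {s: i for i, s in enumerate(states)}
    q = np.zeros((len(states), len(states)))
    for i, (nc, no, nb) in enumerate(states):
        moves = [
            ((nc - 1, no + 1, nb), nc * scheme.r_CO),
            ((nc + 1, no - 1, nb), no * scheme.r_OC),
            ((nc, no - 1, nb + 1), no * scheme.r_OB),
            ((nc, no + 1, nb - 1), nb * scheme.r_BO),
        ]
        for dest, rate in moves:
            if rate > 0 and dest in index:
                q[i, index[dest]] = rate
        q[i, i] = -q[i].sum()
    return q, states


def aggregated_stationary(scheme: GatingScheme, n_channels: int) -> np.ndarray:
    """Stationary distribution of the aggregated chain.

    Independence makes it the multinomial composition of the single-channel
    stationary vector.
    """
    pi1 = stationary_distribution(scheme)
    states = aggregated_states(n_channels)
    log_pi1 = np.log(pi1)
    out = np.empty(len(states))
    from math import lgamma

    for i, (nc, no, nb) in enumerate(states):
        log_coef = (
            lgamma(n_channels + 1) - lgamma(nc + 1) - lgamma(no + 1) - lgamma(nb + 1)
        )
        out[i] = np.exp(log_coef + nc * log_pi1[0] + no * log_pi1[1] + nb * log_pi1[2])
    return out / out.sum()
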