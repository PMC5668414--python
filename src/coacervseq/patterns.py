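"""Charge-patterned sequence design.

A patterned polyelectrolyte is described by three numbers: chain length ``N``,
charged fraction ``f`` and periodicity ``tau`` (monomers per repeat).  Each
period carries a contiguous block of ``tau*f`` charged monomers followed by
``tau*(1-f)`` neutral ones; an alternating chain is tau=2, a chain of eight
charges followed by eight neutral monomers is tau=16.  The charged block sits
at the start of each period: any cyclic shift is statistically equivalent for
a periodic chain, and fixing the phase makes generation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np

__all__ = [
    "ChargePattern",
    "SystemComposition",
    "make_periodic_pattern",
    "charge_balance",
    "composition_from_concentrations",
]


@dataclass(frozen=True)
class ChargePattern:
    """Per-monomer valence sequence of one chain.

    Attributes
    ----------
    N : chain length (monomer count).
    f : charged fraction in [0, 1].
    tau : periodicity (monomers per repeat).
    charges : tuple of per-monomer valences, each in {-1, 0, +1}.
    """

    N: int
    f: float
    tau: int
    charges: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.charges) != self.N:
            raise ValueError("charges length must equal N")
        n_charged = sum(1 for z in self.charges if z != 0)
        if n_charged != round(self.f * self.N) or abs(
            n_charged - self.f * self.N
        ) > 1e-9:
            raise ValueError(
                f"charged count {n_charged} does not equal N*f = {self.f * self.N}"
            )
        for s, z in enumerate(self.charges):
            if z != self.charges[s % self.tau]:
                raise ValueError(f"sequence is not tau={self.tau} periodic at index {s}")

    @property
    def net_charge(self) -> int:
        return int(sum(self.charges))

    @property
    def n_charged(self) -> int:
        return sum(1 for z in self.charges if z != 0)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.charges, dtype=np.int64)

    def to_string(self) -> str:
        """One character per monomer: '+', '-' or '0'."""
        return "".join("+" if z > 0 else "-" if z < 0 else "0" for z in self.charges)

    @classmethod
    def from_string(cls, s: str, tau: int | None = None) -> "ChargePattern":
        charges = tuple({"+": 1, "-": -1, "0": 0}[c] for c in s)
        N = len(charges)
        if tau is None:
            tau = _minimal_period(charges)
        f = sum(1 for z in charges if z != 0) / N
        return cls(N=N, f=f, tau=tau, charges=charges)


def _minimal_period(charges: tuple[int, ...]) -> int:
    N = len(charges)
    for p in range(1, N + 1):
        if N % p == 0 and all(charges[s] == charges[s % p] for s in range(N)):
            return p
    return N


def make_periodic_pattern(N: int, tau: int, f: float, sign: int) -> ChargePattern:
    """Build a tau-periodic block pattern of ``N`` monomers.

    Each period of length ``tau`` starts with ``tau*f`` monomers of valence
    ``sign`` and ends with ``tau*(1-f)`` neutral monomers.  ``tau`` must
    divide ``N`` and ``tau*f`` must be a positive integer; generation fails
    rather than rounding.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    if not (0.0 < f <= 1.0):
        raise ValueError("charged fraction f must be in (0, 1]")
    if tau < 1 or tau > N:
        raise ValueError(f"tau={tau} must satisfy 1 <= tau <= N={N}")
    if N % tau != 0:
        raise ValueError(f"tau={tau} must divide N={N}")
    block = tau * f
    if abs(block - round(block)) > 1e-9 or round(block) < 1:
        raise ValueError(
            f"tau*f = {tau}*{f} = {block} is not a positive integer: "
            "the charged block per period must contain a whole number of monomers"
        )
    block = round(block)
    period = (sign,) * block + (0,) * (tau - block)
    charges = period * (N // tau)
    return ChargePattern(N=N, f=f, tau=tau, charges=charges)


def charge_balance(polyanion: ChargePattern, polycation: ChargePattern) -> tuple[int, int]:
    """Smallest integer chain counts ``(n_polycation, n_polyanion)`` giving zero
    net polymer charge.

    Example: a homopolyanion with 48 negative charges and a half-charged
    polycation with 24 positive charges balance at two polycations per
    polyanion.
    """
    qa, qc = polyanion.net_charge, polycation.net_charge
    if qa >= 0 or qc <= 0:
        raise ValueError(
            "expected a net-negative polyanion and net-positive polycation; "
            f"got net charges {qa} and {qc}"
        )
    ratio = Fraction(-qa, qc)  # polycations per polyanion
    return ratio.numerator, ratio.denominator


@dataclass(frozen=True)
class SystemComposition:
    """Integer particle content of one periodic simulation box."""

    n_Pplus: int  # polycation chains
    n_Pminus: int  # polyanion chains
    n_plus: int  # small cations
    n_minus: int  # small anions
    box_length: float  # reduced units
    c_P: float = 0.0  # realized charged-monomer concentration (caller's units)
    c_S: float = 0.0  # realized added-salt concentration (caller's units)
    polycation: ChargePattern | None = None
    polyanion: ChargePattern | None = None

    def __post_init__(self) -> None:
        for name in ("n_Pplus", "n_Pminus", "n_plus", "n_minus"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.polycation is not None and self.polyanion is not None:
            if self.total_charge != 0:
                raise ValueError(
                    f"system is not electroneutral: net charge {self.total_charge}"
                )

    @property
    def total_charge(self) -> int:
        q = self.n_plus - self.n_minus
        if self.polycation is not None:
            q += self.n_Pplus * self.polycation.net_charge
        if self.polyanion is not None:
            q += self.n_Pminus * self.polyanion.net_charge
        return q

    @property
    def n_beads(self) -> int:
        n = self.n_plus + self.n_minus
        if self.polycation is not None:
            n += self.n_Pplus * self.polycation.N
        if self.polyanion is not None:
            n += self.n_Pminus * self.polyanion.N
        return n


def composition_from_concentrations(
    c_P: float,
    c_S: float,
    box_length: float,
    polycation: ChargePattern,
    polyanion: ChargePattern,
    mM_per_reduced_density: float | None = None,
) -> SystemComposition:
    """Convert target concentrations into integer particle counts for one box.

    ``c_P`` is the total charged-monomer concentration and ``c_S`` the added
    salt concentration.  If ``mM_per_reduced_density`` is given the inputs are
    in mM; otherwise they are reduced number densities (per sigma^3).  Chains
    are added in the smallest charge-balancing ratio, rounding the number of
    repeat units to the nearest integer (realized concentrations are echoed in
    ``c_P``/``c_S``); neutralizing counterions are added if polymer charges do
    not cancel exactly, and salt as equal numbers of cations and anions.
    """
    conv = mM_per_reduced_density if mM_per_reduced_density is not None else 1.0
    rho_P = c_P / conv  # charged monomers / sigma^3
    rho_S = c_S / conv  # salt pairs / sigma^3
    V = box_length**3

    p, q = charge_balance(polyanion, polycation)  # p polycations : q polyanions
    charges_per_unit = p * polycation.n_charged + q * polyanion.n_charged
    n_units = int(round(rho_P * V / charges_per_unit))
    if rho_P > 0 and n_units < 1:
        raise ValueError(
            f"box of edge {box_length} too small to hold one charge-balanced "
            f"chain unit ({p}:{q}) at charged-monomer density {rho_P:g}"
        )
    n_Pplus, n_Pminus = n_units * p, n_units * q

    n_salt = int(round(rho_S * V))
    n_plus = n_minus = n_salt
    residual = n_Pplus * polycation.net_charge + n_Pminus * polyanion.net_charge
    if residual > 0:
        n_minus += residual
    elif residual < 0:
        n_plus += -residual

    return SystemComposition(
        n_Pplus=n_Pplus,
        n_Pminus=n_Pminus,
        n_plus=n_plus,
        n_minus=n_minus,
        box_length=box_length,
        c_P=n_units * charges_per_unit / V * conv,
        c_S=n_salt / V * conv,
        polycation=polycation,
        polyanion=polyanion,
    )
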