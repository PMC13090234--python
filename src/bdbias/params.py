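"""Parameters of the constant-rate birth-death process."""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BDParams:
    """Speciation/extinction rates with the derived composites.

    Parameters
    ----------
    lam : float
        Speciation (birth) rate, events per lineage per unit time; >= 0.
    mu : float
        Extinction (death) rate, events per lineage per unit time; >= 0.

    Derived attributes: ``r = lam - mu`` (net diversification),
    ``epsilon = mu / lam`` (extinction fraction, undefined for ``lam == 0``)
    and ``tau = lam + mu`` (turnover).
    """

    lam: float
    mu: float

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError(f"rates must be nonnegative, got lam={self.lam}, mu={self.mu}")

    @property
    def r(self) -> float:
        return self.lam - self.mu

    @property
    def epsilon(self) -> float:
        if self.lam == 0:
            raise ZeroDivisionError("extinction fraction undefined when lam == 0")
        return self.mu / self.lam

    @property
    def tau(self) -> float:
        return self.lam + self.mu

    @classmethod
    def from_turnover(cls, tau: float, epsilon: float) -> "BDParams":
        """Back-transform (turnover, extinction fraction) to (lam, mu)."""
        if tau < 0 or epsilon < 0:
            raise ValueError("tau and epsilon must be nonnegative")
        lam = tau / (1.0 + epsilon)
        return cls(lam=lam, mu=tau - lam)

    @property
    def is_critical(self) -> bool:
        """True when lam and mu are equal to within the numerical guard."""
        return abs(self.lam - self.mu) < 1e-9 * max(self.lam, self.mu, 1e-300)
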