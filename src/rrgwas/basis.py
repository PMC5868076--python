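"""Time-basis functions for random-regression lactation models.

Every time-dependent term in the model — the group mean curve, the
time-varying SNP effect, the additive-genetic and permanent-environment
trajectories — is a linear combination of a small set of basis functions of
days in milk (DIM).  Two families are supported:

* **Legendre polynomials** on DIM mapped affinely to [-1, 1], the standard
  choice in dairy random-regression evaluations.  With ``normalized=True``
  the k-th function is sqrt((2k+1)/2)·P_k(s), which makes the basis
  orthonormal under the L2 inner product on [-1, 1].
* **Wilmink curve** terms [1, t, exp(-c·t)], a biological lactation-curve
  parameterization with a single decay constant ``c`` (default 0.05/day).

The basis order is the highest polynomial index k, so a Legendre basis of
order ``k`` has ``k + 1`` functions; the Wilmink family always has three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = ["BasisSpec", "standardize_time", "evaluate_basis", "basis_matrix"]

DEFAULT_TIME_DOMAIN = (5.0, 305.0)
DEFAULT_WILMINK_RATE = 0.05


@dataclass(frozen=True)
class BasisSpec:
    """Specification of one time basis.

    Parameters
    ----------
    family:
        ``"legendre"`` or ``"wilmink"``.
    order:
        Highest basis index k for Legendre (k+1 functions).  Ignored for
        Wilmink, which always has its 3 terms.
    time_domain:
        (t_min, t_max) in days; times outside raise a ``ValueError``.
    normalized:
        Legendre only: scale P_k by sqrt((2k+1)/2) so the basis is
        orthonormal on [-1, 1].
    wilmink_rate:
        Exponential decay constant of the Wilmink term, per day.
    """

    family: str = "legendre"
    order: int = 4
    time_domain: tuple[float, float] = DEFAULT_TIME_DOMAIN
    normalized: bool = True
    wilmink_rate: float = DEFAULT_WILMINK_RATE

    def __post_init__(self) -> None:
        if self.family not in ("legendre", "wilmink"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.order < 0:
            raise ValueError("basis order must be non-negative")
        t_min, t_max = self.time_domain
        if not t_min < t_max:
            raise ValueError(f"invalid time domain [{t_min}, {t_max}]")
        if self.family == "wilmink" and self.wilmink_rate <= 0:
            raise ValueError("wilmink_rate must be positive")

    @property
    def n_basis(self) -> int:
        """Number of basis functions (order+1 for Legendre, 3 for Wilmink)."""
        return 3 if self.family == "wilmink" else self.order + 1

    def to_dict(self) -> dict:
        t_min, t_max = self.time_domain
        return {
            "family": self.family,
            "order": self.order,
            "t_min": float(t_min),
            "t_max": float(t_max),
            "normalized": self.normalized,
            "wilmink_rate": self.wilmink_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            family=d.get("family", "legendre"),
            order=int(d.get("order", 4)),
            time_domain=(float(d.get("t_min", 5.0)), float(d.get("t_max", 305.0))),
            normalized=bool(d.get("normalized", True)),
            wilmink_rate=float(d.get("wilmink_rate", DEFAULT_WILMINK_RATE)),
        )


def standardize_time(t, domain=DEFAULT_TIME_DOMAIN):
    """Affinely map days ``t`` in [t_min, t_max] onto [-1, 1].

    Scalar or array input; raises ``ValueError`` for out-of-domain times,
    naming the offending value.
    """
    t = np.asarray(t, dtype=float)
    t_min, t_max = domain
    bad = (t < t_min) | (t > t_max)
    if np.any(bad):
        offending = np.atleast_1d(t)[np.atleast_1d(bad)]
        raise ValueError(
            f"time(s) {offending.tolist()} outside basis domain [{t_min}, {t_max}]"
        )
    return 2.0 * (t - t_min) / (t_max - t_min) - 1.0


def evaluate_basis(t: float, spec: BasisSpec) -> np.ndarray:
    """Evaluate all basis functions of ``spec`` at one time ``t`` (days)."""
    return basis_matrix([t], spec)[0]


def basis_matrix(times, spec: BasisSpec) -> np.ndarray:
    """Row-wise basis evaluation: row r is the basis vector at ``times[r]``.

    Returns an (len(times), spec.n_basis) array; empty input gives an
    empty (0, n_basis) matrix.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size == 0:
        return np.empty((0, spec.n_basis))
    if spec.family == "wilmink":
        # domain check only; Wilmink terms are functions of raw DIM
        standardize_time(times, spec.time_domain)
        return np.column_stack(
            [np.ones_like(times), times, np.exp(-spec.wilmink_rate * times)]
        )
    s = standardize_time(times, spec.time_domain)
    # legvander gives P_0..P_k by the classical three-term recurrence
    V = npleg.legvander(s, spec.order)
    if spec.normalized:
        k = np.arange(spec.order + 1)
        V = V * np.sqrt((2 * k + 1) / 2.0)
    return V
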