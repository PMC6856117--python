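"""Parametric trait-distortion machinery.

A trait distorter of strength ``k`` biases its own transmission at meiosis
(transmission bias ``t(k)``, inherited by ``(1 + t(k))/2`` of a heterozygote's
offspring) while imposing a viability cost ``c_trait(k)`` on the individual
that carries it.  Both responses are monotone non-decreasing maps from
``[0, 1]`` to ``[0, 1]``.  This module holds those response functions, their
derivatives, and the closed-form invasion criteria they imply:

* a distorter invades a naive population iff
  ``c_trait(k) < t(k) * (1 - c_trait(k))``;
* a stronger mutant distorter (dominant) invades a resident iff
  ``dt * (1 - c_trait(k_hat)) > dc_trait``;
* the gene-level optimum ``k_target`` balances marginal transmission benefit
  against marginal individual cost, ``t'(k) (1 - c_trait(k)) = c_trait'(k)``
  (with a factor 2 on the benefit under additive gene action).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TraitResponse",
    "ConflictParams",
    "KTargetResult",
    "distorter_invades",
    "k_target",
    "mutant_invades",
]

_GRID = np.linspace(0.0, 1.0, 201)
_MONO_SLACK = 1e-12
_DIFF_STEP = 1e-6


def _power(a: float, b: float) -> Callable[[float], float]:
    # Works on scalars (fast path, no numpy boxing) and on arrays alike.
    def f(k):
        return a * k**b

    return f


def _power_deriv(a: float, b: float) -> Callable[[float], float]:
    def df(k):
        if b == 1.0:
            return a * np.ones_like(k) if isinstance(k, np.ndarray) else a
        with np.errstate(divide="ignore", invalid="ignore"):
            if not isinstance(k, np.ndarray) and k == 0.0:
                return 0.0 if b > 1.0 else np.inf
            return a * b * k ** (b - 1.0)

    return df


class TraitResponse:
    """Pair of monotone trait-response functions ``t(k)`` and ``c_trait(k)``.

    Parameters
    ----------
    transmission_bias, trait_cost
        Callables mapping strength ``k in [0, 1]`` to values in ``[0, 1]``.
        Monotonicity and range are verified on a sampled grid at construction.
    dt, dc
        Optional analytic first derivatives; central differences with step
        1e-6 are used when absent.
    """

    def __init__(
        self,
        transmission_bias: Callable[[float], float],
        trait_cost: Callable[[float], float],
        *,
        dt: Optional[Callable[[float], float]] = None,
        dc: Optional[Callable[[float], float]] = None,
    ):
        self._t = transmission_bias
        self._c = trait_cost
        self._dt = dt
        self._dc = dc
        self._validate()

    @classmethod
    def power(cls, a_t: float, b_t: float, a_c: float, b_c: float) -> "TraitResponse":
        """Power-law family ``t = a_t * k**b_t``, ``c_trait = a_c * k**b_c``.

        Covers every parameterisation used in the bundled experiments, e.g.
        ``t = 0.87 k, c_trait = 0.9 k**1.5`` and ``t = k, c_trait = k/2``.
        """
        if min(a_t, b_t, a_c, b_c) < 0:
            raise ValueError("power-law coefficients must be non-negative")
        return cls(
            _power(a_t, b_t),
            _power(a_c, b_c),
            dt=_power_deriv(a_t, b_t),
            dc=_power_deriv(a_c, b_c),
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "TraitResponse":
        """Build from a config mapping, e.g.
        ``{"t": {"family": "power", "a": 0.87, "b": 1},
        "c_trait": {"family": "power", "a": 0.9, "b": 1.5}}``.
        """
        t_cfg, c_cfg = cfg["t"], cfg["c_trait"]
        for sub in (t_cfg, c_cfg):
            if sub.get("family", "power") != "power":
                raise ValueError(f"unknown response family: {sub.get('family')!r}")
        return cls.power(t_cfg["a"], t_cfg["b"], c_cfg["a"], c_cfg["b"])

    def _validate(self) -> None:
        for name, f in (("t", self._t), ("c_trait", self._c)):
            vals = np.asarray([float(f(k)) for k in _GRID])
            if np.any(vals < -_MONO_SLACK) or np.any(vals > 1 + _MONO_SLACK):
                raise ValueError(f"{name}(k) must lie in [0, 1] on [0, 1]")
            if np.any(np.diff(vals) < -_MONO_SLACK):
                raise ValueError(f"{name}(k) must be non-decreasing on [0, 1]")

    @staticmethod
    def _check_domain(k: float) -> float:
        k = float(k)
        if not 0.0 <= k <= 1.0:
            raise ValueError(f"strength k={k} outside [0, 1]")
        return k

    def t(self, k: float) -> float:
        """Transmission bias at strength ``k``."""
        return float(self._t(self._check_domain(k)))

    def c(self, k: float) -> float:
        """Individual viability cost of distortion at strength ``k``."""
        return float(self._c(self._check_domain(k)))

    def dt(self, k: float) -> float:
        """d t / d k, analytic if available else central difference."""
        k = self._check_domain(k)
        if self._dt is not None:
            return float(self._dt(k))
        return self._central(self._t, k)

    def dc(self, k: float) -> float:
        """d c_trait / d k, analytic if available else central difference."""
        k = self._check_domain(k)
        if self._dc is not None:
            return float(self._dc(k))
        return self._central(self._c, k)

    @staticmethod
    def _central(f, k: float, h: float = _DIFF_STEP) -> float:
        lo, hi = max(0.0, k - h), min(1.0, k + h)
        return (float(f(hi)) - float(f(lo))) / (hi - lo)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TraitResponse(t(0.5)={self.t(0.5):.4g}, c(0.5)={self.c(0.5):.4g})"


@dataclass
class ConflictParams:
    """Parameters of a distorter/suppressor conflict.

    c_sup
        Individual viability cost of expressed suppression, in [0, 1].
    k, k_hat
        Resident (and optional mutant) distorter strengths, in [0, 1].
    dominance_mode
        How two distorter alleles interact within an individual:
        ``"dominant"`` (the stronger allele sets the phenotype) or
        ``"additive"`` (allele effects average).
    suppressor_mode
        ``"facultative"`` (suppressor expressed, and its cost paid, only when
        its target distorter is present) or ``"obligate"`` (constitutive).
    """

    c_sup: float
    k: float = 0.0
    k_hat: Optional[float] = None
    dominance_mode: str = "dominant"
    suppressor_mode: str = "facultative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_sup <= 1.0:
            raise ValueError("c_sup must lie in [0, 1]")
        if not 0.0 <= self.k <= 1.0:
            raise ValueError("k must lie in [0, 1]")
        if self.k_hat is not None and not 0.0 <= self.k_hat <= 1.0:
            raise ValueError("k_hat must lie in [0, 1]")
        if self.dominance_mode not in ("dominant", "additive"):
            raise ValueError(f"unknown dominance_mode {self.dominance_mode!r}")
        if self.suppressor_mode not in ("facultative", "obligate"):
            raise ValueError(f"unknown suppressor_mode {self.suppressor_mode!r}")


def distorter_invades(tr: TraitResponse, k: float) -> bool:
    """Whether a rare distorter of strength ``k`` invades a naive population.

    Strict inequality ``c_trait(k) < t(k) (1 - c_trait(k))``; the knife-edge
    equality is treated as neutral (returns False).
    """
    c = tr.c(k)
    return c < tr.t(k) * (1.0 - c)


@dataclass
class KTargetResult:
    """Root of the marginal-balance condition defining the gene-level optimum.

    ``at_boundary`` is set when the marginal net benefit is one-signed on
    [0, 1] and the optimum sits at 0 or 1 rather than at an interior root.
    """

    k: float
    at_boundary: bool = False
    n_roots: int = field(default=1, repr=False)

    def __float__(self) -> float:
        return self.k


def k_target(
    tr: TraitResponse,
    dominance_mode: str = "dominant",
    *,
    tol: float = 1e-10,
    scan_points: int = 400,
) -> KTargetResult:
    """Distorter strength at which marginal transmission benefit balances
    marginal individual cost.

    Dominant mode solves ``t'(k) (1 - c_trait(k)) = c_trait'(k)``; additive
    mode solves ``2 t'(k) (1 - c_trait(k)) = c_trait'(k)``.  Bracketed
    root-finding (Brent) to absolute tolerance ``tol``; when the balance
    function is one-signed the boundary (1 for positive, 0 for negative) is
    returned with ``at_boundary=True``.  With multiple interior roots the
    smallest is returned and a warning issued.
    """
    if dominance_mode not in ("dominant", "additive"):
        raise ValueError(f"unknown dominance_mode {dominance_mode!r}")
    mult = 2.0 if dominance_mode == "additive" else 1.0

    def g(k: float) -> float:
        return mult * tr.dt(k) * (1.0 - tr.c(k)) - tr.dc(k)

    # Scan away from 0 where power-law derivatives with exponent < 1 diverge.
    ks = np.linspace(1e-9, 1.0, scan_points)
    gs = np.asarray([g(k) for k in ks])
    gs = np.where(np.isfinite(gs), gs, np.sign(gs) * 1e300)
    sign_changes = np.nonzero(np.diff(np.sign(gs)) != 0)[0]

    if len(sign_changes) == 0:
        if np.all(gs <= 0):
            return KTargetResult(0.0, at_boundary=True, n_roots=0)
        return KTargetResult(1.0, at_boundary=True, n_roots=0)
    if len(sign_changes) > 1:
        warnings.warn(
            f"marginal-balance condition has {len(sign_changes)} roots; "
            "returning the smallest",
            stacklevel=2,
        )
    i = sign_changes[0]
    root = float(brentq(g, ks[i], ks[i + 1], xtol=tol))
    # A root sitting on the domain edge is a boundary optimum (the balance
    # condition only just closes at the admissible extreme).
    if root <= 1e-9 or root >= 1.0 - 1e-9:
        return KTargetResult(round(root), at_boundary=True, n_roots=len(sign_changes))
    return KTargetResult(root, at_boundary=False, n_roots=len(sign_changes))


def mutant_invades(
    tr: TraitResponse,
    k: float,
    k_hat: float,
    dominance_mode: str = "dominant",
) -> bool:
    """Whether a rare mutant distorter of strength ``k_hat`` invades a
    population fixed for an unsuppressed resident of strength ``k``.

    Dominant mode: weaker mutants (``k_hat < k``) are recessive in the
    resident heterozygote and can never invade; stronger mutants invade iff
    ``dt (1 - c_trait(k_hat)) > dc_trait``.  Additive mode uses the single
    criterion ``dt (2 - c_trait(k) - c_trait(k_hat)) > dc_trait`` in either
    direction.  Strict inequalities; equality is neutral (False).
    """
    k = TraitResponse._check_domain(k)
    k_hat = TraitResponse._check_domain(k_hat)
    if k == k_hat:
        raise ValueError("k_hat must differ from resident k (not a mutant)")
    dt = tr.t(k_hat) - tr.t(k)
    dc = tr.c(k_hat) - tr.c(k)
    if dominance_mode == "dominant":
        if k_hat < k:
            return False
        return dt * (1.0 - tr.c(k_hat)) > dc
    if dominance_mode == "additive":
        return dt * (2.0 - tr.c(k) - tr.c(k_hat)) > dc
    raise ValueError(f"unknown dominance_mode {dominance_mode!r}")
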