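"""Long-term genome-wide conflict dynamics with deterministic introductions.

A genome of ``gamma`` loci is split into a cabal (fraction ``theta`` of loci,
which share the distorter's transmission interest) and a commonwealth (the
remaining ``1 - theta``, selected to suppress).  A distorter of strength
``k`` arises at a new cabal locus every ``1/(theta * gamma * rho_D1)``
generations and its dedicated suppressor follows after a lag of
``1/((1 - theta) * gamma * rho_S1)`` generations.  Each introduction cycle is
solved exactly with the deterministic recursions; under a separation of
timescales (equilibration fast relative to introduction) the evolutionary-
time average distortion collapses to the closed form

    k * theta * rho_D1 / ((1 - theta) * rho_S1)

for distorters in the suppressed regime (``c_sup < c_trait(k)``); below the
suppression threshold the average is simply ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .recursions import (
    introduce_suppressor,
    mean_distortion,
    step_single_locus,
    step_two_locus,
)
from .trait_response import ConflictParams, TraitResponse

__all__ = [
    "GenomeArchitecture",
    "CycleResult",
    "average_distortion_approx",
    "cycle_exact",
    "distortion_k_theta_surface",
]


@dataclass
class GenomeArchitecture:
    """Genome partition and per-locus introduction rates.

    gamma
        Number of loci in the genome (positive).
    theta
        Proportional cabal size, in (0, 0.5]: the cabal can never be the
        majority, else it would be the individual interest.
    rho_D1, rho_S1
        Per-locus, per-generation probabilities of a new distorter (cabal
        locus) and a new dedicated suppressor (commonwealth locus).
    rho
        Baseline mutation-rate scalar multiplying both introduction
        probabilities; it cancels from every long-run average.
    """

    gamma: float
    theta: float
    rho_D1: float
    rho_S1: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 0.0 < self.theta <= 0.5:
            raise ValueError("theta must lie in (0, 0.5]")
        for name in ("rho_D1", "rho_S1"):
            r = getattr(self, name) * self.rho
            if not 0.0 < r < 1.0:
                raise ValueError(f"effective {name} must lie in (0, 1)")
        if not np.isfinite(self.distorter_interval) or not np.isfinite(
            self.suppressor_lag
        ):
            raise ValueError("introduction interval and lag must be finite")

    @property
    def distorter_interval(self) -> float:
        """Generations between distorter introductions, 1/(theta gamma rho_D1)."""
        return 1.0 / (self.theta * self.gamma * self.rho * self.rho_D1)

    @property
    def suppressor_lag(self) -> float:
        """Generations from a distorter's arrival to its dedicated
        suppressor's, 1/((1 - theta) gamma rho_S1)."""
        return 1.0 / ((1.0 - self.theta) * self.gamma * self.rho * self.rho_S1)


def average_distortion_approx(
    genome: GenomeArchitecture, tr: TraitResponse, c_sup: float, k: float
) -> float:
    """Separation-of-timescales average trait distortion.

    Piecewise: ``k`` when the suppressor cannot invade (``c_sup >=
    c_trait(k)``, the distorter simply fixes), else
    ``k * theta * rho_D1 / ((1 - theta) * rho_S1)``.  Genome size and the
    baseline rate scalar cancel.
    """
    if tr.c(k) <= c_sup:
        return float(k)
    return float(
        k * genome.theta * genome.rho_D1 / ((1.0 - genome.theta) * genome.rho_S1)
    )


@dataclass
class CycleResult:
    """Exact numerical solution of one distorter introduction cycle."""

    lag_generations: int
    purge_generation: int  # X: total generations the distorter segregates
    distortion: np.ndarray = field(repr=False)  # per generation, T = 1..X
    cycle_average: float = 0.0  # mean over T = 1..X
    evolutionary_average: float = 0.0  # weighted by segregating-time fraction
    peak: float = 0.0
    trough: float = 0.0
    segregating_fraction: float = 0.0  # X * theta * gamma * rho * rho_D1
    co_segregation_warning: bool = False
    truncated_tail: bool = False


def cycle_exact(
    genome: GenomeArchitecture,
    tr: TraitResponse,
    params: ConflictParams,
    k: Optional[float] = None,
    *,
    p0: float = 1e-6,
    eps_sup: float = 1e-3,
    purge_tol: float = 1e-9,
    dist_tol: float = 1e-9,
    max_purge_gen: int = 5_000_000,
) -> CycleResult:
    """Run one deterministic introduction cycle exactly.

    Phase 1: the distorter spreads alone (single-locus recursion) for the
    suppressor lag, rounded to the nearest whole generation (>= 1).  Phase 2:
    the dedicated suppressor enters at total frequency ``eps_sup`` and the
    two-locus recursions run until the distorter is purged (combined D1
    gamete frequency < ``purge_tol``) at generation ``X``.

    The evolutionary-time average weights the within-cycle mean distortion by
    the fraction of evolutionary time in which a distorter segregates,
    ``X * theta * gamma * rho * rho_D1``; a warning flag is set when that
    fraction exceeds 1 (distorters would co-segregate, violating the model's
    one-at-a-time assumption).

    After a long unsuppressed phase the wild-type D0 frequency falls below
    float64 resolution, so the literal allele-loss criterion can become
    unreachable (the suppressed background then decays only algebraically);
    the cycle is therefore also terminated once the expressed mean
    distortion falls below ``dist_tol`` (``truncated_tail=True`` when the
    distorter gametes are still above ``purge_tol`` at that point).  The
    omitted tail carries distortion below ``dist_tol`` per generation, so
    the peak, trough and evolutionary-time average are unaffected.
    """
    k = params.k if k is None else k
    if tr.c(k) <= params.c_sup:
        raise ValueError(
            "suppressor cannot invade (c_sup >= c_trait(k)); the cycle never "
            "closes — the average distortion is k in this regime"
        )
    lag = max(1, round(genome.suppressor_lag))
    t, c, s = tr.t(k), tr.c(k), params.c_sup
    dist = np.empty(lag, dtype=float)
    p = p0
    # Inlined single-locus recursion (hot loop; identical to
    # step_single_locus with t, c hoisted).
    for i in range(lag):
        w_bar = (1.0 - c) * (p * p + 2.0 * p * (1.0 - p)) + (1.0 - p) ** 2
        p = (1.0 - c) * (p * p + (1.0 - p) * p * (t + 1.0)) / w_bar
        dist[i] = k * (1.0 - (1.0 - p) ** 2)
    phase2 = []
    if params.k != k:
        params = ConflictParams(
            c_sup=params.c_sup, k=k, suppressor_mode=params.suppressor_mode
        )
    obligate = params.suppressor_mode == "obligate"
    x = introduce_suppressor(p, eps_sup)
    x00, x01, x10, x11 = x
    h = (1.0 - s) / 2.0
    gen = 0
    truncated = False
    while x10 + x11 >= purge_tol:
        if obligate:
            x00, x01, x10, x11 = step_two_locus(
                np.array([x00, x01, x10, x11]), tr, params
            )
        else:
            # Inlined two-locus polynomials (identical to step_two_locus).
            r00 = (x00 * x00 + x00 * x01 + (1.0 - t) * (1.0 - c) * x00 * x10
                   + h * x00 * x11 + h * x01 * x10)
            r01 = (x00 * x01 + h * x00 * x11 + x01 * x01 + h * x01 * x10
                   + (1.0 - s) * x01 * x11)
            r10 = ((1.0 + t) * (1.0 - c) * x00 * x10 + h * x00 * x11
                   + h * x01 * x10 + (1.0 - c) * x10 * x10
                   + (1.0 - s) * x10 * x11)
            r11 = (h * x00 * x11 + h * x01 * x10 + (1.0 - s) * x01 * x11
                   + (1.0 - s) * x10 * x11 + (1.0 - s) * x11 * x11)
            w_bar = r00 + r01 + r10 + r11
            x00, x01, x10, x11 = r00 / w_bar, r01 / w_bar, r10 / w_bar, r11 / w_bar
        s0 = x00 + x10
        d = k * (s0 * s0 - x00 * x00)
        phase2.append(d)
        if d < dist_tol:
            truncated = (x10 + x11) >= purge_tol
            break
        gen += 1
        if gen >= max_purge_gen:
            raise RuntimeError("distorter not purged within max_purge_gen")
    series = np.concatenate([dist, np.asarray(phase2)])
    x_total = series.size
    seg_frac = x_total * genome.theta * genome.gamma * genome.rho * genome.rho_D1
    warned = seg_frac > 1.0
    if warned:
        warnings.warn(
            "introduction interval shorter than the purge time "
            f"(X * theta * gamma * rho_D1 = {seg_frac:.3g} > 1): distorters "
            "would co-segregate; the one-at-a-time average is an extrapolation",
            stacklevel=2,
        )
    cycle_avg = float(series.mean())
    return CycleResult(
        lag_generations=lag,
        purge_generation=x_total,
        distortion=series,
        cycle_average=cycle_avg,
        evolutionary_average=cycle_avg * seg_frac,
        peak=float(series.max()),
        trough=0.0 if seg_frac < 1.0 else float(series.min()),
        segregating_fraction=float(seg_frac),
        co_segregation_warning=warned,
        truncated_tail=truncated,
    )


def distortion_k_theta_surface(
    ks: Sequence[float],
    thetas: Sequence[float],
    genome_template: GenomeArchitecture,
    tr: TraitResponse,
    c_sup: float,
    *,
    method: str = "exact",
) -> pd.DataFrame:
    """Average trait distortion over a (k, theta) grid, as a tidy table.

    ``method="exact"`` runs :func:`cycle_exact` per suppressed-regime point;
    ``method="approx"`` uses the closed form.  Points below the suppression
    threshold (``c_sup >= c_trait(k)``) take the value ``k`` either way.
    """
    if method not in ("exact", "approx"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for theta in thetas:
        genome = GenomeArchitecture(
            gamma=genome_template.gamma,
            theta=float(theta),
            rho_D1=genome_template.rho_D1,
            rho_S1=genome_template.rho_S1,
            rho=genome_template.rho,
        )
        for k in ks:
            k = float(k)
            if tr.c(k) <= c_sup:
                avg, regime = k, "unsuppressed"
            elif method == "approx":
                avg = average_distortion_approx(genome, tr, c_sup, k)
                regime = "suppressed"
            else:
                params = ConflictParams(c_sup=c_sup, k=k)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    avg = cycle_exact(genome, tr, params, k).evolutionary_average
                regime = "suppressed"
            rows.append(
                {
                    "k": k,
                    "theta": float(theta),
                    "average_distortion": float(avg),
                    "regime": regime,
                }
            )
    return pd.DataFrame(rows)
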