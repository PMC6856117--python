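"""Deterministic gamete-frequency recursions and their stability analysis.

An unlinked autosomal suppressor locus (alleles S0/S1) segregates alongside a
distorter locus (D0/D1, optionally a mutant D2) in an infinite, randomly
mating diploid population.  The state is the vector of gamete frequencies —
four classes ``(x00, x01, x10, x11)`` for D0/S0, D0/S1, D1/S0, D1/S1, six
classes with a mutant distorter — advanced one non-overlapping generation at
a time and normalised by the population mean fitness (the sum of the
right-hand sides).

The facultative-suppressor steppers are transcriptions of the published
recursions; the obligate-suppressor and additive-gene-action variants are
produced by a general mating-table engine (random union of gametes, genotype
viability weights, drive-biased meiosis) that reduces to the same
polynomials in the facultative dominant case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np

from .trait_response import ConflictParams, TraitResponse, mutant_invades

__all__ = [
    "DegeneratePopulationError",
    "NeverPurgedError",
    "Trajectory",
    "step_single_locus",
    "step_two_locus",
    "step_three_allele",
    "mating_table_step",
    "suppressor_jacobian",
    "leading_eigenvalue",
    "iterate_to_equilibrium",
    "introduce_suppressor",
    "mean_distortion",
    "time_to_purge",
    "numeric_jacobian",
    "mutant_block_eigenvalue",
    "adaptive_walk",
    "GENERATION_CAP",
]

#: Hard cap on deterministic iteration length (generations).
GENERATION_CAP = 20_000_000

_NEG_TOL = -1e-15


class DegeneratePopulationError(ValueError):
    """Mean fitness is non-positive; the population is extinct."""


class NeverPurgedError(ValueError):
    """The suppressor cannot invade (c_trait(k) <= c_sup), so the distorter
    is never purged."""


def _normalise(r: np.ndarray) -> np.ndarray:
    w = r.sum()
    if w <= 0.0 or not np.isfinite(w):
        raise DegeneratePopulationError(f"mean fitness w_bar={w}")
    x = r / w
    if np.any(x < _NEG_TOL):
        raise DegeneratePopulationError("negative gamete frequency")
    np.clip(x, 0.0, None, out=x)
    return x


def step_single_locus(p: float, tr: TraitResponse, k: float) -> float:
    """One generation of the single-locus distorter recursion.

    ``w_bar p' = (1 - c_trait(k)) (p^2 + (1 - p) p (t(k) + 1))`` with
    ``w_bar = (1 - c_trait(k)) (p^2 + 2 p (1 - p)) + (1 - p)^2``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency p={p} outside [0, 1]")
    t, c = tr.t(k), tr.c(k)
    w_bar = (1.0 - c) * (p * p + 2.0 * p * (1.0 - p)) + (1.0 - p) ** 2
    if w_bar <= 0.0:
        raise DegeneratePopulationError(f"mean fitness w_bar={w_bar}")
    return (1.0 - c) * (p * p + (1.0 - p) * p * (t + 1.0)) / w_bar


def _two_locus_rhs(x, t: float, c: float, s: float, obligate: bool = False):
    # Obligate (constitutive) suppression differs from facultative only in
    # the genotypes that carry S1 but no distorter — the D0S0 x D0S1 and
    # D0S1 x D0S1 matings — which then pay the (1 - c_sup) factor too.
    # Every genotype containing a distorter expresses a present suppressor
    # in both modes, so all other terms coincide.
    g = (1.0 - s) if obligate else 1.0
    x00, x01, x10, x11 = (float(v) for v in x)
    h = (1.0 - s) / 2.0
    r00 = (
        x00 * x00
        + g * x00 * x01
        + (1.0 - t) * (1.0 - c) * x00 * x10
        + h * x00 * x11
        + h * x01 * x10
    )
    r01 = (
        g * x00 * x01
        + h * x00 * x11
        + g * x01 * x01
        + h * x01 * x10
        + (1.0 - s) * x01 * x11
    )
    r10 = (
        (1.0 + t) * (1.0 - c) * x00 * x10
        + h * x00 * x11
        + h * x01 * x10
        + (1.0 - c) * x10 * x10
        + (1.0 - s) * x10 * x11
    )
    r11 = (
        h * x00 * x11
        + h * x01 * x10
        + (1.0 - s) * x01 * x11
        + (1.0 - s) * x10 * x11
        + (1.0 - s) * x11 * x11
    )
    return (r00, r01, r10, r11)


def step_two_locus(
    x: Sequence[float], tr: TraitResponse, params: ConflictParams
) -> np.ndarray:
    """One generation of the distorter + suppressor recursions over the four
    gamete classes (D0/S0, D0/S1, D1/S0, D1/S1).

    Facultative mode uses the published polynomials; obligate mode (the
    suppressor constitutively expressed, paying c_sup whenever S1 is
    present) modifies the two distorter-free S1-carrying terms accordingly.
    """
    if len(x) != 4:
        raise ValueError("state must have 4 gamete classes")
    t, c = tr.t(params.k), tr.c(params.k)
    r = _two_locus_rhs(
        x, t, c, params.c_sup, obligate=params.suppressor_mode == "obligate"
    )
    w = r[0] + r[1] + r[2] + r[3]
    if w <= 0.0 or not np.isfinite(w):
        raise DegeneratePopulationError(f"mean fitness w_bar={w}")
    out = np.array([r[0] / w, r[1] / w, r[2] / w, r[3] / w])
    if out[0] < _NEG_TOL or out[1] < _NEG_TOL or out[2] < _NEG_TOL or out[3] < _NEG_TOL:
        raise DegeneratePopulationError("negative gamete frequency")
    return out


def step_three_allele(
    x: Sequence[float], tr: TraitResponse, params: ConflictParams
) -> np.ndarray:
    """One generation of the resident + mutant distorter + suppressor
    recursions over the six gamete classes (D0/S0 ... D2/S1).

    Dominant mode (the stronger of two distorter alleles sets phenotype and
    heterozygote cost uses max(k, k_hat)), transcribed from the published
    six-gamete system.
    """
    if len(x) != 6:
        raise ValueError("state must have 6 gamete classes")
    if params.k_hat is None:
        raise ValueError("params.k_hat is required for the three-allele step")
    if params.dominance_mode != "dominant":
        raise ValueError(
            "verbatim three-allele step is dominant-mode; use "
            "mating_table_step for additive gene action"
        )
    k, kh, s = params.k, params.k_hat, params.c_sup
    t1, t2 = tr.t(k), tr.t(kh)
    c1, c2 = tr.c(k), tr.c(kh)
    cm = tr.c(max(k, kh))
    x00, x01, x10, x11, x20, x21 = (float(v) for v in x)
    h = (1.0 - s) / 2.0
    r00 = (
        x00 * x00
        + x00 * x01
        + (1.0 - t1) * (1.0 - c1) * x00 * x10
        + h * x00 * x11
        + (1.0 - t2) * (1.0 - c2) * x00 * x20
        + h * x00 * x21
        + h * x01 * x10
        + h * x01 * x20
    )
    r01 = (
        x00 * x01
        + h * x00 * x11
        + h * x00 * x21
        + x01 * x01
        + h * x01 * x10
        + (1.0 - s) * x01 * x11
        + h * x01 * x20
        + (1.0 - s) * x01 * x21
    )
    r10 = (
        (1.0 + t1) * (1.0 - c1) * x00 * x10
        + h * x00 * x11
        + h * x01 * x10
        + (1.0 - c1) * x10 * x10
        + (1.0 - s) * x10 * x11
        + (1.0 + t1 - t2) * (1.0 - cm) * x10 * x20
        + h * x10 * x21
        + h * x11 * x20
    )
    r11 = (
        h * x00 * x11
        + h * x01 * x10
        + (1.0 - s) * x01 * x11
        + (1.0 - s) * x10 * x11
        + h * x10 * x21
        + (1.0 - s) * x11 * x11
        + h * x11 * x20
        + (1.0 - s) * x11 * x21
    )
    r20 = (
        (1.0 + t2) * (1.0 - c2) * x00 * x20
        + h * x00 * x21
        + h * x01 * x20
        + (1.0 - t1 + t2) * (1.0 - cm) * x10 * x20
        + h * x10 * x21
        + h * x11 * x20
        + (1.0 - c2) * x20 * x20
        + (1.0 - s) * x20 * x21
    )
    r21 = (
        h * x00 * x21
        + h * x01 * x20
        + (1.0 - s) * x01 * x21
        + h * x10 * x21
        + h * x11 * x20
        + (1.0 - s) * x11 * x21
        + (1.0 - s) * x20 * x21
        + (1.0 - s) * x21 * x21
    )
    w = r00 + r01 + r10 + r11 + r20 + r21
    if w <= 0.0 or not np.isfinite(w):
        raise DegeneratePopulationError(f"mean fitness w_bar={w}")
    out = np.array([r00, r01, r10, r11, r20, r21]) / w
    if np.any(out < _NEG_TOL):
        raise DegeneratePopulationError("negative gamete frequency")
    return out


# ---------------------------------------------------------------------------
# General mating-table engine (multiallele distorter locus x suppressor locus)
# ---------------------------------------------------------------------------


def _genotype_rules(
    ki: float,
    kj: float,
    s_present: bool,
    tr: TraitResponse,
    c_sup: float,
    dominance_mode: str,
    suppressor_mode: str,
):
    """Viability and distorter-transmission probability for one genotype.

    Returns ``(w, p_i)`` where ``p_i`` is the probability that allele ``i``
    (strength ``ki``) is transmitted at the distorter locus.
    """
    d_present = (ki > 0.0) or (kj > 0.0)
    if suppressor_mode == "facultative":
        suppressed = s_present and d_present
        pays_sup = suppressed
    else:  # obligate: constitutive expression and cost
        suppressed = s_present
        pays_sup = s_present
    w = 1.0
    if pays_sup:
        w *= 1.0 - c_sup
    if d_present and not suppressed:
        if dominance_mode == "dominant":
            w *= 1.0 - tr.c(max(ki, kj))
        else:
            w *= 1.0 - 0.5 * (tr.c(ki) + tr.c(kj))
    if suppressed or ki == kj:
        p_i = 0.5
    else:
        p_i = (1.0 + tr.t(ki) - tr.t(kj)) / 2.0
    return w, p_i


def mating_table_step(
    x: Sequence[float],
    alleles_k: Sequence[float],
    tr: TraitResponse,
    params: ConflictParams,
    *,
    dominance_mode: Optional[str] = None,
    suppressor_mode: Optional[str] = None,
) -> np.ndarray:
    """One generation by explicit enumeration of ordered gamete pairings.

    ``alleles_k`` lists the distorter-locus allele strengths in gamete-class
    order (e.g. ``[0, k]`` or ``[0, k, k_hat]``); gamete ``(a, s)`` has index
    ``2 * a + s``.  Random union of gametes, genotype viability weighting,
    drive-biased meiosis at the distorter locus, Mendelian segregation at the
    unlinked suppressor locus.
    """
    dominance_mode = dominance_mode or params.dominance_mode
    suppressor_mode = suppressor_mode or params.suppressor_mode
    x = np.asarray(x, dtype=float)
    n_a = len(alleles_k)
    if x.shape != (2 * n_a,):
        raise ValueError("state length must be 2 * number of distorter alleles")
    r = np.zeros_like(x)
    for g1 in range(2 * n_a):
        a1, s1 = divmod(g1, 2)
        for g2 in range(2 * n_a):
            a2, s2 = divmod(g2, 2)
            freq = x[g1] * x[g2]
            if freq == 0.0:
                continue
            w, p1 = _genotype_rules(
                alleles_k[a1],
                alleles_k[a2],
                bool(s1 or s2),
                tr,
                params.c_sup,
                dominance_mode,
                suppressor_mode,
            )
            p_s1 = 0.5 * (s1 + s2)
            for a_out, p_a in ((a1, p1), (a2, 1.0 - p1)):
                for s_out, p_s in ((1, p_s1), (0, 1.0 - p_s1)):
                    r[2 * a_out + s_out] += freq * w * p_a * p_s
    return _normalise(r)


# ---------------------------------------------------------------------------
# Stability analysis
# ---------------------------------------------------------------------------


def suppressor_jacobian(tr: TraitResponse, params: ConflictParams) -> np.ndarray:
    """Jacobian of the two-locus map at the unsuppressed-distorter fixation
    equilibrium (x00, x01, x10, x11) = (0, 0, 1, 0).

    Its leading eigenvalue is ``(1 - c_sup)/(1 - c_trait(k))``, so a rare
    facultative suppressor invades iff ``c_trait(k) > c_sup``.
    """
    if params.suppressor_mode != "facultative":
        raise ValueError("closed-form Jacobian applies to facultative mode")
    t, c, s = tr.t(params.k), tr.c(params.k), params.c_sup
    if c >= 1.0:
        raise ZeroDivisionError("c_trait = 1 makes the equilibrium degenerate")
    a = (1.0 - s) / (1.0 - c)
    return np.array(
        [
            [1.0 - t, a / 2.0, 0.0, 0.0],
            [0.0, a / 2.0, 0.0, 0.0],
            [t - 1.0, -3.0 * a / 2.0, 0.0, -a],
            [0.0, a / 2.0, 0.0, a],
        ]
    )


def leading_eigenvalue(matrix: np.ndarray) -> float:
    """Largest eigenvalue modulus (complex pairs compared by modulus)."""
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


def numeric_jacobian(
    step: Callable[[np.ndarray], np.ndarray], x_star: np.ndarray, h: float = 1e-7
) -> np.ndarray:
    """Forward-difference Jacobian of a normalised stepper at a fixed point.

    Forward (not central) differences keep the perturbed states inside the
    simplex when the fixed point sits on its boundary, as every invasion
    equilibrium does.
    """
    x_star = np.asarray(x_star, dtype=float)
    base = np.asarray(step(x_star))
    n = x_star.size
    jac = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        up = np.asarray(step(x_star + e))
        jac[:, j] = (up - base) / h
    return jac


def mutant_block_eigenvalue(
    tr: TraitResponse, params: ConflictParams, *, h: float = 1e-7
) -> float:
    """Invasion growth factor of a rare mutant distorter against a fixed
    unsuppressed resident, from the numeric Jacobian of the six-gamete map.

    At the equilibrium (0, 0, 1, 0, 0, 0) the perturbation dynamics of the
    mutant classes (x20, x21) close on themselves, so their 2x2 Jacobian
    block alone decides invasion (leading eigenvalue > 1).
    """
    x_star = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    if params.dominance_mode == "dominant":
        step = lambda x: step_three_allele(x, tr, params)  # noqa: E731
    else:
        alleles = [0.0, params.k, params.k_hat]
        step = lambda x: mating_table_step(x, alleles, tr, params)  # noqa: E731
    jac = numeric_jacobian(step, x_star, h=h)
    block = jac[np.ix_([4, 5], [4, 5])]
    return leading_eigenvalue(block)


# ---------------------------------------------------------------------------
# Iteration, trajectories, purge times
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Recorded per-generation states and individual-level mean distortion."""

    generations: np.ndarray
    states: np.ndarray
    mean_distortion: np.ndarray

    def to_frame(self):
        import pandas as pd

        n_classes = self.states.shape[1]
        cols = (
            ["x00", "x01", "x10", "x11"]
            if n_classes == 4
            else ["x00", "x01", "x10", "x11", "x20", "x21"]
        )
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "generation", self.generations)
        df["mean_distortion"] = self.mean_distortion
        return df


@dataclass
class EquilibriumResult:
    state: np.ndarray
    generations: int
    converged: bool
    trajectory: Optional[Trajectory] = field(default=None, repr=False)


def mean_distortion(x: Sequence[float], k: float) -> float:
    """Population mean individual trait distortion under random gamete union.

    An individual expresses distortion ``k`` iff it carries at least one
    distorter allele and no (dominant) suppressor allele; with gamete
    frequencies ``x`` that has probability ``(x00 + x10)^2 - x00^2``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape == (4,):
        s0 = x[0] + x[2]
        return k * (s0 * s0 - x[0] * x[0])
    if x.shape == (6,):
        # Strength expressed is that of the stronger distorter allele; report
        # the k-weighted carrier decomposition is not needed for 4-class plots,
        # so fall back to the probability-weighted mean with per-allele k set
        # by the caller via mean_distortion_six.
        raise ValueError("use mean_distortion_six for six-class states")
    raise ValueError("state must have 4 gamete classes")


def mean_distortion_six(x: Sequence[float], k: float, k_hat: float) -> float:
    """Mean distortion for the six-class state (stronger allele dominant)."""
    x = np.asarray(x, dtype=float)
    s0 = x[0] + x[2] + x[4]  # suppressor-free gametes
    if s0 == 0.0:
        return 0.0
    # Unsuppressed individuals: both gametes S0.  Expressed strength is that
    # of the stronger distorter allele carried.
    k_hi, k_lo = (k_hat, k) if k_hat >= k else (k, k_hat)
    x_hi, x_lo = (x[4], x[2]) if k_hat >= k else (x[2], x[4])
    p_hi = s0 * s0 - (s0 - x_hi) ** 2  # >= 1 strong allele, no suppressor
    p_lo = (x[0] + x_lo) ** 2 - x[0] ** 2  # no strong, >= 1 weak, no suppressor
    return k_hi * p_hi + k_lo * p_lo


def iterate_to_equilibrium(
    x0: Sequence[float],
    stepper: Callable[[np.ndarray], np.ndarray],
    *,
    tol: float = 1e-12,
    max_gen: int = 1_000_000,
    k: Optional[float] = None,
    record: bool = False,
) -> EquilibriumResult:
    """Iterate a stepper until the max per-class change drops below ``tol``
    or ``max_gen`` is reached, reporting which.

    When ``k`` is given and the state has 4 classes, the per-generation mean
    individual distortion is recorded alongside the states (if ``record``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    x = np.asarray(x0, dtype=float).copy()
    states: List[np.ndarray] = []
    dists: List[float] = []
    converged = False
    gen = 0
    for gen in range(1, max_gen + 1):
        x_new = np.asarray(stepper(x))
        if record:
            states.append(x_new.copy())
            if k is not None and x_new.shape == (4,):
                dists.append(mean_distortion(x_new, k))
        if x_new.shape == x.shape:
            delta = max(abs(a - b) for a, b in zip(x_new.tolist(), x.tolist()))
        else:
            delta = np.inf
        x = x_new
        if delta < tol:
            converged = True
            break
    traj = None
    if record:
        arr = np.asarray(states)
        traj = Trajectory(
            generations=np.arange(1, len(states) + 1),
            states=arr,
            mean_distortion=np.asarray(dists) if dists else np.full(len(states), np.nan),
        )
    return EquilibriumResult(x, gen, converged, traj)


def introduce_suppressor(
    p: float, eps: float = 1e-3, *, split: str = "proportional"
) -> np.ndarray:
    """Four-class state for a suppressor introduced at total frequency
    ``eps`` into a population with distorter frequency ``p``.

    ``split="proportional"`` places the S1 gametes on D0/D1 backgrounds in
    proportion to their frequencies; ``split="equal"`` puts ``eps/2`` on
    each background (requires both backgrounds at frequency >= eps/2).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p outside [0, 1]")
    if not 0.0 < eps < 1.0:
        raise ValueError("eps outside (0, 1)")
    if split == "proportional":
        return np.array(
            [(1.0 - p) * (1.0 - eps), (1.0 - p) * eps, p * (1.0 - eps), p * eps]
        )
    if split == "equal":
        half = eps / 2.0
        if (1.0 - p) < half or p < half:
            raise ValueError("equal split needs both backgrounds >= eps/2")
        return np.array([1.0 - p - half, half, p - half, half])
    raise ValueError(f"unknown split {split!r}")


@dataclass
class PurgeResult:
    generations: int
    capped: bool
    invasion_generations: int = 0

    def __int__(self) -> int:
        return self.generations


def time_to_purge(
    tr: TraitResponse,
    params: ConflictParams,
    *,
    intro_scheme: str = "simultaneous",
    p0: float = 1e-6,
    f: float = 0.99,
    eps_sup: float = 1e-3,
    purge_tol: float = 1e-9,
    cap: int = GENERATION_CAP,
) -> PurgeResult:
    """Generations from distorter introduction (frequency ``p0``) to its loss
    (combined D1 gamete frequency below ``purge_tol``).

    ``intro_scheme="simultaneous"`` (the non-equilibrium experiment)
    introduces the distorter at ``p0`` and the suppressor at ``eps_sup``
    together and runs the two-locus recursions throughout; distorters too
    weak to invade are then simply flushed out by selection.
    ``intro_scheme="at_frequency"`` lets the distorter spread alone until it
    reaches frequency ``f`` before the suppressor enters (the equilibrium
    experiment's schedule); it requires an invading distorter.

    Honours a hard cap of twenty million generations (``capped=True`` when
    hit).  Raises :class:`NeverPurgedError` when ``c_trait(k) <= c_sup``
    (the suppressor cannot invade, so an invading distorter persists).
    """
    k = params.k
    if tr.c(k) <= params.c_sup:
        raise NeverPurgedError(
            f"c_trait({k}) = {tr.c(k):.4g} <= c_sup = {params.c_sup}; "
            "suppressor cannot invade"
        )
    if intro_scheme not in ("simultaneous", "at_frequency"):
        raise ValueError(f"unknown intro_scheme {intro_scheme!r}")
    t, c, s = tr.t(k), tr.c(k), params.c_sup
    obligate = params.suppressor_mode == "obligate"
    g = (1.0 - s) if obligate else 1.0
    h = (1.0 - s) / 2.0
    gen = 0
    invasion_gen = 0
    if intro_scheme == "at_frequency":
        from .trait_response import distorter_invades

        if not distorter_invades(tr, k):
            raise ValueError("distorter cannot invade; it never reaches frequency f")
        p = p0
        # Inlined recursions (hot loop, capped at 2e7 generations):
        # identical arithmetic to step_single_locus / step_two_locus.
        while p < f:
            w_bar = (1.0 - c) * (p * p + 2.0 * p * (1.0 - p)) + (1.0 - p) ** 2
            p = (1.0 - c) * (p * p + (1.0 - p) * p * (t + 1.0)) / w_bar
            gen += 1
            if gen >= cap:
                return PurgeResult(gen, capped=True, invasion_generations=gen)
        invasion_gen = gen
        x00, x01, x10, x11 = introduce_suppressor(p, eps_sup)
    else:
        x00, x01, x10, x11 = (
            (1.0 - p0) * (1.0 - eps_sup),
            (1.0 - p0) * eps_sup,
            p0 * (1.0 - eps_sup),
            p0 * eps_sup,
        )
    while x10 + x11 >= purge_tol:
        r00 = (x00 * x00 + g * x00 * x01 + (1.0 - t) * (1.0 - c) * x00 * x10
               + h * x00 * x11 + h * x01 * x10)
        r01 = (g * x00 * x01 + h * x00 * x11 + g * x01 * x01 + h * x01 * x10
               + (1.0 - s) * x01 * x11)
        r10 = ((1.0 + t) * (1.0 - c) * x00 * x10 + h * x00 * x11
               + h * x01 * x10 + (1.0 - c) * x10 * x10 + (1.0 - s) * x10 * x11)
        r11 = (h * x00 * x11 + h * x01 * x10 + (1.0 - s) * x01 * x11
               + (1.0 - s) * x10 * x11 + (1.0 - s) * x11 * x11)
        w_bar = r00 + r01 + r10 + r11
        x00, x01, x10, x11 = r00 / w_bar, r01 / w_bar, r10 / w_bar, r11 / w_bar
        gen += 1
        if gen >= cap:
            return PurgeResult(gen, capped=True, invasion_generations=invasion_gen)
    return PurgeResult(gen, capped=False, invasion_generations=invasion_gen)


def adaptive_walk(
    tr: TraitResponse,
    params: ConflictParams,
    delta: float,
    n_steps: int,
    *,
    k0: float = 0.0,
) -> np.ndarray:
    """Sequence of resident distorter strengths under delta-weak selection.

    Repeatedly proposes a stronger mutant ``k_hat = k + delta`` (dominant
    mode: weaker mutants are recessive and never invade) and replaces the
    resident whenever the mutant invades; stops at the first rejection, at
    the strength ceiling 1, or after ``n_steps`` proposals.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ks = [float(k0)]
    for _ in range(n_steps):
        k = ks[-1]
        k_hat = min(k + delta, 1.0)
        if k_hat <= k:
            break
        if mutant_invades(tr, k, k_hat, params.dominance_mode):
            ks.append(k_hat)
        else:
            break
    return np.asarray(ks)
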