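"""Stochastic agent-based simulations of distorter/suppressor coevolution.

Three forward-time Wright-Fisher-style engines over a population of ``N``
hermaphroditic diploids with non-overlapping generations, fitness-
proportional sampling of breeding pairs with replacement, and one offspring
per pair:

* :func:`run_single_locus` — one distorter locus and one unlinked suppressor
  locus, both with continuously evolving allele strengths in [0, 1];
* :class:`MultilocusSim` (``mode="discrete"``) — genome-wide conflict with
  fixed-strength distorters (k) and suppressors (1), loci activated
  stochastically across the cabal and commonwealth, background (generalist)
  suppression at a fraction ``z`` and waste costs from inter-locus-recessive
  distorters;
* :class:`MultilocusSim` (``mode="continuous"``) — the same genome-wide
  model with per-allele strengths evolving freely in [0, 1].

Scalar reference implementations of the per-individual formulas (fitness,
total suppression, phenotype, meiosis probabilities) are exposed alongside
the vectorised engines and are cross-checked against them in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dynamics import GenomeArchitecture
from .trait_response import TraitResponse

__all__ = [
    "SimConfig",
    "GenomeLedger",
    "fitness_single_locus",
    "meiosis_single_locus",
    "run_single_locus",
    "run_single_locus_replicates",
    "total_suppression_discrete",
    "total_suppression_continuous",
    "phenotype_discrete",
    "waste_cost",
    "unit_drive_probability",
    "MultilocusSim",
    "MultilocusResult",
    "run_multilocus",
    "replicate_seed",
    "Z_BY_SOPHISTICATION",
    "REC_COST_RATIO",
]

#: Background (generalist) suppression fraction by distorter sophistication:
#: low-sophistication distorters are partially hit by any expressed
#: suppressor; high-sophistication ones only by their dedicated suppressor.
Z_BY_SOPHISTICATION = {"low": 0.5, "high": 0.0}

#: Per-recessive-distorter waste cost relative to c_trait(Dist):
#: c_rec(Waste) = ratio * c_trait(Dist) * (|I_distorter| - 1).
REC_COST_RATIO = {"low": 1.0, "high": 3.0 / 5.0}


def replicate_seed(seed: int, replicate: int) -> int:
    """Per-replicate seed: base seed plus replicate index (kept < 2**31)."""
    return (int(seed) + int(replicate)) % (2**31 - 1)


@dataclass
class SimConfig:
    """Agent-based simulation configuration.

    Defaults are the study conditions of the bundled experiments: a
    population of 2000 individuals, a per-allele mutation probability of
    0.01 per generation with a normal kernel of variance 0.2 truncated to
    [0, 1] (continuous strengths), or a 0.001 functional/neutral flip
    probability (discrete multilocus mode).
    """

    N: int = 2000
    T_end: int = 20_000
    seed: int = 0
    mut_prob: float = 0.01
    mut_var: float = 0.2
    flip_prob: float = 0.001
    k: float = 0.5
    n_replicates: int = 1
    allow_selfing: bool = True
    mutation_truncation: str = "clamp"  # or "resample"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        for name in ("mut_prob", "flip_prob", "k"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mutation_truncation not in ("clamp", "resample"):
            raise ValueError("mutation_truncation must be 'clamp' or 'resample'")


# ---------------------------------------------------------------------------
# Single-locus continuous ABM
# ---------------------------------------------------------------------------


def fitness_single_locus(
    k_a: float, k_b: float, m_a: float, m_b: float, tr: TraitResponse, c_sup: float
) -> float:
    """Viability of one individual in the single-locus model.

    ``1 - c_trait(max(k_a, k_b)) (1 - max(m_a, m_b)) - c_sup max(m_a, m_b)``
    when an active distorter is present (max(k_a, k_b) > 0), else 1: an
    individual without a distorter pays no suppression cost (facultative
    expression).
    """
    kmax = max(k_a, k_b)
    if kmax <= 0.0:
        return 1.0
    mmax = max(m_a, m_b)
    return 1.0 - tr.c(kmax) * (1.0 - mmax) - c_sup * mmax


def meiosis_single_locus(
    k_a: float,
    k_b: float,
    m_a: float,
    m_b: float,
    tr: TraitResponse,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Transmitted (distorter, suppressor) allele strengths for one gamete.

    The ``k_a`` allele displaces ``k_b`` with probability
    ``(1 + (t(k_a) - t(k_b)) (1 - max(m_a, m_b))) / 2``; suppressor alleles
    segregate in Mendelian fashion, independently (unlinked loci).
    """
    mmax = max(m_a, m_b)
    p_a = (1.0 + (tr.t(k_a) - tr.t(k_b)) * (1.0 - mmax)) / 2.0
    k_out = k_a if rng.random() < p_a else k_b
    m_out = m_a if rng.random() < 0.5 else m_b
    return k_out, m_out


def _mutate_continuous(
    vals: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> None:
    """In-place mutation: with prob ``mut_prob`` redraw from a normal kernel
    (variance ``mut_var``) centred on the current value, truncated to [0, 1]."""
    mask = rng.random(vals.shape) < cfg.mut_prob
    n = int(mask.sum())
    if n == 0:
        return
    sd = np.sqrt(cfg.mut_var)
    draws = vals[mask] + rng.normal(0.0, sd, size=n)
    if cfg.mutation_truncation == "clamp":
        np.clip(draws, 0.0, 1.0, out=draws)
    else:  # rejection-resample out-of-range draws
        bad = (draws < 0.0) | (draws > 1.0)
        while np.any(bad):
            draws[bad] = vals[mask][bad] + rng.normal(0.0, sd, size=int(bad.sum()))
            bad = (draws < 0.0) | (draws > 1.0)
    vals[mask] = draws


@dataclass
class SingleLocusResult:
    """Per-generation population averages from the single-locus ABM."""

    mean_k: np.ndarray  # E[k]: mean distorter allele strength
    mean_m: np.ndarray  # E[m]: mean suppressor allele strength
    seed: int


def run_single_locus(
    cfg: SimConfig,
    tr: TraitResponse,
    c_sup: float,
    *,
    seed: Optional[int] = None,
    init_k: float | np.ndarray = 0.0,
    init_m: float | np.ndarray = 0.0,
    mutate: bool = True,
) -> SingleLocusResult:
    """Evolve the single distorter + suppressor locus pair for ``T_end``
    generations, tracking the population mean allele strengths E[k], E[m].

    ``init_k``/``init_m`` may be scalars or arrays of shape (2, N) giving the
    two allele strengths per individual.  With ``mutate=False`` and
    strengths restricted to {0, k} and {0, 1} the engine reduces to a finite-
    population realisation of the deterministic two-locus recursions.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.N
    ka, kb = _init_pair(init_k, n)
    ma, mb = _init_pair(init_m, n)
    mean_k = np.empty(cfg.T_end)
    mean_m = np.empty(cfg.T_end)
    for gen in range(cfg.T_end):
        kmax = np.maximum(ka, kb)
        mmax = np.maximum(ma, mb)
        fit = np.where(kmax > 0.0, 1.0 - _c_vec(tr, kmax) * (1.0 - mmax) - c_sup * mmax, 1.0)
        np.clip(fit, 0.0, None, out=fit)
        total = fit.sum()
        if total <= 0.0:
            raise RuntimeError(f"all-zero fitness population at generation {gen}")
        parents = rng.choice(n, size=2 * n, p=fit / total)
        if not cfg.allow_selfing:
            p1, p2 = parents[:n], parents[n:]
            clash = p1 == p2
            while np.any(clash):
                p2[clash] = rng.choice(n, size=int(clash.sum()), p=fit / total)
                clash = p1 == p2
            parents = np.concatenate([p1, p2])
        pa = (1.0 + (_t_vec(tr, ka[parents]) - _t_vec(tr, kb[parents])) * (1.0 - mmax[parents])) / 2.0
        take_a = rng.random(2 * n) < pa
        k_gam = np.where(take_a, ka[parents], kb[parents])
        m_gam = np.where(rng.random(2 * n) < 0.5, ma[parents], mb[parents])
        ka, kb = k_gam[:n].copy(), k_gam[n:].copy()
        ma, mb = m_gam[:n].copy(), m_gam[n:].copy()
        if mutate and cfg.mut_prob > 0.0:
            for arr in (ka, kb, ma, mb):
                _mutate_continuous(arr, cfg, rng)
        mean_k[gen] = 0.5 * (ka.mean() + kb.mean())
        mean_m[gen] = 0.5 * (ma.mean() + mb.mean())
    return SingleLocusResult(mean_k, mean_m, seed=cfg.seed if seed is None else seed)


def run_single_locus_replicates(
    cfg: SimConfig, tr: TraitResponse, c_sup: float, **kwargs
) -> Tuple[np.ndarray, np.ndarray, List[SingleLocusResult]]:
    """Average E[k] and E[m] trajectories over ``cfg.n_replicates`` runs,
    replicate r seeded with ``seed + r``."""
    results = [
        run_single_locus(cfg, tr, c_sup, seed=replicate_seed(cfg.seed, r), **kwargs)
        for r in range(cfg.n_replicates)
    ]
    mean_k = np.mean([r.mean_k for r in results], axis=0)
    mean_m = np.mean([r.mean_m for r in results], axis=0)
    return mean_k, mean_m, results


def _init_pair(init, n: int) -> Tuple[np.ndarray, np.ndarray]:
    if np.isscalar(init):
        return np.full(n, float(init)), np.full(n, float(init))
    arr = np.asarray(init, dtype=float)
    if arr.shape != (2, n):
        raise ValueError("array init must have shape (2, N)")
    return arr[0].copy(), arr[1].copy()


def _t_vec(tr: TraitResponse, k: np.ndarray) -> np.ndarray:
    return np.asarray(tr._t(k), dtype=float)


def _c_vec(tr: TraitResponse, k: np.ndarray) -> np.ndarray:
    return np.asarray(tr._c(k), dtype=float)


# ---------------------------------------------------------------------------
# Multilocus formulas (scalar reference implementations)
# ---------------------------------------------------------------------------


def total_suppression_discrete(
    dedicated_present: bool, n_expressed_suppressors: int, z: float
) -> float:
    """Total suppression faced by one distorter, discrete mode.

    1 if its dedicated suppressor is present, else ``min(z q, 1)`` where
    ``q`` counts the expressed suppressors in the individual.
    """
    if dedicated_present:
        return 1.0
    return min(z * n_expressed_suppressors, 1.0)


def total_suppression_continuous(
    own_m: float, other_expressed_m: Sequence[float], z: float
) -> float:
    """Total suppression faced by one distorter, continuous mode:
    ``min(max(m_a, m_b) + z * sum over other expressed suppressors, 1)``."""
    return min(own_m + z * float(np.sum(other_expressed_m)), 1.0)


def waste_cost(dist: float, waste: float, sophistication: str, tr: TraitResponse) -> float:
    """Cost of the redundant gene-product pool from inter-locus-recessive
    distorters.

    The cost is a function of Waste — a fully suppressed recessive
    distorter produces no redundant gene product and costs nothing here —
    scaled so that each *unsuppressed* recessive distorter costs
    ``ratio * c_trait(Dist)`` (ratio 1 for low sophistication, 3/5 for
    high): ``c_rec = ratio * c_trait(Dist) * Waste / Dist``.
    """
    if dist <= 0.0 or waste <= 0.0:
        return 0.0
    return REC_COST_RATIO[sophistication] * tr.c(dist) * (waste / dist)


def phenotype_discrete(
    totsup: Sequence[float],
    k: float,
    sophistication: str,
    tr: TraitResponse,
    c_sup: float,
) -> Tuple[float, float, float]:
    """(Dist, Waste, fitness) of one individual from the total suppression
    faced by each of its distorters.

    ``Dist = max_i (1 - TotSup_i) k`` (the least-suppressed distorter is
    inter-locus dominant), ``Waste = sum_{i != i_dom} (1 - TotSup_i) k``,
    fitness ``1 - c_trait(Dist) - c_rec(Waste) - c_sup * sum_i TotSup_i``
    clamped to 0 for sampling.
    """
    totsup = np.asarray(totsup, dtype=float)
    if totsup.size == 0:
        return 0.0, 0.0, 1.0
    vals = (1.0 - totsup) * k
    dist = float(vals.max())
    waste = float(vals.sum() - dist)
    fit = 1.0 - tr.c(dist) - waste_cost(dist, waste, sophistication, tr) - c_sup * float(totsup.sum())
    return dist, waste, max(fit, 0.0)


def unit_drive_probability(het_drive_values: Sequence[float]) -> float:
    """Probability that the driving unit is transmitted at meiosis:
    ``(1 + max_i v_i) / 2`` where ``v_i`` is the post-suppression drive
    strength of heterozygous distorter i (0.5 when no heterozygous
    distorter — fully Mendelian)."""
    vals = np.asarray(het_drive_values, dtype=float)
    if vals.size == 0:
        return 0.5
    return (1.0 + float(vals.max())) / 2.0


# ---------------------------------------------------------------------------
# Multilocus engines
# ---------------------------------------------------------------------------


@dataclass
class GenomeLedger:
    """Sparse record of activated loci: only loci at which a distorter or
    suppressor has actually arisen are materialised; the ``gamma``-locus
    genome itself never is.  Commonwealth locus i is the dedicated
    suppressor of cabal locus i (consecutive-integer pairing), so activated
    commonwealth loci can never outnumber activated cabal loci."""

    n_cabal: int = 0
    n_commonwealth: int = 0
    sophistication: str = "low"

    def __post_init__(self) -> None:
        if self.sophistication not in Z_BY_SOPHISTICATION:
            raise ValueError("sophistication must be 'low' or 'high'")
        if self.n_commonwealth > self.n_cabal:
            raise ValueError("activated commonwealth loci cannot exceed cabal loci")

    @property
    def z(self) -> float:
        return Z_BY_SOPHISTICATION[self.sophistication]


@dataclass
class MultilocusResult:
    mean_dist: np.ndarray  # population mean expressed distortion per generation
    n_cabal: np.ndarray
    n_commonwealth: np.ndarray
    seed: int
    mode: str
    sophistication: str
    negative_fitness_events: int = 0

    @property
    def time_average_distortion(self) -> float:
        return float(self.mean_dist.mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": np.arange(1, self.mean_dist.size + 1),
                "mean_dist": self.mean_dist,
                "n_cabal": self.n_cabal,
                "n_commonwealth": self.n_commonwealth,
            }
        )


class MultilocusSim:
    """Genome-wide agent-based simulation with stochastic locus activation.

    Parameters
    ----------
    cfg
        Population size, horizon, mutation parameters, fixed distorter
        strength ``k`` (discrete mode).
    genome
        Genome architecture; the effective per-locus activation
        probabilities are ``rho * rho_D1`` (cabal) and ``rho * rho_S1``
        (commonwealth, gated so dedicated suppressors never outnumber
        distorter loci).
    mode
        ``"discrete"`` (fixed strengths k and 1, functional/neutral flips at
        0.001 per allele) or ``"continuous"`` (strengths evolve in [0, 1]
        under the 0.01 normal-kernel mutation).
    sophistication
        ``"low"`` (background suppression z = 0.5, full waste cost) or
        ``"high"`` (z = 0, reduced waste cost).
    """

    def __init__(
        self,
        cfg: SimConfig,
        genome: GenomeArchitecture,
        tr: TraitResponse,
        c_sup: float,
        mode: str = "discrete",
        sophistication: str = "low",
    ):
        if mode not in ("discrete", "continuous"):
            raise ValueError("mode must be 'discrete' or 'continuous'")
        self.cfg = cfg
        self.genome = genome
        self.tr = tr
        self.c_sup = float(c_sup)
        self.mode = mode
        self.sophistication = sophistication
        self.z = Z_BY_SOPHISTICATION[sophistication]
        self.rec_ratio = REC_COST_RATIO[sophistication]
        self._n_cabal_total = int(round(genome.theta * genome.gamma))
        self._n_comm_total = int(round((1.0 - genome.theta) * genome.gamma))
        self._tk = tr.t(cfg.k)

    # -- phenotype --------------------------------------------------------

    def _phenotype(self, Ak, Bk, Am, Bm):
        """Vectorised per-individual phenotype.

        Returns (dist, fitness, drive_value) where ``drive_value`` is the
        post-suppression drive strength of each individual's driving unit.
        """
        if self.mode == "discrete":
            return self._phenotype_discrete(Ak, Bk, Am, Bm)
        return self._phenotype_continuous(Ak, Bk, Am, Bm)

    def _phenotype_discrete(self, Ak, Bk, Am, Bm):
        # All uncovered distorters in one individual share the background
        # suppression level min(z q, 1), so Dist, Waste, total suppression
        # and the unit drive strength reduce to per-individual counts.
        n = Ak.shape[0]
        ls = Am.shape[1]
        P = Ak | Bk  # distorter present
        het = Ak ^ Bk
        n_dist = P.sum(axis=1)
        het_count = het.sum(axis=1)
        if ls:
            ded = Am | Bm  # dedicated suppressor present
            covered = ded & P[:, :ls]  # covered distorter <=> expressed sup.
            q = covered.sum(axis=1)
            cov_het = (ded & het[:, :ls]).sum(axis=1)
        else:
            q = np.zeros(n, dtype=np.int64)
            cov_het = np.zeros(n, dtype=np.int64)
        n_unsup = n_dist - q
        bg = np.minimum(self.z * q, 1.0)  # background suppression level
        unsup_val = (1.0 - bg) * self.cfg.k
        dist = np.where(n_unsup > 0, unsup_val, 0.0)
        c_dist = _c_vec(self.tr, dist)
        # Waste / Dist = number of *unsuppressed* recessive distorters (the
        # uncovered loci all share the value (1 - bg) k); fully suppressed
        # distorters add no redundant gene product.
        c_rec = self.rec_ratio * c_dist * np.maximum(n_unsup - 1, 0)
        totsup_sum = q + n_unsup * bg
        fitness = 1.0 - c_dist - c_rec - self.c_sup * totsup_sum
        drive = np.where(het_count > cov_het, (1.0 - bg) * self._tk, 0.0)
        return dist, fitness, drive

    def _phenotype_continuous(self, Ak, Bk, Am, Bm):
        n = Ak.shape[0]
        lc, ls = Ak.shape[1], Am.shape[1]
        Kmax = np.maximum(Ak, Bk)
        het_strength = _t_vec(self.tr, Kmax) - _t_vec(self.tr, np.minimum(Ak, Bk))
        P = Kmax > 0.0  # I_distorter membership
        # Suppressor strength per (padded) cabal locus, gated by expression:
        # a suppressor is expressed only when its target distorter is present.
        M = np.zeros((n, lc))
        if ls:
            M[:, :ls] = np.maximum(Am, Bm)
        M_expr = np.where(P, M, 0.0)
        s_tot = M_expr.sum(axis=1, keepdims=True)
        totsup = np.minimum(M_expr + self.z * (s_tot - M_expr), 1.0)
        totsup = np.where(P, totsup, 0.0)
        vals = np.where(P, (1.0 - totsup) * Kmax, 0.0)
        dist = vals.max(axis=1) if lc else np.zeros(n)
        waste = vals.sum(axis=1) - dist if lc else np.zeros(n)
        c_dist = _c_vec(self.tr, dist)
        ratio = np.zeros_like(dist)
        np.divide(waste, dist, out=ratio, where=dist > 0.0)
        c_rec = self.rec_ratio * c_dist * ratio
        fitness = 1.0 - c_dist - c_rec - self.c_sup * totsup.sum(axis=1)
        # Only unequal-allele distorter loci contribute to the driving unit.
        drive_vals = np.where(P, (1.0 - totsup) * het_strength, 0.0)
        drive = drive_vals.max(axis=1) if lc else np.zeros(n)
        return dist, fitness, drive

    # -- one replicate ----------------------------------------------------

    def run(self, seed: int) -> MultilocusResult:
        cfg = self.cfg
        rng = np.random.default_rng(seed)
        n = cfg.N
        dt = bool if self.mode == "discrete" else float
        Ak = np.zeros((n, 0), dtype=dt)
        Bk = np.zeros((n, 0), dtype=dt)
        Am = np.zeros((n, 0), dtype=dt)
        Bm = np.zeros((n, 0), dtype=dt)
        p_d = self.genome.rho * self.genome.rho_D1
        p_s = self.genome.rho * self.genome.rho_S1
        mean_dist = np.empty(cfg.T_end)
        n_cab = np.empty(cfg.T_end, dtype=int)
        n_com = np.empty(cfg.T_end, dtype=int)
        neg_events = 0
        for gen in range(cfg.T_end):
            # --- locus activation ---
            dormant_c = self._n_cabal_total - Ak.shape[1]
            new_c = rng.binomial(dormant_c, p_d) if dormant_c > 0 else 0
            for _ in range(new_c):
                Ak, Bk = _append_locus(Ak, Bk, rng, n, self._seed_value(rng, "k"))
            gate = Ak.shape[1] - Am.shape[1]
            dormant_s = self._n_comm_total - Am.shape[1]
            if gate > 0 and dormant_s > 0:
                new_s = min(rng.binomial(dormant_s, p_s), gate)
                for _ in range(new_s):
                    Am, Bm = _append_locus(Am, Bm, rng, n, self._seed_value(rng, "m"))
            # --- phenotype and selection ---
            dist, fitness, drive = self._phenotype(Ak, Bk, Am, Bm)
            neg_events += int((fitness < 0.0).sum())
            np.clip(fitness, 0.0, None, out=fitness)
            total = fitness.sum()
            if total <= 0.0:
                raise RuntimeError(f"all-zero fitness population at generation {gen}")
            parents = rng.choice(n, size=2 * n, p=fitness / total)
            # --- meiosis ---
            u = (1.0 + drive[parents]) / 2.0
            success = rng.random(2 * n) < u
            Gk = _distorter_gametes(Ak, Bk, parents, success, self.mode)
            Gm = _mendelian_gametes(Am, Bm, parents, rng)
            Ak, Bk = Gk[:n], Gk[n:]
            Am, Bm = Gm[:n], Gm[n:]
            # --- mutation ---
            if self.mode == "discrete":
                for arr in (Ak, Bk, Am, Bm):
                    if arr.size:
                        _sparse_flips(arr, cfg.flip_prob, rng)
            else:
                for arr in (Ak, Bk, Am, Bm):
                    if arr.size:
                        _mutate_continuous(arr, cfg, rng)
            mean_dist[gen] = dist.mean()
            n_cab[gen] = Ak.shape[1]
            n_com[gen] = Am.shape[1]
        return MultilocusResult(
            mean_dist,
            n_cab,
            n_com,
            seed=seed,
            mode=self.mode,
            sophistication=self.sophistication,
            negative_fitness_events=neg_events,
        )

    def _seed_value(self, rng: np.random.Generator, locus_type: str):
        """Allele value seeded at a newly activated locus: one functional
        copy (strength k / 1 in discrete mode; one mutational step from 0 in
        continuous mode) in one random haplotype of one random individual."""
        if self.mode == "discrete":
            return True
        draw = abs(rng.normal(0.0, np.sqrt(self.cfg.mut_var)))
        return float(min(draw, 1.0))


def _append_locus(a: np.ndarray, b: np.ndarray, rng, n: int, value):
    lc = a.shape[1]
    new_a = np.zeros((n, lc + 1), dtype=a.dtype)
    new_b = np.zeros((n, lc + 1), dtype=a.dtype)
    new_a[:, :lc] = a
    new_b[:, :lc] = b
    ind = rng.integers(n)
    if rng.random() < 0.5:
        new_a[ind, lc] = value
    else:
        new_b[ind, lc] = value
    return new_a, new_b


def _distorter_gametes(Ak, Bk, parents, success, mode):
    """Gametes at cabal loci: drive success transmits the stronger allele at
    every locus of the driving unit, failure the weaker; equal alleles
    transmit trivially."""
    a, b = Ak[parents], Bk[parents]
    if mode == "discrete":
        hom = a & b
        het = a ^ b
        return hom | (het & success[:, None])
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    return np.where(success[:, None], hi, lo)


def _random_bits(rng, shape):
    """Boolean array of fair coin flips, drawn as packed random bytes
    (an order of magnitude cheaper than per-element uniforms)."""
    n = int(np.prod(shape))
    if n == 0:
        return np.zeros(shape, dtype=bool)
    raw = np.frombuffer(rng.bytes((n + 7) // 8), dtype=np.uint8)
    return np.unpackbits(raw)[:n].reshape(shape).view(bool)


def _mendelian_gametes(Am, Bm, parents, rng):
    a, b = Am[parents], Bm[parents]
    if a.size == 0:
        return a
    pick = _random_bits(rng, a.shape)
    return np.where(pick, a, b)


def _sparse_flips(arr, p, rng):
    """Flip functional/neutral states in place at per-allele probability
    ``p``, materialising only the flipped positions."""
    n_flip = rng.binomial(arr.size, p)
    if n_flip:
        idx = rng.integers(0, arr.size, size=n_flip)
        arr.reshape(-1)[idx] ^= True


def run_multilocus(
    cfg: SimConfig,
    genome: GenomeArchitecture,
    tr: TraitResponse,
    c_sup: float,
    mode: str = "discrete",
    sophistication: str = "low",
) -> Tuple[List[MultilocusResult], float, float]:
    """Run ``cfg.n_replicates`` multilocus replicates (replicate r seeded
    ``seed + r``) and return (results, mean, standard error) of the
    per-replicate time-averaged distortion."""
    sim = MultilocusSim(cfg, genome, tr, c_sup, mode=mode, sophistication=sophistication)
    results = [sim.run(replicate_seed(cfg.seed, r)) for r in range(cfg.n_replicates)]
    avgs = np.asarray([r.time_average_distortion for r in results])
    mean = float(avgs.mean())
    se = float(avgs.std(ddof=1) / np.sqrt(len(avgs))) if len(avgs) > 1 else float("nan")
    return results, mean, se
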