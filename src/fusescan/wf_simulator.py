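"""Forward-time Wright-Fisher model of a deletion-born fusion's fate.

A haploid population of fixed size N holds individuals in three states:
0 (no fusion, fitness 1), 1 (non-functional novel gene, fitness 1 - c) and
2 (functionalized gene). Each generation the next population is drawn by
fitness-proportionate multinomial sampling (selection + drift); after
reproduction each state-1 individual independently functionalizes with
probability p_func or loses the gene with probability p_purge (mutually
exclusive outcomes of one trinomial split). A replicate ends at the first
appearance of any state-2 individual (functionalized), at state-1
extinction (lost), or at the generation cap t_max. The hitchhiking
scenario of interest initializes state 1 at frequency p_init — a lone
individual at p_init = 1/N, or the whole population when the causal
deletion has already swept.

p_func is the per-individual, per-generation functionalization rate (the
mutation-rate-like parameter often written mu); p_purge the corresponding
loss rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N = 10**6
DEFAULT_T_MAX = 100_000
DEFAULT_SEED = 42


@dataclass
class WFParams:
    N: int = DEFAULT_N
    c: float = 0.0
    p_init: float = 1e-6
    p_purge: float = 0.0
    p_func: float = 0.0
    t_max: int = DEFAULT_T_MAX
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 <= self.c < 1:
            raise ValueError("c must be in [0, 1)")
        for name in ("p_init", "p_purge", "p_func"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_func + self.p_purge > 1:
            raise ValueError("p_func + p_purge must not exceed 1")


@dataclass
class WFOutcome:
    functionalized: bool
    end_generation: int
    end_reason: str  # "functionalized" | "lost" | "t_max"
    trajectory: list[tuple[int, int]] | None = None  # (n0, n1) per gen


@dataclass
class SweepGrid:
    p_func_values: np.ndarray
    p_purge_values: np.ndarray
    replicates: int
    prob_matrix: np.ndarray  # shape (len(p_func), len(p_purge))


def _initial_count(N: int, p_init: float) -> int:
    if p_init <= 0:
        return 0
    return max(1, round(N * p_init))


def run_wf_replicate(params: WFParams,
                     rng: np.random.Generator | None = None,
                     record_trajectory: bool = False) -> WFOutcome:
    """One replicate; returns the outcome and the generation it occurred.

    When the population is homogeneous state-1 (no state-0 competitors),
    resampling is the identity and generations pass without change until
    the first purge/functionalization event; that waiting time is drawn
    geometrically instead of iterating event-free generations, which is
    distributionally exact.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    N, c = params.N, params.c
    p_f, p_p = params.p_func, params.p_purge
    p_event = p_f + p_p
    n1 = _initial_count(N, params.p_init)
    n0 = N - n1
    t = 0
    traj: list[tuple[int, int]] | None = (
        [(n0, n1)] if record_trajectory else None)

    def done(func: bool, gen: int, reason: str) -> WFOutcome:
        return WFOutcome(func, gen, reason, traj)

    if n1 == 0:
        return done(False, 0, "lost")
    while t < params.t_max:
        if n0 == 0 and p_event <= 0:
            # state 1 fixed with no transitions: absorbed until t_max
            return done(False, params.t_max, "t_max")
        if n0 == 0 and traj is None:
            # homogeneous state-1 population: fast-forward to first event
            if p_event <= 0:
                return done(False, params.t_max, "t_max")
            p_any = -np.expm1(N * np.log1p(-p_event))  # 1-(1-p)^N
            if p_any <= 0:
                return done(False, params.t_max, "t_max")
            gap = int(rng.geometric(p_any))
            t += gap
            if t > params.t_max:
                return done(False, params.t_max, "t_max")
            # event counts conditioned on >= 1 event among N trials
            while True:
                n_func, n_purge, _ = rng.multinomial(
                    N, [p_f, p_p, 1 - p_event])
                if n_func + n_purge > 0:
                    break
            if n_func > 0:
                return done(True, t, "functionalized")
            n1 -= n_purge
            n0 += n_purge
            if n1 == 0:
                return done(False, t, "lost")
            continue
        t += 1
        # selection + drift
        w1 = n1 * (1.0 - c)
        total = n0 + w1
        n1 = int(rng.binomial(N, w1 / total))
        n0 = N - n1
        if n1 == 0:
            if traj is not None:
                traj.append((n0, n1))
            return done(False, t, "lost")
        # functionalization / purging as one trinomial split of state 1
        if p_event > 0:
            n_func, n_purge, _ = rng.multinomial(
                n1, [p_f, p_p, 1 - p_event])
            if n_func > 0:
                return done(True, t, "functionalized")
            n1 -= n_purge
            n0 += n_purge
            if n1 == 0:
                if traj is not None:
                    traj.append((n0, n1))
                return done(False, t, "lost")
        if traj is not None:
            traj.append((n0, n1))
    return done(False, params.t_max, "t_max")


def log_spaced(lo: float, hi: float, n: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


DEFAULT_P_FUNC_GRID = log_spaced(1e-16, 1e-2, 20)
DEFAULT_P_PURGE_GRID = log_spaced(1e-8, 1e-2, 20)


def sweep_functionalization(base: WFParams,
                            p_func_values: np.ndarray | None = None,
                            p_purge_values: np.ndarray | None = None,
                            replicates: int = 100,
                            seed: int | None = None) -> SweepGrid:
    """Fraction of replicates that functionalize per (p_func, p_purge) cell.

    A single root seed spawns one independent substream per (cell,
    replicate), so serial and parallel execution orders agree and two runs
    with the same seed produce a bit-identical matrix.
    """
    pf = (np.asarray(p_func_values) if p_func_values is not None
          else DEFAULT_P_FUNC_GRID)
    pp = (np.asarray(p_purge_values) if p_purge_values is not None
          else DEFAULT_P_PURGE_GRID)
    root = np.random.SeedSequence(base.seed if seed is None else seed)
    prob = np.zeros((pf.size, pp.size))
    streams = root.spawn(pf.size * pp.size)
    for i, pfv in enumerate(pf):
        for j, ppv in enumerate(pp):
            cell_ss = streams[i * pp.size + j]
            rep_ss = cell_ss.spawn(replicates)
            params = WFParams(N=base.N, c=base.c, p_init=base.p_init,
                              p_purge=float(ppv), p_func=float(pfv),
                              t_max=base.t_max, seed=base.seed)
            wins = 0
            for r in range(replicates):
                rng = np.random.default_rng(rep_ss[r])
                if run_wf_replicate(params, rng).functionalized:
                    wins += 1
            prob[i, j] = wins / replicates
    return SweepGrid(pf, pp, replicates, prob)
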