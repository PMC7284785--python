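"""Panicle progenitor-cell (chimera) segregation model.

An M1 plant grown from a mutagenized dry seed is a genetic chimera: each
panicle descends from one of P progenitor cells already present in the
embryo. A mutation induced in one progenitor forms a sector, so only the
panicles derived from that cell segregate mutants in M2. The model:

  * the k harvested panicles are allocated to the P progenitors
    ("balanced": each contributes floor(k/P) or ceil(k/P); or
    "uniform-random": each panicle picks a progenitor uniformly);
  * each progenitor independently carries a scorable mutation with
    probability m;
  * a panicle from a mutated progenitor is detected as mutant with
    probability d (near 1 for a recessive marker scored on 36 seedlings).

The observable per plant is x = number of mutant-bearing panicles out of
k. Inference of P conditions on x >= 1 (plants with at least one mutant
panicle), which removes dependence on the absolute mutation rate scale,
and profiles m out by 1-D likelihood maximization for each candidate P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom

_MAX_EXACT_P = 20


@dataclass
class ProgenitorModel:
    """P progenitor cells, per-progenitor mutation probability m,
    per-panicle detection probability d, and the panicle allocation rule."""

    P: int
    m: float
    d: float = 1.0
    allocation: str = "balanced"

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not 0.0 <= self.m <= 1.0 or not 0.0 <= self.d <= 1.0:
            raise ValueError("m and d must be probabilities in [0, 1]")
        if self.allocation not in ("balanced", "uniform-random"):
            raise ValueError("allocation must be 'balanced' or 'uniform-random'")


def balanced_counts(k: int, P: int) -> list[int]:
    """Panicles contributed per progenitor under balanced allocation.

    The remainder is assigned to randomly chosen progenitors, but since
    progenitors are exchangeable the distribution of x depends only on
    the multiset of counts returned here.
    """
    base, rem = divmod(k, P)
    return [base + 1] * rem + [base] * (P - rem)


def panicle_mutant_distribution(
    model: ProgenitorModel, k: int, monte_carlo: bool = False, n_draws: int = 10**6, seed: int = 0
) -> np.ndarray:
    """Exact pmf of x = mutant-bearing panicles out of k, over x = 0..k.

    Balanced allocation: x is a sum over progenitors of independent
    mixtures (1-m)*delta_0 + m*Binomial(c_i, d); the pmf is their exact
    convolution, equivalent to enumerating all 2^P mutation states.
    Uniform-random allocation: conditioning on j mutated progenitors,
    each panicle is independently mutant with probability d*j/P, giving
    an exact binomial mixture over j ~ Binomial(P, m).

    For P above 20 the exact path is refused unless ``monte_carlo=True``,
    in which case the pmf is estimated from ``n_draws`` simulated plants.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if model.P > _MAX_EXACT_P and not monte_carlo:
        raise ValueError(f"P > {_MAX_EXACT_P}: pass monte_carlo=True to estimate the pmf by simulation")
    if monte_carlo:
        from .synthetic_data import generate_panicle_table

        table = generate_panicle_table(
            P=model.P, m=model.m, k=k, n_plants=n_draws, d=model.d, seed=seed, allocation=model.allocation
        )
        counts = np.bincount(table["n_mutant_panicles"].to_numpy(), minlength=k + 1)
        return counts / counts.sum()

    if model.allocation == "balanced":
        pmf = np.array([1.0])
        for c in balanced_counts(k, model.P):
            comp = model.m * binom.pmf(np.arange(c + 1), c, model.d)
            comp[0] += 1.0 - model.m
            pmf = np.convolve(pmf, comp)
        return pmf  # length k+1 since counts sum to k
    # uniform-random
    xs = np.arange(k + 1)
    pmf = np.zeros(k + 1)
    for j in range(model.P + 1):
        w = binom.pmf(j, model.P, model.m)
        pmf += w * binom.pmf(xs, k, model.d * j / model.P)
    return pmf


def conditional_distribution(model: ProgenitorModel, k: int) -> np.ndarray:
    """pmf of x over 1..k conditional on x >= 1 (plants with mutants)."""
    pmf = panicle_mutant_distribution(model, k)
    p_pos = 1.0 - pmf[0]
    if p_pos <= 0.0:
        raise ValueError("P(x >= 1) = 0 (m = 0 or d = 0): conditional distribution undefined")
    return pmf[1:] / p_pos


@dataclass
class ProgenitorFit:
    """ML inference of the progenitor number from a panicle table."""

    P_hat: int
    m_hat: float
    profile: dict[int, float]  # P -> maximized log-likelihood
    m_by_P: dict[int, float] = field(default_factory=dict)


def fit_progenitor_number(
    table: pd.DataFrame,
    P_grid: list[int] | range = range(1, 7),
    d: float = 1.0,
    allocation: str = "balanced",
) -> ProgenitorFit:
    """Profile-likelihood fit of the progenitor number P.

    ``table`` columns: ``plant_id``, ``k``, ``n_mutant_panicles``. Only
    plants with at least one mutant panicle inform the fit (the model is
    conditioned on x >= 1). For each P in the grid, m is profiled out by
    bounded 1-D maximization of the multinomial log-likelihood of the
    conditional distribution; P_hat is the grid argmax, ties broken
    toward smaller P (parsimony).
    """
    obs = table[table["n_mutant_panicles"] >= 1]
    if len(obs) == 0:
        raise ValueError("no plants with mutant panicles: cannot infer P")
    if (table["n_mutant_panicles"] > table["k"]).any():
        raise ValueError("n_mutant_panicles may not exceed k")

    # tally observed x by k so the likelihood handles mixed panicle numbers
    tallies: dict[int, np.ndarray] = {}
    for k, grp in obs.groupby("k"):
        tallies[int(k)] = np.bincount(grp["n_mutant_panicles"].to_numpy(), minlength=int(k) + 1)[1:]

    def negll(m: float, P: int) -> float:
        total = 0.0
        for k, counts in tallies.items():
            cond = conditional_distribution(ProgenitorModel(P=P, m=m, d=d, allocation=allocation), k)
            total += float(counts @ np.log(np.maximum(cond, 1e-300)))
        return -total

    profile: dict[int, float] = {}
    m_by_P: dict[int, float] = {}
    for P in P_grid:
        res = minimize_scalar(
            negll, bounds=(1e-6, 1 - 1e-6), args=(P,), method="bounded", options={"xatol": 1e-8}
        )
        profile[int(P)] = -float(res.fun)
        m_by_P[int(P)] = float(res.x)

    P_hat = None
    for P in sorted(profile):  # ascending: strict improvement required, so ties go to smaller P
        if P_hat is None or profile[P] > profile[P_hat] + 1e-9:
            P_hat = P
    return ProgenitorFit(P_hat=P_hat, m_hat=m_by_P[P_hat], profile=profile, m_by_P=m_by_P)


def mutation_frequency(table: pd.DataFrame, basis: str) -> float:
    """Mutation frequency on the M1 plant or panicle(-row) basis.

    plant basis: fraction of M1 plants with >= 1 mutant-bearing panicle;
    panicle basis: fraction of all harvested panicles bearing mutants.
    When every plant contributes the same number of panicles (the usual
    design), the plant basis is always >= the panicle basis.
    """
    if len(table) == 0:
        raise ValueError("empty panicle table")
    x = table["n_mutant_panicles"].to_numpy()
    if basis == "plant":
        return float((x >= 1).mean())
    if basis == "panicle":
        return float(x.sum() / table["k"].to_numpy().sum())
    raise ValueError("basis must be 'plant' or 'panicle'")


def detection_probability(n_seedlings: int, segregant_fraction: float) -> float:
    """Probability that >= 1 segregant appears among n scored seedlings.

    1 - (1 - f)^n. For a monogenic recessive (f = 1/4) scored on 36
    seedlings per panicle this is ~0.99997, justifying d ~ 1.
    """
    if n_seedlings < 0:
        raise ValueError("n_seedlings must be >= 0")
    return 1.0 - (1.0 - segregant_fraction) ** n_seedlings
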