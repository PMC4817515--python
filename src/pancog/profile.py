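"""Pan/core-genome accumulation profiles and the open/closed verdict.

For each sampled ordering of the genomes, the pan curve is the cumulative
count of distinct families discovered and the core curve the count of
families shared by all genomes added so far.  The pan curve is fitted as
a power law P(n) = kappa * n^gamma on log-log axes; the per-step
new-family counts follow Heaps' law N(n) = k * n^(-alpha).  A pan-genome
is called open when the pan exponent stays positive (gamma >= gamma_open)
or the Heaps decay alpha is <= 1 — i.e. the trend line has not reached a
plateau.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core_model import PresenceAbsenceMatrix

__all__ = ["PanProfile", "PowerLawFit", "accumulation_profiles", "fit_power_law"]


@dataclass
class PanProfile:
    n_values: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    new_genes_mean: np.ndarray
    n_orderings: int
    exhaustive: bool
    seed: int | None


@dataclass
class PowerLawFit:
    kappa: float
    gamma: float
    r_squared_pan: float
    heaps_k: float
    alpha: float
    r_squared_new: float
    verdict: str  # "open" | "closed"
    gamma_open: float


def accumulation_profiles(matrix: PresenceAbsenceMatrix, n_orderings: int = 1000,
                          seed: int | None = 0) -> PanProfile:
    """Pan/core accumulation curves over genome addition orders.

    When G! <= n_orderings all orderings are enumerated exactly; otherwise
    *n_orderings* seeded random permutations are sampled (an unbiased
    estimate of the same means).
    """
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    cells = matrix.cells.to_numpy()  # families x genomes
    G = cells.shape[1]
    if G < 2:
        raise ValueError("need at least two genomes")

    n_perms_total = math.factorial(G)
    exhaustive = n_perms_total <= n_orderings
    if exhaustive:
        orders = itertools.permutations(range(G))
        n_used = n_perms_total
    else:
        rng = np.random.default_rng(seed)
        orders = (rng.permutation(G) for _ in range(n_orderings))
        n_used = n_orderings

    pan = np.zeros((n_used, G), dtype=np.int64)
    core = np.zeros((n_used, G), dtype=np.int64)
    new = np.zeros((n_used, G), dtype=np.int64)
    for r, order in enumerate(orders):
        present = cells[:, list(order)]
        cum_union = np.logical_or.accumulate(present, axis=1)
        cum_inter = np.logical_and.accumulate(present, axis=1)
        p = cum_union.sum(axis=0)
        pan[r] = p
        core[r] = cum_inter.sum(axis=0)
        new[r, 0] = p[0]
        new[r, 1:] = np.diff(p)
        if (np.diff(p) < 0).any() or (np.diff(core[r]) > 0).any():
            raise AssertionError("accumulation monotonicity violated")

    return PanProfile(
        n_values=np.arange(1, G + 1),
        pan_mean=pan.mean(axis=0), pan_sd=pan.std(axis=0, ddof=0),
        core_mean=core.mean(axis=0), core_sd=core.std(axis=0, ddof=0),
        new_genes_mean=new.mean(axis=0),
        n_orderings=n_used, exhaustive=exhaustive,
        seed=None if exhaustive else seed,
    )


def fit_power_law(profile: PanProfile, gamma_open: float = 0.05) -> PowerLawFit:
    """Least-squares power-law fits of the pan curve and the new-family
    (Heaps) curve, with the openness verdict."""
    n = profile.n_values.astype(float)
    if len(n) < 4:
        raise ValueError("need at least 4 genomes to fit")
    if (profile.pan_mean <= 0).any():
        raise ValueError("pan sizes must be positive for a log-log fit")

    gamma, log_kappa, r2_pan = _loglog_fit(n, profile.pan_mean.astype(float))

    # Heaps fit on n >= 2 (the first step "discovers" a whole genome)
    mask = (n >= 2) & (profile.new_genes_mean > 0)
    if mask.sum() >= 2:
        slope, log_k, r2_new = _loglog_fit(n[mask], profile.new_genes_mean[mask])
        alpha = -slope
        heaps_k = math.exp(log_k)
    else:
        alpha, heaps_k, r2_new = math.inf, 0.0, 0.0

    verdict = "open" if (gamma >= gamma_open or alpha <= 1.0) else "closed"
    return PowerLawFit(kappa=math.exp(log_kappa), gamma=gamma,
                       r_squared_pan=r2_pan, heaps_k=heaps_k, alpha=alpha,
                       r_squared_new=r2_new, verdict=verdict,
                       gamma_open=gamma_open)


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), r2
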