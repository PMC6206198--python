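"""Self-contained adaptive Metropolis-within-Gibbs sampler.

Scalar random-walk updates on a transformed scale, one parameter at a time,
with per-parameter step sizes adapted toward a 0.44 acceptance rate during an
initial adaptation phase only (so the post-adaptation chain is a valid
Markov chain).  The posterior is supplied as a sum of likelihood
*components*, each declaring which parameters it reads, so an update only
recomputes the components it can change — the joint model factorizes into
dead-recovery, recapture and age-composition blocks that share no parameters.

Probability parameters with Uniform(0,1) priors are sampled on the logit
scale (the prior contributes the Jacobian log[x(1-x)]); bounded hyper-
parameters are sampled on their natural scale with a flat prior inside the
bounds; standard-normal year effects contribute -z^2/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["ParamSpec", "Component", "run_chains", "rhat"]

_LOGIT = "logit-unit"
_UNIFORM = "uniform"
_NORMAL = "normal"


@dataclass(frozen=True)
class ParamSpec:
    """One scalar parameter: its prior/transform kind and initial raw value."""

    name: str
    kind: str  # "logit-unit" | "uniform" | "normal"
    init: float
    lo: float = float("-inf")
    hi: float = float("inf")
    step: float = 0.5


@dataclass(frozen=True)
class Component:
    """A log-likelihood term reading a subset of the constrained parameters."""

    name: str
    param_idx: tuple[int, ...]
    fn: Callable[[np.ndarray], float]


def _constrain(kind: str, raw: float) -> float:
    if kind == _LOGIT:
        return float(expit(raw))
    return raw


def _log_prior(spec: ParamSpec, raw: float, x: float) -> float:
    if spec.kind == _LOGIT:
        # Uniform(0,1) prior on x plus logit Jacobian
        if x <= 0.0 or x >= 1.0:
            return -math.inf
        return math.log(x * (1.0 - x))
    if spec.kind == _UNIFORM:
        return 0.0 if spec.lo < raw < spec.hi else -math.inf
    if spec.kind == _NORMAL:
        return -0.5 * raw * raw
    raise ValueError(f"unknown parameter kind {spec.kind!r}")


def _run_single_chain(
    specs: Sequence[ParamSpec],
    components: Sequence[Component],
    inits: np.ndarray,
    n_iter: int,
    n_burn: int,
    thin: int,
    n_adapt: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(specs)
    raw = np.array(inits, dtype=float)
    x = np.array([_constrain(s.kind, r) for s, r in zip(specs, raw)])
    lp = np.array([_log_prior(s, r, xi) for s, r, xi in zip(specs, raw, x)])
    if not np.isfinite(lp).all():
        raise ValueError("initial values have zero prior density")
    comp_ll = np.array([c.fn(x) for c in components])
    comps_of: list[list[int]] = [[] for _ in range(n)]
    for ci, c in enumerate(components):
        for i in c.param_idx:
            comps_of[i].append(ci)
    step = np.array([s.step for s in specs])
    acc = np.zeros(n)
    batch = 50
    n_kept = (n_iter - n_burn + thin - 1) // thin
    kept = np.empty((n_kept, n))
    accepted_total = 0
    k = 0
    for it in range(n_iter):
        for i in range(n):
            prop = raw[i] + step[i] * rng.standard_normal()
            xi_new = _constrain(specs[i].kind, prop)
            lp_new = _log_prior(specs[i], prop, xi_new)
            if lp_new == -math.inf:
                continue
            xi_old = x[i]
            x[i] = xi_new
            delta = lp_new - lp[i]
            new_lls = []
            for ci in comps_of[i]:
                ll = components[ci].fn(x)
                new_lls.append(ll)
                delta += ll - comp_ll[ci]
            if delta >= 0.0 or math.log(rng.random()) < delta:
                raw[i] = prop
                lp[i] = lp_new
                for ci, ll in zip(comps_of[i], new_lls):
                    comp_ll[ci] = ll
                acc[i] += 1
                accepted_total += 1
            else:
                x[i] = xi_old
        if it < n_adapt and (it + 1) % batch == 0:
            rate = acc / batch
            delta_s = min(0.25, (it + 1) ** -0.5 + 0.02)
            step *= np.exp(np.where(rate > 0.44, delta_s, -delta_s))
            acc[:] = 0.0
        if it >= n_burn and (it - n_burn) % thin == 0:
            kept[k] = x
            k += 1
    return kept[:k], step


def run_chains(
    specs: Sequence[ParamSpec],
    components: Sequence[Component],
    inits: np.ndarray,
    n_chains: int,
    n_iter: int,
    n_burn: int,
    thin: int,
    n_adapt: int,
    seed,
) -> np.ndarray:
    """Run independent chains; returns draws of shape (chains, kept, params).

    ``inits`` has shape ``(n_chains, n_params)`` (raw scale).  Seeds derive
    per chain from ``seed`` via :class:`numpy.random.SeedSequence`, so output
    is fully determined by the arguments.
    """
    if n_burn >= n_iter:
        raise ValueError("burn-in must be shorter than the chain")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    inits = np.atleast_2d(np.asarray(inits, dtype=float))
    if inits.shape[0] != n_chains:
        raise ValueError("need one initial vector per chain")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_chains)
    out = []
    for c in range(n_chains):
        rng = np.random.default_rng(child[c])
        kept, _ = _run_single_chain(
            specs, components, inits[c], n_iter, n_burn, thin, n_adapt, rng
        )
        out.append(kept)
    return np.stack(out)


def rhat(draws: np.ndarray) -> float:
    """Classic Gelman–Rubin potential scale reduction factor.

    ``draws`` has shape (chains, samples); requires >= 2 chains of equal
    length.  R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean
    within-chain variance and B the between-chain variance of chain means.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("R-hat requires >= 2 chains (shape (chains, samples))")
    m, n = draws.shape
    if n < 2:
        raise ValueError("chains too short for R-hat")
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))
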