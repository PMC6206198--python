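"""Likelihood kernels for the joint dead-recovery / within-season-recapture model.

The dead-recovery component follows the Seber survival/reporting
parameterization: a bird alive at occasion ``t`` survives the year with
probability ``S``; if it dies, its band is found and reported with
probability ``r``.  Birds banded as juveniles use first-year parameters
(``S_j``, ``r_j``) for their first interval and adult parameters thereafter.
Each banded cohort contributes a multinomial over "first recovered at
occasion k" cells plus an implicit never-recovered cell.

Within-season recaptures and the juvenile fraction among new bandings add two
independent binomial components; because they share no parameters with the
recovery multinomials, their posteriors factorize (exploited by tests and by
conjugate cross-checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import BandingDataset, CollapsedMArray, MArray

__all__ = [
    "DemographicParams",
    "DerivedParams",
    "adult_cell_probs",
    "juvenile_cell_probs",
    "collapsed_cell_probs",
    "cell_prob_matrix",
    "recovery_loglik",
    "recapture_loglik",
    "age_composition_loglik",
    "derive",
]


def _as_prob_array(x, name: str) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if ((a < 0) | (a > 1)).any():
        raise ValueError(f"{name} must lie in [0, 1]")
    return a


@dataclass
class DemographicParams:
    """Parameters of the joint model; vectors may be length 1 (time-constant) or T.

    ``S_j``/``S_a``: first-year and adult annual survival; ``r_j``/``r_a``:
    recovery (reporting-given-death) probabilities; ``p_j``/``p_a``:
    within-season capture probabilities (age-specific constants); ``c_j``:
    probability a newly banded bird is a juvenile.
    """

    S_j: np.ndarray
    S_a: np.ndarray
    r_j: np.ndarray
    r_a: np.ndarray
    p_j: float
    p_a: float
    c_j: np.ndarray

    def __post_init__(self) -> None:
        self.S_j = _as_prob_array(self.S_j, "S_j")
        self.S_a = _as_prob_array(self.S_a, "S_a")
        self.r_j = _as_prob_array(self.r_j, "r_j")
        self.r_a = _as_prob_array(self.r_a, "r_a")
        self.c_j = _as_prob_array(self.c_j, "c_j")
        for name in ("p_j", "p_a"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
            setattr(self, name, v)

    @classmethod
    def constant(cls, S_j, S_a, r_j, r_a, p_j, p_a, c_j) -> "DemographicParams":
        return cls(
            np.atleast_1d(float(S_j)),
            np.atleast_1d(float(S_a)),
            np.atleast_1d(float(r_j)),
            np.atleast_1d(float(r_a)),
            float(p_j),
            float(p_a),
            np.atleast_1d(float(c_j)),
        )

    def expand(self, T: int) -> "DemographicParams":
        """Broadcast every time-indexed vector to length ``T``."""

        def bc(a: np.ndarray) -> np.ndarray:
            if len(a) == T:
                return a
            if len(a) == 1:
                return np.full(T, a[0])
            raise ValueError(f"parameter length {len(a)} incompatible with T={T}")

        return DemographicParams(
            bc(self.S_j), bc(self.S_a), bc(self.r_j), bc(self.r_a),
            self.p_j, self.p_a, bc(self.c_j),
        )

    @property
    def is_time_constant(self) -> bool:
        return all(
            len(a) == 1 for a in (self.S_j, self.S_a, self.r_j, self.r_a, self.c_j)
        )


@dataclass
class DerivedParams:
    """Derived quantities: vulnerability, fecundity, population growth."""

    V: float
    F: np.ndarray
    lam: np.ndarray


# ---------------------------------------------------------------------------
# multinomial cell probabilities


def adult_cell_probs(S_a, r_a, t: int, T: int) -> np.ndarray:
    """Recovery-cell probabilities for an adult cohort banded at occasion ``t``.

    Returns probabilities for occasions ``t..T-1`` (0-based) plus the
    never-recovered cell: the cohort member is first recovered at occasion
    ``k`` with probability ``prod(S_a[t:k]) * (1 - S_a[k]) * r_a[k]``.
    """
    if T <= t:
        raise ValueError("horizon must exceed cohort index")
    S_a = _as_prob_array(S_a, "S_a")
    r_a = _as_prob_array(r_a, "r_a")
    if len(S_a) == 1:
        S_a = np.full(T, S_a[0])
    if len(r_a) == 1:
        r_a = np.full(T, r_a[0])
    cells = np.empty(T - t + 1)
    alive = 1.0
    for k in range(t, T):
        cells[k - t] = alive * (1.0 - S_a[k]) * r_a[k]
        alive *= S_a[k]
    cells[-1] = 1.0 - cells[:-1].sum()
    return cells


def juvenile_cell_probs(S_j, r_j, S_a, r_a, t: int, T: int) -> np.ndarray:
    """Recovery-cell probabilities for a juvenile cohort banded at occasion ``t``.

    First interval uses first-year parameters (``S_j``, ``r_j``); survivors
    are adults thereafter.
    """
    if T <= t:
        raise ValueError("horizon must exceed cohort index")
    S_a = _as_prob_array(S_a, "S_a")
    r_a = _as_prob_array(r_a, "r_a")
    if len(S_a) == 1:
        S_a = np.full(T, S_a[0])
    if len(r_a) == 1:
        r_a = np.full(T, r_a[0])
    S_j = float(np.atleast_1d(S_j)[0]) if np.ndim(S_j) else float(S_j)
    r_j = float(np.atleast_1d(r_j)[0]) if np.ndim(r_j) else float(r_j)
    cells = np.empty(T - t + 1)
    cells[0] = (1.0 - S_j) * r_j
    alive = S_j
    for k in range(t + 1, T):
        cells[k - t] = alive * (1.0 - S_a[k]) * r_a[k]
        alive *= S_a[k]
    cells[-1] = 1.0 - cells[:-1].sum()
    return cells


def collapsed_cell_probs(params: DemographicParams, age_class: str, D: int) -> np.ndarray:
    """Lag-indexed cell probabilities (lags 1..D plus never) under constant rates.

    Adult lag-d cell: ``S_a**(d-1) * (1-S_a) * r_a``.  Juvenile lag-1:
    ``(1-S_j) * r_j``; lag d>=2: ``S_j * S_a**(d-2) * (1-S_a) * r_a``.
    """
    if D < 1:
        raise ValueError("max lag D must be >= 1")
    if not params.is_time_constant:
        raise ValueError("collapsed cell probabilities require time-constant parameters")
    S_a, r_a = params.S_a[0], params.r_a[0]
    cells = np.empty(D + 1)
    if age_class == "adult":
        for d in range(1, D + 1):
            cells[d - 1] = S_a ** (d - 1) * (1.0 - S_a) * r_a
    else:
        S_j, r_j = params.S_j[0], params.r_j[0]
        cells[0] = (1.0 - S_j) * r_j
        for d in range(2, D + 1):
            cells[d - 1] = S_j * S_a ** (d - 2) * (1.0 - S_a) * r_a
    cells[-1] = 1.0 - cells[:-1].sum()
    return cells


def cell_prob_matrix(m: MArray, params: DemographicParams) -> np.ndarray:
    """All-cohort cell probabilities for a square m-array.

    Returns shape ``(T, K+1)``: occasion cells then the never-recovered cell.
    Vectorized for parameters strictly inside (0, 1); falls back to exact
    per-cohort products at the boundary.
    """
    if not np.array_equal(m.occasion_years, m.cohort_years):
        raise ValueError("likelihood requires occasions aligned with cohort years")
    T = m.n_cohorts
    p = params.expand(T)
    S_a, r_a, S_j, r_j = p.S_a, p.r_a, p.S_j, p.r_j
    P = np.zeros((T, T + 1))
    interior = ((S_a > 0) & (S_a < 1)).all()
    if interior:
        Lpad = np.concatenate([[1.0], np.cumprod(S_a)])  # Lpad[k] = prod(S_a[:k])
        death = (1.0 - S_a) * r_a  # per occasion
        if m.age_class == "adult":
            # P[t, k] = Lpad[k]/Lpad[t] * death[k], k >= t
            ratio = Lpad[None, :-1] / Lpad[:, None][: T]
            P[:, :T] = np.triu(ratio * death[None, :])
        else:
            ratio = Lpad[None, :-1] / Lpad[1:, None]
            M = ratio * death[None, :] * S_j[:, None]
            M = np.triu(M, k=1)
            idx = np.arange(T)
            M[idx, idx] = (1.0 - S_j) * r_j
            P[:, :T] = M
    else:
        for t in range(T):
            if m.age_class == "adult":
                cells = adult_cell_probs(S_a, r_a, t, T)
            else:
                cells = juvenile_cell_probs(S_j[t], r_j[t], S_a, r_a, t, T)
            P[t, t:T] = cells[:-1]
    P[:, T] = 1.0 - P[:, :T].sum(axis=1)
    return P


# ---------------------------------------------------------------------------
# log-likelihoods


def _multinomial_ll(counts: np.ndarray, never: np.ndarray, probs: np.ndarray,
                    releases: np.ndarray) -> float:
    """Sum of per-cohort multinomial log-pmfs; ``probs`` includes the never cell."""
    full = np.column_stack([counts, never]).astype(float)
    mask = full > 0
    if (probs[mask] <= 0).any():
        return -np.inf
    const = (
        gammaln(releases + 1.0).sum()
        - gammaln(full + 1.0).sum()
    )
    return float(const + (full[mask] * np.log(probs[mask])).sum())


def _marray_ll(m: MArray, params: DemographicParams) -> float:
    P = cell_prob_matrix(m, params)
    return _multinomial_ll(m.recoveries, m.never_recovered, P, m.releases)


def _collapsed_ll(m: CollapsedMArray, params: DemographicParams, pooled: bool) -> float:
    if not params.is_time_constant:
        raise ValueError("collapsed m-arrays require time-constant parameters")
    D = m.max_lag
    q = collapsed_cell_probs(params, m.age_class, D)[:-1]  # lag cells only
    if pooled or m.lag_matrix is None:
        R = m.releases.sum()
        counts = m.lag_recoveries
        never = R - counts.sum()
        probs = np.concatenate([q, [1.0 - q.sum()]])
        return _multinomial_ll(counts[None, :], np.array([never]), probs[None, :],
                               np.array([float(R)]))
    # exact: each cohort truncated at its own maximum observable lag
    T = m.n_cohorts
    ll = 0.0
    for t in range(T):
        Dt = min(D, int(m.horizons[t]))
        counts = m.lag_matrix[t, :Dt]
        if m.lag_matrix[t, Dt:].any():
            raise ValueError(f"cohort {m.cohort_years[t]} has recoveries beyond its horizon")
        qt = q[:Dt]
        never = m.releases[t] - counts.sum()
        probs = np.concatenate([qt, [1.0 - qt.sum()]])
        ll += _multinomial_ll(counts[None, :], np.array([never]), probs[None, :],
                              np.array([float(m.releases[t])]))
    return ll


def recovery_loglik(
    juvenile: MArray | CollapsedMArray | None,
    adult: MArray | CollapsedMArray | None,
    params: DemographicParams,
    pooled_collapsed: bool = False,
) -> float:
    """Joint dead-recovery log-likelihood over juvenile and adult m-arrays.

    Additive over cohorts and age classes; returns ``-inf`` (never raises)
    when a zero-probability cell holds a nonzero count.  For collapsed
    m-arrays the default likelihood is the exact sum of per-cohort
    multinomials truncated at each cohort's own horizon (when per-cohort lag
    rows are available); ``pooled_collapsed=True`` selects the single pooled
    multinomial instead.
    """
    ll = 0.0
    for arr in (juvenile, adult):
        if arr is None:
            continue
        if isinstance(arr, MArray):
            ll += _marray_ll(arr, params)
        else:
            ll += _collapsed_ll(arr, params, pooled_collapsed)
    return ll


def _binom_logpmf(k: int, n: int, p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    if k < 0 or k > n:
        raise ValueError("count outside [0, n]")
    const = gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    with np.errstate(divide="ignore"):
        term1 = k * np.log(p) if k > 0 else 0.0
        term2 = (n - k) * np.log1p(-p) if n - k > 0 else 0.0
    return float(const + term1 + term2)


def recapture_loglik(rs, p_j: float, p_a: float) -> float:
    """Within-season recapture binomials: f2 ~ Bin(M, p) per age class."""
    if rs.f2_j > rs.M_j or rs.f2_a > rs.M_a:
        raise ValueError("f2 exceeds number banded")
    return _binom_logpmf(rs.f2_j, rs.M_j, p_j) + _binom_logpmf(rs.f2_a, rs.M_a, p_a)


def age_composition_loglik(M_j, M_a, c_j) -> float:
    """Juvenile fraction binomial: M_j ~ Bin(M_j + M_a, c_j).

    ``M_j``/``M_a``/``c_j`` may be per-year vectors (summed over years).
    """
    M_j = np.atleast_1d(np.asarray(M_j, dtype=int))
    M_a = np.atleast_1d(np.asarray(M_a, dtype=int))
    if (M_j < 0).any() or (M_a < 0).any():
        raise ValueError("negative banding counts")
    c = np.atleast_1d(np.asarray(c_j, dtype=float))
    if len(c) == 1:
        c = np.full(len(M_j), c[0])
    return float(sum(_binom_logpmf(int(mj), int(mj + ma), float(ci))
                     for mj, ma, ci in zip(M_j, M_a, c)))


def derive(params: DemographicParams) -> DerivedParams:
    """Derived parameters: V = p_j/p_a, F_t = [c_t/(1-c_t)]/V, lambda_t = S_a,t + F_t*S_j,t."""
    if params.p_a <= 0:
        raise ValueError("p_a must be positive to define vulnerability")
    if (params.c_j >= 1).any():
        raise ValueError("c_j must be < 1 to define the age ratio")
    V = params.p_j / params.p_a
    F = (params.c_j / (1.0 - params.c_j)) / V
    S_a, S_j, F = np.broadcast_arrays(params.S_a, params.S_j, F)
    lam = S_a + F * S_j
    return DerivedParams(V=float(V), F=np.array(F, dtype=float), lam=np.array(lam, dtype=float))
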