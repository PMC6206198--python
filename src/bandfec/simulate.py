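"""Replicate generator for the estimator-performance study.

Each replicate emulates a 24-year banding program on a stationary population:
fixed numbers of juveniles and adults are available for capture each autumn
(``N_j``, ``N_a``, whose ratio fixes true fecundity ``F = N_j/N_a``), each is
banded with an age-specific capture probability, banded birds can be
recaptured once more within the season with the same probability, and each
banded cohort's dead recoveries follow the Seber cell probabilities (first
interval at juvenile rates, adult rates thereafter).  Survival and fecundity
truths are held at S_a = 0.60, S_j = 0.50, F = 0.80 (so lambda = 1), while
recovery and capture probabilities are drawn fresh per replicate from uniform
ranges to sweep the amount of data: r_j ~ U[0.0001, 0.4],
r_a ~ U[0.0001, 0.2], p_a ~ U[0.0001, 0.02] and V ~ U[0.5, 1.5] with
p_j = V * p_a.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chao import ChaoUndefinedError, adjusted_fecundity, naive_fecundity, vulnerability_from_ratio
from .data import BandingDataset, MArray, RecaptureSummary
from .likelihood import adult_cell_probs, juvenile_cell_probs
from .model import MCMCSettings, TagRecoveryModel

__all__ = ["SimConfig", "ReplicateParams", "SimReplicate", "draw_replicate_params",
           "simulate_dataset", "run_study"]


@dataclass(frozen=True)
class SimConfig:
    """Study design: truths, population sizes, parameter ranges, seeding."""

    n_replicates: int = 1000
    n_years: int = 24
    S_a: float = 0.60
    S_j: float = 0.50
    F: float = 0.80
    N_j: int = 240_000
    N_a: int = 300_000
    r_j_range: tuple[float, float] = (0.0001, 0.4)
    r_a_range: tuple[float, float] = (0.0001, 0.2)
    p_a_range: tuple[float, float] = (0.0001, 0.02)
    V_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0
    redraw_each_year: bool = False

    def __post_init__(self) -> None:
        if abs(self.F - self.N_j / self.N_a) > 1e-9:
            raise ValueError(
                f"inconsistent truths: F={self.F} but N_j/N_a={self.N_j / self.N_a}"
            )
        for name in ("r_j_range", "r_a_range", "p_a_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must lie within [0, 1]")

    @property
    def lam(self) -> float:
        return self.S_a + self.F * self.S_j


@dataclass(frozen=True)
class ReplicateParams:
    """Encounter-rate parameters drawn for one replicate."""

    r_j: float
    r_a: float
    p_a: float
    V: float

    @property
    def p_j(self) -> float:
        return self.V * self.p_a


@dataclass
class SimReplicate:
    """One generated dataset with its truths and encounter tallies."""

    index: int
    params: ReplicateParams
    dataset: BandingDataset
    tallies: dict[str, int]
    truths: dict[str, float]


def _replicate_rng(config: SimConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(index,))
    )


def draw_replicate_params(config: SimConfig, index: int) -> ReplicateParams:
    """Uniform draws for one replicate, reproducible from (master seed, index)."""
    rng = _replicate_rng(config, index)
    return _draw_params(config, rng)


def _draw_params(config: SimConfig, rng: np.random.Generator) -> ReplicateParams:
    return ReplicateParams(
        r_j=float(rng.uniform(*config.r_j_range)),
        r_a=float(rng.uniform(*config.r_a_range)),
        p_a=float(rng.uniform(*config.p_a_range)),
        V=float(rng.uniform(*config.V_range)),
    )


def simulate_dataset(
    params: ReplicateParams,
    config: SimConfig,
    rng: np.random.Generator,
    index: int = 0,
) -> SimReplicate:
    """Generate one replicate's m-arrays and pooled recapture summary.

    Banding totals arise as M_t ~ Bin(N, p) per year; within-season second
    captures as f2_t ~ Bin(M_t, p); dead recoveries per cohort follow the
    Seber multinomial cells truncated at the study horizon.
    """
    T = config.n_years
    years = np.arange(1, T + 1)
    if config.redraw_each_year:
        per_year = [_draw_params(config, rng) for _ in range(T)]
    else:
        per_year = [params] * T
    p_j = np.array([pp.p_j for pp in per_year])
    p_a = np.array([pp.p_a for pp in per_year])
    r_j = np.array([pp.r_j for pp in per_year])
    r_a = np.array([pp.r_a for pp in per_year])
    S_j = np.full(T, config.S_j)
    S_a = np.full(T, config.S_a)

    M_j_t = rng.binomial(config.N_j, p_j)
    f2_j_t = rng.binomial(M_j_t, p_j)
    M_a_t = rng.binomial(config.N_a, p_a)
    f2_a_t = rng.binomial(M_a_t, p_a)

    m_juv = np.zeros((T, T), dtype=int)
    m_ad = np.zeros((T, T), dtype=int)
    for t in range(T):
        cells_j = juvenile_cell_probs(S_j[t], r_j[t], S_a, r_a, t, T)
        draw = rng.multinomial(M_j_t[t], cells_j)
        m_juv[t, t:] = draw[:-1]
        cells_a = adult_cell_probs(S_a, r_a, t, T)
        draw = rng.multinomial(M_a_t[t], cells_a)
        m_ad[t, t:] = draw[:-1]

    rs = RecaptureSummary.from_counts(
        int(M_j_t.sum()), int(f2_j_t.sum()), int(M_a_t.sum()), int(f2_a_t.sum())
    )
    ds = BandingDataset(
        juvenile=MArray("juvenile", years, M_j_t, m_juv),
        adult=MArray("adult", years, M_a_t, m_ad),
        recaptures=rs,
        label=f"replicate-{index}",
    )
    first_year_j = int(np.trace(m_juv))
    tallies = {
        "M_j_total": int(M_j_t.sum()),
        "M_a_total": int(M_a_t.sum()),
        "f2_j": int(f2_j_t.sum()),
        "f2_a": int(f2_a_t.sum()),
        "f2_total": int(f2_j_t.sum() + f2_a_t.sum()),
        "rec_j_first": first_year_j,
        "rec_j_later": int(m_juv.sum() - first_year_j),
        "rec_j_total": int(m_juv.sum()),
        "rec_a_total": int(m_ad.sum()),
        "rec_total": int(m_juv.sum() + m_ad.sum()),
    }
    truths = {
        "S_j": config.S_j, "S_a": config.S_a, "F": config.F, "lambda": config.lam,
        "r_j": params.r_j, "r_a": params.r_a, "p_j": params.p_j, "p_a": params.p_a,
        "V": params.V,
    }
    return SimReplicate(index, params, ds, tallies, truths)


def make_replicate(config: SimConfig, index: int) -> SimReplicate:
    """Draw parameters and generate the dataset for replicate ``index``."""
    rng = _replicate_rng(config, index)
    params = _draw_params(config, rng)
    return simulate_dataset(params, config, rng, index)


def _estimate(
    rep: SimReplicate,
    estimator: str,
    config: SimConfig,
    mcmc_settings: MCMCSettings | None = None,
) -> dict[str, float]:
    rs = rep.dataset.recaptures
    if estimator == "chao":
        F_hat = adjusted_fecundity(rs)
        return {
            "F": F_hat,
            "V": vulnerability_from_ratio(rs.M_j, rs.M_a, F_hat),
            "naive_F": naive_fecundity(rs.M_j, rs.M_a),
        }
    if estimator == "mle":
        model = TagRecoveryModel(rep.dataset)
        est = model.fit_mle()
        est["naive_F"] = naive_fecundity(rs.M_j, rs.M_a)
        est.pop("converged", None)
        return est
    if estimator == "bayes":
        model = TagRecoveryModel(rep.dataset)
        # per-replicate seed derived from the replicate stream, < 2**31
        seed = int(
            _replicate_rng(config, rep.index).integers(0, 2**31 - 1)
        )
        base = mcmc_settings or MCMCSettings.reduced()
        from dataclasses import replace as _replace

        res = model.fit(_replace(base, seed=seed))
        pts = res.point_estimates()
        keep = ("S_j", "S_a", "r_j", "r_a", "p_j", "p_a", "V", "F", "lambda")
        out = {k: pts[k] for k in keep if k in pts}
        out["naive_F"] = naive_fecundity(rs.M_j, rs.M_a)
        return out
    raise ValueError(f"unknown estimator {estimator!r}")


def run_study(
    config: SimConfig,
    estimator: str = "chao",
    replicates: Iterable[int] | None = None,
    mcmc_settings: MCMCSettings | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Generate and fit replicates; one row per replicate.

    Columns: ``truth_*`` (true values), ``drawn_*`` (replicate-level rates),
    encounter tallies, ``est_*`` point estimates (NaN on failure), ``ok`` and
    ``note``.  ``replicates`` selects an index subset (the per-replicate seed
    depends only on the master seed and index, so partial runs are resumable
    and order-independent).
    """
    idx = list(replicates) if replicates is not None else list(range(config.n_replicates))
    rows = []
    for i in idx:
        rep = make_replicate(config, i)
        row: dict[str, object] = {"rep": i}
        row.update({f"truth_{k}": v for k, v in rep.truths.items()})
        row.update({f"drawn_{k}": v for k, v in asdict(rep.params).items()})
        row["drawn_p_j"] = rep.params.p_j
        row.update(rep.tallies)
        try:
            est = _estimate(rep, estimator, config, mcmc_settings)
        except (ChaoUndefinedError, ValueError, ZeroDivisionError) as exc:
            row["ok"] = False
            row["note"] = str(exc)
        else:
            row.update({f"est_{k}": v for k, v in est.items()})
            row["ok"] = True
            row["note"] = ""
        rows.append(row)
        if progress and (len(rows) % 25 == 0):  # pragma: no cover - cosmetic
            print(f"  replicate {len(rows)}/{len(idx)}", flush=True)
    return pd.DataFrame(rows)
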