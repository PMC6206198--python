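"""Joint Bayesian model for survival, fecundity and population growth.

:class:`TagRecoveryModel` is built from a :class:`~bandfec.data.BandingDataset`
and assembles whichever likelihood components the data support:

* dead-recovery multinomials (juvenile + adult m-arrays) for survival
  ``S_j, S_a`` and recovery probabilities ``r_j, r_a``;
* within-season recapture binomials for capture probabilities ``p_j, p_a``;
* the age-composition binomial for the juvenile fraction ``c_j``.

``fit()`` samples the posterior with an adaptive Metropolis-within-Gibbs
sampler and returns :class:`TagRecoveryResults`, which carries per-draw
derived parameters — relative vulnerability ``V = p_j/p_a``, fecundity
``F_t = [c_t/(1-c_t)]/V`` and population growth ``lambda_t = S_a,t +
F_t S_j,t`` — along with posterior summaries (mean, SD, CV, 90% credible
interval) and the Gelman–Rubin diagnostic per parameter.

Time-constant parameters carry Uniform(0,1) priors on the probability scale;
parameters placed on the temporal list become logit-normal year effects with
hyper-priors mean ~ Uniform(-2, 2) and SD ~ Uniform(0, 2) (non-centered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .data import BandingDataset, CollapsedMArray, MArray, RecaptureSummary
from .likelihood import DemographicParams, recovery_loglik
from .sampler import Component, ParamSpec, rhat, run_chains

__all__ = ["PriorSpec", "MCMCSettings", "TagRecoveryModel", "TagRecoveryResults"]

_RECOVERY_BASES = ("S_j", "S_a", "r_j", "r_a")
_DISPLAY = {
    "S_j": "S.juv", "S_a": "S.ad", "r_j": "r.juv", "r_a": "r.ad",
    "p_j": "p.juv", "p_a": "p.ad", "V": "V", "age_ratio": "Mj/Ma",
    "F": "F", "lambda": "lambda", "c_j": "c.juv",
}


@dataclass(frozen=True)
class PriorSpec:
    """Prior bounds: Uniform(0,1) for constants; logit-scale hyper-priors for
    temporal parameters (mean ~ U(mu_lo, mu_hi), SD ~ U(sd_lo, sd_hi))."""

    mu_lo: float = -2.0
    mu_hi: float = 2.0
    sd_lo: float = 0.0
    sd_hi: float = 2.0


@dataclass(frozen=True)
class MCMCSettings:
    """Chain schedule.  Defaults follow the data-rich (pintail-scale) run:
    3 chains x 25,000 iterations, 5,000 burn-in, thin 10, 1,000 adaptation."""

    n_chains: int = 3
    n_iter: int = 25_000
    n_burn: int = 5_000
    thin: int = 10
    n_adapt: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_iter:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def sparse(cls, seed: int = 0) -> "MCMCSettings":
        """Ten-fold longer schedule for sparse data (junco-scale)."""
        return cls(3, 250_000, 50_000, 10, 10_000, seed)

    @classmethod
    def reduced(cls, seed: int = 0) -> "MCMCSettings":
        """Short schedule for simulation studies and smoke tests."""
        return cls(3, 5_000, 1_000, 5, 1_000, seed)


class TagRecoveryModel:
    """Joint dead-recovery + within-season-recapture model.

    Parameters
    ----------
    data : BandingDataset
        Any subset of {juvenile m-array, adult m-array, recapture summary}.
    temporal : iterable of str
        Subset of {"S_j","S_a","r_j","r_a","c_j"} given logit-normal year
        effects; requires full (uncollapsed) m-arrays with >= 2 cohorts.
        Capture probabilities are age-specific constants in all models.
    priors : PriorSpec
    pooled_collapsed : bool
        Use the single pooled multinomial for collapsed m-arrays instead of
        the exact per-cohort form.
    """

    def __init__(
        self,
        data: BandingDataset,
        temporal: tuple[str, ...] = (),
        priors: PriorSpec | None = None,
        pooled_collapsed: bool = False,
    ) -> None:
        self.data = data
        self.priors = priors or PriorSpec()
        self.pooled_collapsed = pooled_collapsed
        self.temporal = tuple(temporal)
        bad = set(self.temporal) - {"S_j", "S_a", "r_j", "r_a", "c_j"}
        if bad:
            raise ValueError(f"cannot place year effects on {sorted(bad)}")

        self.has_recovery = data.juvenile is not None or data.adult is not None
        self.has_recapture = data.recaptures is not None
        self.has_agecomp = data.banding_totals is not None
        if not (self.has_recovery or self.has_recapture or self.has_agecomp):
            raise ValueError("dataset carries no usable likelihood component")
        self.T = data.n_occasions
        if self.temporal:
            collapsed = isinstance(data.juvenile, CollapsedMArray) or isinstance(
                data.adult, CollapsedMArray
            )
            if collapsed:
                raise ValueError("temporal model requires full (uncollapsed) m-arrays")
            if self.T < 2:
                raise ValueError("temporal model requires >=2 cohorts")
        self._build_layout()

    # ------------------------------------------------------------------
    # parameter layout and likelihood components

    def _active_bases(self) -> list[str]:
        bases: list[str] = []
        if self.has_recovery:
            bases += list(_RECOVERY_BASES)
        if self.has_recapture:
            bases += ["p_j", "p_a"]
        if self.has_agecomp:
            bases += ["c_j"]
        return bases

    def _build_layout(self) -> None:
        pr = self.priors
        self.specs: list[ParamSpec] = []
        self._scalar_idx: dict[str, int] = {}
        self._temporal_idx: dict[str, tuple[int, int, np.ndarray]] = {}
        for base in self._active_bases():
            if base in self.temporal:
                i_mu = len(self.specs)
                self.specs.append(
                    ParamSpec(f"mu_{base}", "uniform", 0.0, pr.mu_lo, pr.mu_hi, step=0.2)
                )
                i_sd = len(self.specs)
                self.specs.append(
                    ParamSpec(f"sd_{base}", "uniform", 0.2, pr.sd_lo, pr.sd_hi, step=0.2)
                )
                z_idx = np.arange(len(self.specs), len(self.specs) + self.T)
                for t in range(self.T):
                    self.specs.append(ParamSpec(f"z_{base}[{t}]", "normal", 0.0))
                self._temporal_idx[base] = (i_mu, i_sd, z_idx)
            else:
                self._scalar_idx[base] = len(self.specs)
                self.specs.append(ParamSpec(base, "logit-unit", 0.0))
        self.n_params = len(self.specs)
        self.components = self._build_components()

    def _vec(self, base: str, x: np.ndarray) -> np.ndarray:
        """Constrained time-vector (length T or 1) for one parameter."""
        if base in self._temporal_idx:
            i_mu, i_sd, z_idx = self._temporal_idx[base]
            return expit(x[i_mu] + x[i_sd] * x[z_idx])
        return np.array([x[self._scalar_idx[base]]])

    def _build_components(self) -> list[Component]:
        comps: list[Component] = []
        if self.has_recovery:
            idx: list[int] = []
            for base in _RECOVERY_BASES:
                if base in self._temporal_idx:
                    i_mu, i_sd, z_idx = self._temporal_idx[base]
                    idx += [i_mu, i_sd, *z_idx.tolist()]
                else:
                    idx.append(self._scalar_idx[base])
            juv, ad = self.data.juvenile, self.data.adult
            pooled = self.pooled_collapsed

            def recovery_fn(x: np.ndarray) -> float:
                params = DemographicParams(
                    self._vec("S_j", x), self._vec("S_a", x),
                    self._vec("r_j", x), self._vec("r_a", x),
                    0.5, 0.5, np.array([0.5]),
                )
                return recovery_loglik(juv, ad, params, pooled)

            comps.append(Component("recovery", tuple(idx), recovery_fn))
        if self.has_recapture:
            rs = self.data.recaptures
            i_pj, i_pa = self._scalar_idx["p_j"], self._scalar_idx["p_a"]
            cj = float(
                gammaln(rs.M_j + 1) - gammaln(rs.f2_j + 1) - gammaln(rs.M_j - rs.f2_j + 1)
            )
            ca = float(
                gammaln(rs.M_a + 1) - gammaln(rs.f2_a + 1) - gammaln(rs.M_a - rs.f2_a + 1)
            )
            f2j, n1j = rs.f2_j, rs.M_j - rs.f2_j
            f2a, n1a = rs.f2_a, rs.M_a - rs.f2_a

            def recapture_fn(x: np.ndarray) -> float:
                pj, pa = x[i_pj], x[i_pa]
                return (
                    cj + f2j * math.log(pj) + n1j * math.log1p(-pj)
                    + ca + f2a * math.log(pa) + n1a * math.log1p(-pa)
                )

            comps.append(Component("recapture", (i_pj, i_pa), recapture_fn))
        if self.has_agecomp:
            if "c_j" in self._temporal_idx:
                Mjt = self.data.juvenile.releases.astype(float)
                Mat = self.data.adult.releases.astype(float)
                i_mu, i_sd, z_idx = self._temporal_idx["c_j"]
                const = float(
                    (gammaln(Mjt + Mat + 1) - gammaln(Mjt + 1) - gammaln(Mat + 1)).sum()
                )

                def agecomp_fn(x: np.ndarray) -> float:
                    c = expit(x[i_mu] + x[i_sd] * x[z_idx])
                    return const + float((Mjt * np.log(c) + Mat * np.log1p(-c)).sum())

                idx = (i_mu, i_sd, *z_idx.tolist())
            else:
                Mj, Ma = self.data.banding_totals
                i_c = self._scalar_idx["c_j"]
                const = float(gammaln(Mj + Ma + 1) - gammaln(Mj + 1) - gammaln(Ma + 1))

                def agecomp_fn(x: np.ndarray) -> float:
                    c = x[i_c]
                    return const + Mj * math.log(c) + Ma * math.log1p(-c)

                idx = (i_c,)
            comps.append(Component("agecomp", idx, agecomp_fn))
        return comps

    # ------------------------------------------------------------------

    def loglike(self, params: DemographicParams) -> float:
        """Joint log-likelihood at given parameter values (all active components)."""
        from .likelihood import age_composition_loglik, recapture_loglik

        ll = 0.0
        if self.has_recovery:
            ll += recovery_loglik(
                self.data.juvenile, self.data.adult, params, self.pooled_collapsed
            )
        if self.has_recapture:
            ll += recapture_loglik(self.data.recaptures, params.p_j, params.p_a)
        if self.has_agecomp:
            if len(params.c_j) > 1 and self.data.juvenile is not None:
                ll += age_composition_loglik(
                    self.data.juvenile.releases, self.data.adult.releases, params.c_j
                )
            else:
                Mj, Ma = self.data.banding_totals
                ll += age_composition_loglik(Mj, Ma, params.c_j[0])
        return ll

    def _initial_values(self) -> dict[str, float]:
        """Crude data-driven starting points on the probability scale."""
        init: dict[str, float] = {b: 0.5 for b in self._active_bases()}
        rs = self.data.recaptures
        if rs is not None:
            init["p_j"] = (rs.f2_j + 1) / (rs.M_j + 2)
            init["p_a"] = (rs.f2_a + 1) / (rs.M_a + 2)
        tot = self.data.banding_totals
        if tot is not None:
            init["c_j"] = (tot[0] + 1) / (tot[0] + tot[1] + 2)
        for arr, rbase in ((self.data.juvenile, "r_j"), (self.data.adult, "r_a")):
            if arr is not None:
                frac = arr.total_recoveries() / max(1, int(arr.releases.sum()))
                init[rbase] = float(np.clip(2.0 * frac + 1e-6, 1e-5, 0.5))
        return init

    def _chain_inits(self, n_chains: int, rng: np.random.Generator) -> np.ndarray:
        base_init = self._initial_values()
        inits = np.zeros((n_chains, self.n_params))
        for c in range(n_chains):
            for base, i in self._scalar_idx.items():
                inits[c, i] = logit(base_init[base]) + 0.3 * rng.standard_normal()
            for base, (i_mu, i_sd, z_idx) in self._temporal_idx.items():
                mu0 = float(np.clip(logit(base_init[base]), self.priors.mu_lo + 0.1,
                                    self.priors.mu_hi - 0.1))
                inits[c, i_mu] = mu0 + 0.1 * rng.standard_normal()
                inits[c, i_mu] = float(
                    np.clip(inits[c, i_mu], self.priors.mu_lo + 1e-3, self.priors.mu_hi - 1e-3)
                )
                inits[c, i_sd] = float(rng.uniform(0.05, 0.3))
                inits[c, z_idx] = 0.1 * rng.standard_normal(len(z_idx))
        return inits

    def fit(self, settings: MCMCSettings | None = None) -> "TagRecoveryResults":
        """Sample the posterior; returns results with draws and summaries."""
        st = settings or MCMCSettings()
        rng = np.random.default_rng(np.random.SeedSequence(st.seed).spawn(1)[0])
        inits = self._chain_inits(st.n_chains, rng)
        X = run_chains(
            self.specs, self.components, inits,
            st.n_chains, st.n_iter, st.n_burn, st.thin, st.n_adapt, st.seed,
        )
        return TagRecoveryResults(self, X, st)

    def fit_mle(self) -> dict[str, float]:
        """Maximum-likelihood point estimates (time-constant models only).

        Optimizes the joint log-likelihood on the logit scale; returns a dict
        of parameter estimates including derived V, F and lambda.
        """
        if self.temporal:
            raise ValueError("MLE fitting supports time-constant models only")
        bases = self._active_bases()
        init = self._initial_values()
        x0 = np.array([logit(init[b]) for b in bases])

        def negll(theta: np.ndarray) -> float:
            x = np.zeros(self.n_params)
            for b, v in zip(bases, theta):
                x[self._scalar_idx[b]] = expit(v)
            return -sum(c.fn(x) for c in self.components)

        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
        est = {b: float(expit(v)) for b, v in zip(bases, res.x)}
        if "p_j" in est and "p_a" in est:
            est["V"] = est["p_j"] / est["p_a"]
            if "c_j" in est:
                est["F"] = est["c_j"] / (1 - est["c_j"]) / est["V"]
                if "S_a" in est:
                    est["lambda"] = est["S_a"] + est["F"] * est["S_j"]
        est["converged"] = bool(res.success)
        return est


class TagRecoveryResults:
    """Posterior draws, summaries and derived parameters for a fitted model.

    Draw arrays are indexed ``(chain, sample)`` for scalar quantities and
    ``(chain, sample, year)`` for temporal ones.
    """

    def __init__(self, model: TagRecoveryModel, X: np.ndarray, settings: MCMCSettings):
        self.model = model
        self.settings = settings
        self._X = X  # (chains, kept, params)
        self.quantities: dict[str, np.ndarray] = {}
        self._extract()

    # ------------------------------------------------------------------

    def _extract(self) -> None:
        m = self.model
        X = self._X
        q = self.quantities
        for base, i in m._scalar_idx.items():
            q[base] = X[:, :, i]
        for base, (i_mu, i_sd, z_idx) in m._temporal_idx.items():
            q[f"mu_{base}"] = X[:, :, i_mu]
            q[f"sd_{base}"] = X[:, :, i_sd]
            q[base] = expit(
                X[:, :, i_mu][..., None] + X[:, :, i_sd][..., None] * X[:, :, z_idx]
            )
        if "p_j" in q and "p_a" in q:
            q["V"] = q["p_j"] / q["p_a"]
        if "c_j" in q:
            c = q["c_j"]
            q["age_ratio"] = c / (1.0 - c)
            if "V" in q:
                V = q["V"]
                q["F"] = q["age_ratio"] / (V[..., None] if c.ndim == 3 else V)
        if "F" in q and "S_a" in q and "S_j" in q:
            F, Sa, Sj = q["F"], q["S_a"], q["S_j"]
            if F.ndim == 3 or Sa.ndim == 3:
                if F.ndim == 2:
                    F = F[..., None]
                if Sa.ndim == 2:
                    Sa, Sj = Sa[..., None], Sj[..., None]
                elif Sj.ndim == 2:
                    Sj = Sj[..., None]
            q["lambda"] = Sa + F * Sj

    # ------------------------------------------------------------------

    @property
    def n_draws(self) -> int:
        return self._X.shape[0] * self._X.shape[1]

    def draws(self, name: str) -> np.ndarray:
        """Pooled posterior draws of a quantity (chains stacked)."""
        a = self.quantities[name]
        return a.reshape(-1, *a.shape[2:])

    def rhats(self) -> dict[str, float]:
        """Gelman–Rubin diagnostic per scalar quantity (max over years if temporal)."""
        out: dict[str, float] = {}
        for name, a in self.quantities.items():
            if a.shape[0] < 2:
                out[name] = float("nan")
            elif a.ndim == 2:
                out[name] = rhat(a)
            else:
                out[name] = float(max(rhat(a[:, :, t]) for t in range(a.shape[2])))
        return out

    @property
    def converged(self) -> bool:
        return all(v < 1.01 for v in self.rhats().values())

    # ------------------------------------------------------------------

    def summary(self, formatted: bool = False) -> pd.DataFrame:
        """Posterior summary table: mean, SD, CV = SD/mean, 90% CRI, R-hat.

        Temporal quantities are summarized by the across-year mean of annual
        posterior means, with ``sd_t`` the across-year SD of those means.
        """
        rhats = self.rhats()
        rows = []
        order = ["S_j", "S_a", "r_j", "r_a", "p_j", "p_a", "V", "age_ratio", "F", "lambda"]
        for name in order:
            if name not in self.quantities:
                continue
            a = self.quantities[name]
            row: dict[str, object] = {"parameter": _DISPLAY.get(name, name)}
            if a.ndim == 2:
                flat = a.reshape(-1)
                row.update(
                    mean=flat.mean(), sd=flat.std(ddof=1),
                    q5=np.quantile(flat, 0.05), q95=np.quantile(flat, 0.95),
                )
                row["cv"] = row["sd"] / row["mean"] if row["mean"] != 0 else np.nan
                row["sd_t"] = np.nan
            else:
                annual_means = a.reshape(-1, a.shape[2]).mean(axis=0)
                flat = a.reshape(-1, a.shape[2]).mean(axis=1)  # per-draw across-year mean
                row.update(
                    mean=annual_means.mean(), sd=flat.std(ddof=1),
                    q5=np.quantile(flat, 0.05), q95=np.quantile(flat, 0.95),
                )
                row["cv"] = row["sd"] / row["mean"] if row["mean"] != 0 else np.nan
                row["sd_t"] = annual_means.std(ddof=1) if a.shape[2] > 1 else 0.0
            row["rhat"] = rhats[name]
            rows.append(row)
        df = pd.DataFrame(rows).set_index("parameter")
        if formatted:
            return df.map(lambda v: f"{v:.4g}" if np.isfinite(v) else "")
        return df

    def annual_summary(self, name: str) -> pd.DataFrame:
        """Per-year posterior mean/SD/CRI for a temporal quantity."""
        a = self.quantities[name]
        if a.ndim != 3:
            raise ValueError(f"{name} is not temporal")
        flat = a.reshape(-1, a.shape[2])
        return pd.DataFrame(
            {
                "year": np.arange(1, a.shape[2] + 1),
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q5": np.quantile(flat, 0.05, axis=0),
                "q95": np.quantile(flat, 0.95, axis=0),
            }
        ).set_index("year")

    def sd_t(self, name: str, method: str = "across-years") -> float:
        """Annual variation of a temporal quantity.

        ``"across-years"``: SD across years of the annual posterior means
        (the default reporting convention here); ``"hyper"``: posterior mean
        of the logit-scale hyper-SD.
        """
        if method == "hyper":
            return float(self.draws(f"sd_{name}").mean())
        a = self.quantities[name]
        if a.ndim != 3:
            raise ValueError(f"{name} is not temporal")
        return float(a.reshape(-1, a.shape[2]).mean(axis=0).std(ddof=1))

    def corr_lambda_F(self) -> float:
        """Pearson correlation between annual posterior means of lambda_t and F_t."""
        lam, F = self.quantities.get("lambda"), self.quantities.get("F")
        if lam is None or F is None or lam.ndim != 3 or F.ndim != 3:
            raise ValueError("annual lambda and F require a temporal fit")
        lam_t = lam.reshape(-1, lam.shape[2]).mean(axis=0)
        F_t = F.reshape(-1, F.shape[2]).mean(axis=0)
        return float(np.corrcoef(lam_t, F_t)[0, 1])

    def point_estimates(self) -> dict[str, float]:
        """Posterior means of scalar quantities (time-averaged if temporal)."""
        out = {}
        for name, a in self.quantities.items():
            out[name] = float(a.mean())
        return out
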