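"""Hierarchical Bayesian Bernoulli-logit model of prey-DNA detection.

The response is the binary detection of prey species *s* in a subsample of
scat *i* at degradation day *j*:

    Y[s,i,j] ~ Bernoulli(p[s,i,j])
    logit p  = beta0[s] + beta1[s]*pr0 + beta2[s]*pr1 + beta3[s]*pr2
               + beta4[s]*pr3 + beta5*degradation_day + beta6*individual
               + alpha[i]

where pr0..pr3 are the proportions of species *s* in the individual's
ration on the defecation day and the three preceding days, and alpha[i] is
a per-scat random intercept absorbing the repeated subsampling of each
scat.

Priors: the five species-indexed coefficient families beta0..beta4 are
pooled hierarchically, beta_k[s] ~ N(mu_k, sigma_k^2), with
mu_k ~ N(0, 100) and sigma_k ~ Uniform(0, 10); alpha[i] ~ N(0,
sigma_alpha^2) with sigma_alpha ~ Uniform(0, 10); the non-species
coefficients beta5 (degradation) and beta6 (individual) get N(0, 100)
priors directly, since each is a single scalar and pooling needs at least
two exchangeable units.

Inference is by adaptive Metropolis-within-Gibbs: every scalar gets a
Gaussian random-walk proposal whose step size is tuned toward a 30-45%
acceptance rate during burn-in and then frozen; the hyper-means mu_k are
updated by conjugate Gibbs draws; the standard deviations are updated on
the log scale (with the Jacobian term) with the proposal reflected below
the Uniform(0, 10) upper bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ModelInput
from .exceptions import ConfigurationError, InputError

__all__ = [
    "ParameterState",
    "PosteriorDraws",
    "ConvergenceReport",
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "gelman_rubin",
    "summarize_posterior",
    "headline_summary",
]

_N_FAMILIES = 5          # beta0..beta4 are species-indexed
_HYPER_SD = 10.0         # N(0, 100) prior: variance 100, SD 10
_SIGMA_UPPER = 10.0      # Uniform(0, 10) prior on all standard deviations
_LOG_SIGMA_UPPER = math.log(_SIGMA_UPPER)


@dataclass
class ParameterState:
    """One point in parameter space.

    ``beta0`` .. ``beta4`` are arrays over species; ``alpha`` over scats;
    ``mu`` and ``sigma`` hold the five hyper-means / hyper-SDs of the
    species-indexed families.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    beta4: np.ndarray
    beta5: float
    beta6: float
    alpha: np.ndarray
    mu: np.ndarray = field(default_factory=lambda: np.zeros(_N_FAMILIES))
    sigma: np.ndarray = field(default_factory=lambda: np.ones(_N_FAMILIES))
    sigma_alpha: float = 1.0

    def betas(self) -> np.ndarray:
        """Stacked (5, S) coefficient array."""
        return np.stack([self.beta0, self.beta1, self.beta2, self.beta3, self.beta4])


def _linear_predictor(state: ParameterState, data: ModelInput) -> np.ndarray:
    s = data.species_index - 1
    i = data.scat_index - 1
    return (
        state.beta0[s]
        + state.beta1[s] * data.pr0
        + state.beta2[s] * data.pr1
        + state.beta3[s] * data.pr2
        + state.beta4[s] * data.pr3
        + state.beta5 * data.degradation_day
        + state.beta6 * data.individual
        + state.alpha[i]
    )


def log_likelihood(state: ParameterState, data: ModelInput) -> float:
    """Bernoulli log likelihood, stable for linear predictors of any size.

    Uses sum(y * eta - log(1 + exp(eta))) with log1p-exp evaluated via
    ``np.logaddexp``, so |eta| up to the overflow limit of double
    precision (~700 and far beyond) stays finite.  Per-row terms are
    accumulated with exact (fsum) summation, so the result is invariant
    to row permutations bit for bit.
    """
    S = len(data.species_labels)
    for k in range(_N_FAMILIES):
        if getattr(state, f"beta{k}").shape != (S,):
            raise InputError(f"beta{k} length does not match species count {S}")
    if state.alpha.shape != (len(data.scat_labels),):
        raise InputError("alpha length does not match scat count")
    eta = _linear_predictor(state, data)
    return math.fsum(data.y * eta - np.logaddexp(0.0, eta))


def log_prior(state: ParameterState, hierarchical: bool = True,
              scat_effects: bool = True) -> float:
    """Joint log prior density; -inf outside the support of the
    Uniform(0, 10) SD priors."""
    lp = 0.0
    if hierarchical:
        if np.any(state.sigma <= 0) or np.any(state.sigma > _SIGMA_UPPER):
            return -np.inf
        lp += norm.logpdf(state.mu, 0.0, _HYPER_SD).sum()
        lp += _N_FAMILIES * math.log(1.0 / _SIGMA_UPPER)
        for k in range(_N_FAMILIES):
            lp += norm.logpdf(getattr(state, f"beta{k}"), state.mu[k], state.sigma[k]).sum()
    else:
        for k in range(_N_FAMILIES):
            lp += norm.logpdf(getattr(state, f"beta{k}"), 0.0, _HYPER_SD).sum()
    lp += norm.logpdf(state.beta5, 0.0, _HYPER_SD)
    lp += norm.logpdf(state.beta6, 0.0, _HYPER_SD)
    if scat_effects:
        if not 0.0 < state.sigma_alpha <= _SIGMA_UPPER:
            return -np.inf
        lp += math.log(1.0 / _SIGMA_UPPER)
        lp += norm.logpdf(state.alpha, 0.0, state.sigma_alpha).sum()
    return float(lp)


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC draws of all monitored scalars.

    ``draws`` has shape (n_chains, n_kept, n_params) with parameter order
    given by ``names``.
    """

    draws: np.ndarray
    names: list[str]
    n_chains: int
    n_iter: int
    n_burnin: int
    seed: int
    thinning: int = 1
    species_labels: list[str] = field(default_factory=list)
    scat_labels: list[str] = field(default_factory=list)
    acceptance: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_kept) array for one monitored scalar."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no monitored parameter named {name!r}") from None
        return self.draws[:, :, j]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat vector."""
        return self.get(name).reshape(-1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format draws with chain and iteration columns."""
        nc, nk, _ = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(nc * nk, -1), columns=self.names)
        df.insert(0, "iteration", np.tile(np.arange(nk), nc))
        df.insert(0, "chain", np.repeat(np.arange(nc), nk))
        return df

    def to_arviz(self):
        import arviz as az

        return az.from_dict(posterior={n: self.get(n) for n in self.names})

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(d / "draws.csv", index=False)
        meta = {
            "names": self.names,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
            "thinning": self.thinning,
            "species_labels": self.species_labels,
            "scat_labels": self.scat_labels,
        }
        (d / "draws_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "draws_meta.json").read_text())
        df = pd.read_csv(d / "draws.csv")
        nc = meta["n_chains"]
        nk = len(df) // nc
        draws = df[meta["names"]].to_numpy().reshape(nc, nk, len(meta["names"]))
        return cls(draws=draws, **meta)


class _DataPack:
    """Row-sorted data with the per-group index structure and sufficient
    statistics the scalar updates need.

    Rows are sorted species-major so each species' rows form one
    contiguous slice; a scalar proposal then only touches the rows its
    coefficient enters, and the y-dependent part of the likelihood change
    reduces to a precomputed inner product.
    """

    def __init__(self, data: ModelInput):
        data.validate()
        order = np.lexsort((data.scat_index, data.species_index))
        self.y = data.y[order].astype(np.float64)
        self.x = [None, data.pr0[order], data.pr1[order], data.pr2[order], data.pr3[order]]
        self.deg = data.degradation_day[order]
        self.ind = data.individual[order]
        sidx = data.species_index[order] - 1
        iidx = data.scat_index[order] - 1
        self.S = data.n_species
        self.N = data.n_scats
        self.n = data.n_rows
        self.species_slice = [
            slice(*np.searchsorted(sidx, [s, s + 1])) for s in range(self.S)
        ]
        self.scat_rows = [np.flatnonzero(iidx == i) for i in range(self.N)]
        self.sidx = sidx
        self.iidx = iidx
        # y-weighted covariate sums per (family, species): the likelihood
        # change for a shift d in beta_k[s] is d * Syx[k][s] minus the
        # softplus change over that species' rows.
        self.Syx = np.zeros((_N_FAMILIES, self.S))
        for s in range(self.S):
            sl = self.species_slice[s]
            ys = self.y[sl]
            self.Syx[0, s] = ys.sum()
            for k in range(1, _N_FAMILIES):
                self.Syx[k, s] = ys @ self.x[k][sl]
        self.Sy_deg = self.y @ self.deg
        self.Sy_ind = self.y @ self.ind
        self.Sy_scat = np.array([self.y[r].sum() for r in self.scat_rows])
        # 0/1 individual code per scat (used by the translation moves)
        self.scat_ind = np.array([float(self.ind[r[0]]) if len(r) else 0.0
                                  for r in self.scat_rows])


class _ChainState:
    """Mutable sampler state for one chain, with cached linear predictor
    and per-row softplus."""

    def __init__(self, pack: _DataPack, beta: np.ndarray, beta5: float, beta6: float,
                 alpha: np.ndarray, mu: np.ndarray, sigma: np.ndarray, sigma_alpha: float):
        self.pack = pack
        self.beta = beta          # (5, S)
        self.beta5 = beta5
        self.beta6 = beta6
        self.alpha = alpha        # (N,)
        self.mu = mu
        self.sigma = sigma
        self.sigma_alpha = sigma_alpha
        self.refresh_eta()

    def refresh_eta(self) -> None:
        p = self.pack
        eta = self.beta[0, p.sidx].copy()
        for k in range(1, _N_FAMILIES):
            eta += self.beta[k, p.sidx] * p.x[k]
        eta += self.beta5 * p.deg + self.beta6 * p.ind + self.alpha[p.iidx]
        self.eta = eta
        self.sp = np.logaddexp(0.0, eta)

    def log_posterior(self, hierarchical: bool, scat_effects: bool) -> float:
        ll = float(self.pack.y @ self.eta - self.sp.sum())
        state = ParameterState(
            beta0=self.beta[0], beta1=self.beta[1], beta2=self.beta[2],
            beta3=self.beta[3], beta4=self.beta[4], beta5=self.beta5,
            beta6=self.beta6, alpha=self.alpha, mu=self.mu,
            sigma=self.sigma, sigma_alpha=self.sigma_alpha,
        )
        return ll + log_prior(state, hierarchical, scat_effects)


def _init_state(pack: _DataPack, rng: np.random.Generator,
                hierarchical: bool, scat_effects: bool) -> _ChainState:
    """Overdispersed initialisation drawn from the prior (SD truncated away
    from zero so species coefficients do not start degenerate)."""
    if hierarchical:
        mu = rng.normal(0.0, _HYPER_SD, size=_N_FAMILIES)
        sigma = rng.uniform(0.5, _SIGMA_UPPER, size=_N_FAMILIES)
        beta = np.stack([rng.normal(mu[k], sigma[k], size=pack.S)
                         for k in range(_N_FAMILIES)])
    else:
        mu = np.zeros(_N_FAMILIES)
        sigma = np.ones(_N_FAMILIES)
        beta = rng.normal(0.0, _HYPER_SD, size=(_N_FAMILIES, pack.S))
    beta5 = float(rng.normal(0.0, _HYPER_SD))
    beta6 = float(rng.normal(0.0, _HYPER_SD))
    if scat_effects:
        sigma_alpha = float(rng.uniform(0.5, _SIGMA_UPPER))
        alpha = rng.normal(0.0, sigma_alpha, size=pack.N)
    else:
        sigma_alpha = 1.0
        alpha = np.zeros(pack.N)
    return _ChainState(pack, beta, beta5, beta6, alpha, mu, sigma, sigma_alpha)


def _monitored_names(species_labels, scat_labels, hierarchical, scat_effects,
                     monitor_alpha) -> list[str]:
    names = [f"beta{k}[{sp}]" for k in range(_N_FAMILIES) for sp in species_labels]
    names += ["beta5", "beta6"]
    if hierarchical:
        names += [f"mu_beta{k}" for k in range(_N_FAMILIES)]
        names += [f"sigma_beta{k}" for k in range(_N_FAMILIES)]
    if scat_effects:
        names += ["sigma_alpha"]
        if monitor_alpha:
            names += [f"alpha[{sc}]" for sc in scat_labels]
    return names


def _run_chain(pack: _DataPack, rng: np.random.Generator, n_iter: int, n_burnin: int,
               hierarchical: bool, scat_effects: bool, monitor_alpha: bool,
               adapt_interval: int, accept_band: tuple[float, float],
               max_init_retries: int = 20) -> tuple[np.ndarray, dict]:
    S, N = pack.S, pack.N
    for _ in range(max_init_retries):
        st = _init_state(pack, rng, hierarchical, scat_effects)
        if np.isfinite(st.log_posterior(hierarchical, scat_effects)):
            break
    else:
        raise ConfigurationError("could not find a finite-posterior initial state")

    step_beta = np.full((_N_FAMILIES, S), 0.5)
    step_b5 = 0.02
    step_b6 = 0.5
    step_alpha = np.full(N, 0.5)
    step_lsig = np.full(_N_FAMILIES, 0.5)
    step_lsiga = 0.5
    step_shift0 = 0.5
    step_shift6 = 0.5
    acc_beta = np.zeros((_N_FAMILIES, S))
    acc_b5 = acc_b6 = 0.0
    acc_alpha = np.zeros(N)
    acc_lsig = np.zeros(_N_FAMILIES)
    acc_lsiga = 0.0
    acc_shift0 = acc_shift6 = 0.0
    tot_acc = {"beta": 0, "beta_n": 0, "alpha": 0, "alpha_n": 0,
               "beta5": 0, "beta6": 0, "sigma": 0, "sigma_n": 0, "kept_iters": 0}

    prior_var = _HYPER_SD ** 2
    lo, hi = accept_band
    n_kept = n_iter - n_burnin
    n_params = len(_monitored_names(range(S), range(N), hierarchical,
                                    scat_effects, monitor_alpha))
    out = np.empty((n_kept, n_params))

    for it in range(n_iter):
        adapting = it < n_burnin
        # --- species-indexed coefficient families -----------------------
        for k in range(_N_FAMILIES):
            xk = pack.x[k]
            for s in range(S):
                sl = pack.species_slice[s]
                d = rng.normal() * step_beta[k, s]
                eta_new = st.eta[sl] + d if k == 0 else st.eta[sl] + d * xk[sl]
                sp_new = np.logaddexp(0.0, eta_new)
                dll = d * pack.Syx[k, s] - (sp_new.sum() - st.sp[sl].sum())
                b_old = st.beta[k, s]
                b_new = b_old + d
                if hierarchical:
                    m, v = st.mu[k], st.sigma[k] ** 2
                else:
                    m, v = 0.0, prior_var
                dlp = ((b_old - m) ** 2 - (b_new - m) ** 2) / (2.0 * v)
                if math.log(rng.random()) < dll + dlp:
                    st.beta[k, s] = b_new
                    st.eta[sl] = eta_new
                    st.sp[sl] = sp_new
                    acc_beta[k, s] += 1
                    if not adapting:
                        tot_acc["beta"] += 1
                if not adapting:
                    tot_acc["beta_n"] += 1

        # --- degradation-day and individual coefficients ----------------
        for which in (5, 6):
            x = pack.deg if which == 5 else pack.ind
            syx = pack.Sy_deg if which == 5 else pack.Sy_ind
            step = step_b5 if which == 5 else step_b6
            b_old = st.beta5 if which == 5 else st.beta6
            d = rng.normal() * step
            eta_new = st.eta + d * x
            sp_new = np.logaddexp(0.0, eta_new)
            dll = d * syx - (sp_new.sum() - st.sp.sum())
            b_new = b_old + d
            dlp = (b_old ** 2 - b_new ** 2) / (2.0 * prior_var)
            if math.log(rng.random()) < dll + dlp:
                st.eta = eta_new
                st.sp = sp_new
                if which == 5:
                    st.beta5 = b_new
                    acc_b5 += 1
                else:
                    st.beta6 = b_new
                    acc_b6 += 1
                if not adapting:
                    tot_acc[f"beta{which}"] += 1

        # --- per-scat random intercepts ----------------------------------
        if scat_effects:
            va = st.sigma_alpha ** 2
            for i in range(N):
                rows = pack.scat_rows[i]
                d = rng.normal() * step_alpha[i]
                eta_new = st.eta[rows] + d
                sp_new = np.logaddexp(0.0, eta_new)
                dll = d * pack.Sy_scat[i] - (sp_new.sum() - st.sp[rows].sum())
                a_old = st.alpha[i]
                a_new = a_old + d
                dlp = (a_old ** 2 - a_new ** 2) / (2.0 * va)
                if math.log(rng.random()) < dll + dlp:
                    st.alpha[i] = a_new
                    st.eta[rows] = eta_new
                    st.sp[rows] = sp_new
                    acc_alpha[i] += 1
                    if not adapting:
                        tot_acc["alpha"] += 1
                if not adapting:
                    tot_acc["alpha_n"] += 1

        # --- likelihood-invariant translation moves ----------------------
        # The linear predictor only identifies beta0[s] + alpha[i] (and
        # beta6 + alpha over one individual's scats) jointly; single-site
        # updates mix slowly along these flat ridges.  Shifting the whole
        # intercept family against the scat effects leaves eta (hence the
        # likelihood) unchanged, so the acceptance ratio is prior-only.
        if scat_effects:
            va = st.sigma_alpha ** 2
            # all species intercepts up, all scat effects down
            d = rng.normal() * step_shift0
            if hierarchical:
                m0, v0 = st.mu[0], st.sigma[0] ** 2
            else:
                m0, v0 = 0.0, prior_var
            dlp = (((st.beta[0] - m0) ** 2).sum()
                   - ((st.beta[0] + d - m0) ** 2).sum()) / (2.0 * v0)
            dlp += ((st.alpha ** 2).sum() - ((st.alpha - d) ** 2).sum()) / (2.0 * va)
            if math.log(rng.random()) < dlp:
                st.beta[0] += d
                st.alpha -= d
                acc_shift0 += 1
            # individual contrast against the second individual's scats
            sel = pack.scat_ind == 1.0
            if sel.any():
                d = rng.normal() * step_shift6
                a = st.alpha[sel]
                dlp = (st.beta6 ** 2 - (st.beta6 + d) ** 2) / (2.0 * prior_var)
                dlp += ((a ** 2).sum() - ((a - d) ** 2).sum()) / (2.0 * va)
                if math.log(rng.random()) < dlp:
                    st.beta6 += d
                    st.alpha[sel] -= d
                    acc_shift6 += 1

        # --- hyper-means: conjugate Gibbs --------------------------------
        if hierarchical:
            for k in range(_N_FAMILIES):
                v_post = 1.0 / (S / st.sigma[k] ** 2 + 1.0 / prior_var)
                m_post = v_post * st.beta[k].sum() / st.sigma[k] ** 2
                st.mu[k] = rng.normal(m_post, math.sqrt(v_post))

            # --- hyper-SDs: log-scale random walk, reflected below 10 ----
            for k in range(_N_FAMILIES):
                ssq = float(((st.beta[k] - st.mu[k]) ** 2).sum())
                z = math.log(st.sigma[k])
                z_new = z + rng.normal() * step_lsig[k]
                if z_new > _LOG_SIGMA_UPPER:
                    z_new = 2.0 * _LOG_SIGMA_UPPER - z_new
                # target in z: -S*z - ssq/(2 e^{2z}) + z (Jacobian)
                logr = (-(S - 1) * z_new - ssq / (2.0 * math.exp(2.0 * z_new))) \
                    - (-(S - 1) * z - ssq / (2.0 * math.exp(2.0 * z)))
                if math.log(rng.random()) < logr:
                    st.sigma[k] = math.exp(z_new)
                    acc_lsig[k] += 1
                    if not adapting:
                        tot_acc["sigma"] += 1
                if not adapting:
                    tot_acc["sigma_n"] += 1

        if scat_effects:
            ssq = float((st.alpha ** 2).sum())
            z = math.log(st.sigma_alpha)
            z_new = z + rng.normal() * step_lsiga
            if z_new > _LOG_SIGMA_UPPER:
                z_new = 2.0 * _LOG_SIGMA_UPPER - z_new
            logr = (-(N - 1) * z_new - ssq / (2.0 * math.exp(2.0 * z_new))) \
                - (-(N - 1) * z - ssq / (2.0 * math.exp(2.0 * z)))
            if math.log(rng.random()) < logr:
                st.sigma_alpha = math.exp(z_new)
                acc_lsiga += 1
                if not adapting:
                    tot_acc["sigma"] += 1
            if not adapting:
                tot_acc["sigma_n"] += 1

        # --- step-size adaptation (burn-in only) -------------------------
        if adapting and (it + 1) % adapt_interval == 0:
            def tune(step, acc):
                rate = acc / adapt_interval
                factor = np.where(rate > hi, 1.25, np.where(rate < lo, 0.8, 1.0))
                return step * factor
            step_beta = tune(step_beta, acc_beta)
            step_alpha = tune(step_alpha, acc_alpha)
            step_lsig = tune(step_lsig, acc_lsig)
            step_b5 = float(tune(np.array(step_b5), np.array(acc_b5)))
            step_b6 = float(tune(np.array(step_b6), np.array(acc_b6)))
            step_lsiga = float(tune(np.array(step_lsiga), np.array(acc_lsiga)))
            step_shift0 = float(tune(np.array(step_shift0), np.array(acc_shift0)))
            step_shift6 = float(tune(np.array(step_shift6), np.array(acc_shift6)))
            acc_beta[:] = 0
            acc_alpha[:] = 0
            acc_lsig[:] = 0
            acc_b5 = acc_b6 = acc_lsiga = 0.0
            acc_shift0 = acc_shift6 = 0.0

        # --- record ------------------------------------------------------
        if it >= n_burnin:
            j = it - n_burnin
            vals = list(st.beta.reshape(-1)) + [st.beta5, st.beta6]
            if hierarchical:
                vals += list(st.mu) + list(st.sigma)
            if scat_effects:
                vals += [st.sigma_alpha]
                if monitor_alpha:
                    vals += list(st.alpha)
            out[j] = vals
            tot_acc["kept_iters"] += 1

    rates = {
        "beta": tot_acc["beta"] / max(tot_acc["beta_n"], 1),
        "alpha": tot_acc["alpha"] / max(tot_acc["alpha_n"], 1),
        "beta5": tot_acc["beta5"] / max(tot_acc["kept_iters"], 1),
        "beta6": tot_acc["beta6"] / max(tot_acc["kept_iters"], 1),
        "sigma": tot_acc["sigma"] / max(tot_acc["sigma_n"], 1),
    }
    return out, rates


def run_mcmc(
    data: ModelInput,
    n_chains: int = 3,
    n_iter: int = 20_000,
    n_burnin: int = 5_000,
    seed: int = 0,
    *,
    hierarchical: bool = True,
    scat_effects: bool = True,
    monitor_alpha: bool = False,
    adapt_interval: int = 50,
    accept_band: tuple[float, float] = (0.30, 0.45),
) -> PosteriorDraws:
    """Sample the posterior with adaptive Metropolis-within-Gibbs.

    ``n_iter`` counts total iterations per chain; the first ``n_burnin``
    are used for step-size adaptation and discarded.  Chains are
    initialised by overdispersed draws from the prior with per-chain
    seeds spawned from ``seed``; the same data and seed reproduce the
    draws exactly.

    Set ``hierarchical=False`` to put N(0, 100) priors directly on every
    coefficient (no pooling), and ``scat_effects=False`` to drop the
    per-scat random intercepts; both reductions are used by the
    grid-integration validation of the sampler.
    """
    if data.n_rows == 0:
        raise InputError("model input is empty")
    if not n_iter > n_burnin >= 0:
        raise ConfigurationError("need n_iter > n_burnin >= 0")
    if n_chains < 1:
        raise ConfigurationError("need at least one chain")

    pack = _DataPack(data)
    names = _monitored_names(data.species_labels, data.scat_labels,
                             hierarchical, scat_effects, monitor_alpha)
    children = np.random.SeedSequence(seed).spawn(n_chains)
    all_draws = []
    rates = []
    for c in range(n_chains):
        rng = np.random.default_rng(children[c])
        draws, r = _run_chain(pack, rng, n_iter, n_burnin, hierarchical,
                              scat_effects, monitor_alpha, adapt_interval,
                              accept_band)
        all_draws.append(draws)
        rates.append(r)
    return PosteriorDraws(
        draws=np.stack(all_draws),
        names=names,
        n_chains=n_chains,
        n_iter=n_iter,
        n_burnin=n_burnin,
        seed=seed,
        species_labels=list(data.species_labels),
        scat_labels=list(data.scat_labels),
        acceptance={"per_chain": rates},
    )


@dataclass
class ConvergenceReport:
    """Gelman-Rubin diagnostics for every monitored scalar."""

    rhat: pd.Series
    ess: pd.Series
    converged: bool
    threshold: float = 1.1

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())


def gelman_rubin(draws: PosteriorDraws, threshold: float = 1.1,
                 split: bool = False) -> ConvergenceReport:
    """Potential scale reduction factor per monitored scalar.

    Rhat = sqrt(((n-1)/n * W + B/n) / W) with B and W the standard
    between- and within-chain variances of the retained draws.  With
    ``split=True`` each chain is halved first, which also flags
    non-stationarity within single chains.  The degenerate case W = 0
    with all chains at the same constant is reported as 1.0 with a
    warning.  Effective sample sizes come from arviz.
    """
    import arviz as az

    arr = draws.draws
    if split:
        nc, nk, npar = arr.shape
        half = nk // 2
        if half < 5:
            raise InputError("need at least 10 post-burn-in draws per chain")
        arr = np.concatenate([arr[:, :half, :], arr[:, half:2 * half, :]], axis=0)
    if arr.shape[0] < 2:
        raise InputError("Gelman-Rubin requires at least 2 chains")
    if arr.shape[1] < 10:
        raise InputError("need at least 10 post-burn-in draws per chain")

    n = arr.shape[1]
    chain_means = arr.mean(axis=1)                       # (chains, params)
    W = arr.var(axis=1, ddof=1).mean(axis=0)             # (params,)
    B_over_n = chain_means.var(axis=0, ddof=1)           # B/n
    rhat = np.empty(arr.shape[2])
    degenerate = W == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    if degenerate.any():
        same = degenerate & (B_over_n == 0)
        if same.any():
            warnings.warn("constant identical chains: Rhat floored at 1.0")
            rhat[same] = 1.0
        rhat[degenerate & ~same] = np.inf

    ess = az.ess(az.from_dict(posterior={nm: draws.get(nm) for nm in draws.names}))
    ess_s = pd.Series({nm: float(ess[nm].values) for nm in draws.names})
    rhat_s = pd.Series(rhat, index=draws.names)
    return ConvergenceReport(rhat=rhat_s, ess=ess_s,
                             converged=bool((rhat_s < threshold).all()),
                             threshold=threshold)


_QUANTS = (0.025, 0.25, 0.50, 0.75, 0.975)


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Pooled posterior mean, SD and central quantiles per scalar.

    Quantiles use linear interpolation.  Rows are indexed by parameter
    name in monitoring order.
    """
    if draws.n_kept == 0:
        raise InputError("no draws to summarise")
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    qs = np.quantile(flat, _QUANTS, axis=0)
    return pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1]),
            "q2.5": qs[0], "q25": qs[1], "q50": qs[2], "q75": qs[3], "q97.5": qs[4],
        },
        index=pd.Index(draws.names, name="parameter"),
    )


#: Report label -> monitored scalar for the headline fixed-effect summary:
#: the species-averaged (hyper-mean) meal-proportion effects at lags 0-3,
#: the degradation-day slope and the individual contrast.
HEADLINE_PARAMS = {
    "Day 0/pr fed": "mu_beta1",
    "Day 1/pr fed": "mu_beta2",
    "Day 2/pr fed": "mu_beta3",
    "Day 3/pr fed": "mu_beta4",
    "Degradation": "beta5",
    "Cheetah": "beta6",
}


def headline_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Six-row summary of the species-averaged lag effects, degradation
    slope and individual effect (mean, SD, 95% credible interval)."""
    full = summarize_posterior(draws)
    rows = {}
    for label, name in HEADLINE_PARAMS.items():
        if name not in full.index:
            continue
        r = full.loc[name]
        rows[label] = {"mean": r["mean"], "sd": r["sd"],
                       "ci2.5": r["q2.5"], "ci97.5": r["q97.5"]}
    return pd.DataFrame(rows).T
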