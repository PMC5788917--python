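"""Hierarchical Bayesian beta model of social influence on ratings.

A final rating ``y`` (squeezed onto the unit interval) is beta distributed
with mean

    mu = logistic( logit(I) + s * (logit(S) - logit(I)) )

where ``I`` and ``S`` are the rater's initial rating and the displayed peer
rating on the unit scale, and ``s`` is the social-influence slope: ``s = 0``
reproduces the initial rating, ``s = 1`` the peer rating, ``s > 1`` is
over-adjustment and ``s < 0`` contrariness.  The slope decomposes as
``s = beta_c + u_p``: a fixed effect per stimulus condition plus a
participant random slope ``u_p ~ N(0, sigma_u^2)``.  The beta likelihood is
parameterised by mean and precision, ``Beta(mu*phi, (1-mu)*phi)``.

Priors: ``beta_c ~ N(0, 1)`` (variance 100 under the flat-prior robustness
variant), ``sigma_u^2 ~ Exp(1)``, ``phi ~ Exp(1)``.

Posterior sampling is adaptive random-walk Metropolis-within-Gibbs with
blocked updates; conditional independence (trials partition by condition
given ``u``, and by participant given ``beta``) lets each block be updated
in a single vectorised step.  Step sizes adapt toward a 0.44 acceptance rate
during burn-in only, so the kept draws come from a fixed transition kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .data import CONDITIONS, Dataset

LINK_SCALES = ("logit_interpolation", "raw_interpolation")
RANDOM_EFFECT_STRUCTURES = ("shared_across_conditions", "per_condition", "none")

_RAW_EPS = 1e-6
_MU_CLIP = 1e-12


class ConfigError(ValueError):
    """Invalid model or MCMC configuration."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood / prior / link configuration, including robustness variants."""

    link_scale: str = "logit_interpolation"
    prior_beta_mean: float = 0.0
    prior_beta_var: float = 1.0
    prior_random_variance_rate: float = 1.0
    prior_precision_rate: float = 1.0
    random_effect_structure: str = "shared_across_conditions"
    flat_prior_variant: bool = False

    def __post_init__(self):
        if self.link_scale not in LINK_SCALES:
            raise ConfigError(f"unknown link_scale {self.link_scale!r}")
        if self.random_effect_structure not in RANDOM_EFFECT_STRUCTURES:
            raise ConfigError(
                f"unknown random_effect_structure {self.random_effect_structure!r}"
            )
        for name in ("prior_beta_var", "prior_random_variance_rate", "prior_precision_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def beta_var(self) -> float:
        """Prior variance of the condition effects (100 under the flat variant)."""
        return 100.0 if self.flat_prior_variant else self.prior_beta_var


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule.  Defaults are the full replication budget: 3 chains of
    50,000 iterations, 5,000 burn-in, thinning every 10."""

    n_chains: int = 3
    n_iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.thin < 1:
            raise ConfigError("n_chains and thin must be >= 1")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ConfigError("require 0 <= burn_in < n_iterations")
        if self.n_kept < 1:
            raise ConfigError("zero kept draws after burn-in/thinning")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class ModelParameters:
    """One point in parameter space (used by the density functions and tests)."""

    beta: dict
    u: dict = field(default_factory=dict)
    sigma_u2: float | None = 1.0
    phi: float = 1.0


class PosteriorSamples:
    """Kept MCMC draws: array of shape (n_chains, n_kept, n_params) plus names.

    Parameter names follow the pattern ``beta[<condition>]``,
    ``u[<participant>]`` (or ``u[<participant>,<condition>]`` under the
    per-condition variant), ``sigma_u2`` and ``phi``.
    """

    def __init__(self, draws, names, spec, mcmc, conditions, participant_ids):
        self.draws = np.asarray(draws)
        self.names = list(names)
        self.spec = spec
        self.mcmc = mcmc
        self.conditions = tuple(conditions)
        self.participant_ids = tuple(participant_ids)
        if self.draws.shape[2] != len(self.names):
            raise ValueError("draws/names shape mismatch")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_kept)."""
        try:
            return self.draws[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}; have {self.names[:6]}...") from None

    def pooled(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains."""
        return self.get(name).reshape(-1)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format draws table: chain, iteration (kept index), parameter, value."""
        n_c, n_k, n_p = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(1, n_c + 1), n_k * n_p),
                "iteration": np.tile(np.repeat(np.arange(1, n_k + 1), n_p), n_c),
                "parameter": np.tile(self.names, n_c * n_k),
                "value": self.draws.reshape(-1),
            }
        )

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, spec=None, mcmc=None) -> "PosteriorSamples":
        names = list(dict.fromkeys(frame["parameter"]))
        chains = sorted(frame["chain"].unique())
        n_k = frame["iteration"].nunique()
        draws = np.empty((len(chains), n_k, len(names)))
        pivoted = frame.pivot_table(
            index=["chain", "iteration"], columns="parameter", values="value", sort=False
        )[names]
        for ci, c in enumerate(chains):
            draws[ci] = pivoted.loc[c].to_numpy()
        conditions = [n[5:-1] for n in names if n.startswith("beta[")]
        pids = [n[2:-1].split(",")[0] for n in names if n.startswith("u[")]
        return cls(draws, names, spec, mcmc, conditions, list(dict.fromkeys(pids)))


# ---------------------------------------------------------------------------
# densities


def predicted_mean(initial_u, social_u, s, link_scale: str = "logit_interpolation"):
    """Mean of the final-rating law given initial/peer ratings and slope ``s``.

    Under ``logit_interpolation`` (default) the slope interpolates on the
    log-odds scale, keeping the mean interior for any real ``s``; under
    ``raw_interpolation`` it interpolates on the raw unit scale with the mean
    clamped to [1e-6, 1 - 1e-6].  Both variants return exactly the initial
    rating at ``s = 0`` and exactly the peer rating at ``s = 1``.
    """
    i_arr, s_arr, w = np.asarray(initial_u, float), np.asarray(social_u, float), np.asarray(s, float)
    if np.any(i_arr <= 0) or np.any(i_arr >= 1) or np.any(s_arr <= 0) or np.any(s_arr >= 1):
        raise DomainError("initial_u and social_u must lie strictly inside (0, 1)")
    if link_scale == "logit_interpolation":
        mu = expit(logit(i_arr) + w * (logit(s_arr) - logit(i_arr)))
    elif link_scale == "raw_interpolation":
        mu = np.clip(i_arr + w * (s_arr - i_arr), _RAW_EPS, 1.0 - _RAW_EPS)
    else:
        raise ConfigError(f"unknown link_scale {link_scale!r}")
    # The interpolation endpoints are exact identities of the model; return
    # them without round-off.
    mu = np.where(w == 0.0, i_arr, np.where(w == 1.0, s_arr, mu))
    return float(mu) if mu.ndim == 0 else mu


def _mu_from_slope(logit_i, dlogit, init_u, social_u, s, link_scale):
    """Vectorised trial means from per-trial slopes (sampler hot path)."""
    if link_scale == "logit_interpolation":
        mu = expit(logit_i + s * dlogit)
    else:
        mu = np.clip(init_u + s * (social_u - init_u), _RAW_EPS, 1.0 - _RAW_EPS)
    return np.clip(mu, _MU_CLIP, 1.0 - _MU_CLIP)


def _beta_logpdf_terms(mu, phi, log_y, log_1my):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * log_y + (b - 1.0) * log_1my + gammaln(phi) - gammaln(a) - gammaln(b)


class _TrialArrays:
    """Precomputed per-trial quantities shared by the density and the sampler."""

    def __init__(self, trials: pd.DataFrame, conditions, participant_ids):
        self.conditions = list(conditions)
        self.participant_ids = list(participant_ids)
        cond_ix = {c: i for i, c in enumerate(self.conditions)}
        part_ix = {p: i for i, p in enumerate(self.participant_ids)}
        self.cond = trials["condition"].map(cond_ix).to_numpy(dtype=np.intp)
        self.part = trials["participant_id"].map(part_ix).to_numpy(dtype=np.intp)
        self.init_u = trials["initial_u"].to_numpy(dtype=float)
        self.social_u = trials["social_u"].to_numpy(dtype=float)
        y = trials["final_u"].to_numpy(dtype=float)
        self.logit_i = logit(self.init_u)
        self.dlogit = logit(self.social_u) - self.logit_i
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.n = len(y)

    def loglik_vector(self, s_trials, phi, link_scale):
        mu = _mu_from_slope(
            self.logit_i, self.dlogit, self.init_u, self.social_u, s_trials, link_scale
        )
        return _beta_logpdf_terms(mu, phi, self.log_y, self.log_1my)


def _transformed_frame(trials) -> pd.DataFrame:
    if isinstance(trials, Dataset):
        return trials.transformed()
    frame = pd.DataFrame(trials)
    if "initial_u" not in frame.columns:
        raise ConfigError("trials must be transformed (initial_u/social_u/final_u)")
    return frame


def _slope_per_trial(arrays: _TrialArrays, params: ModelParameters, spec: ModelSpec):
    beta = np.array([params.beta[c] for c in arrays.conditions], float)
    s = beta[arrays.cond]
    if spec.random_effect_structure == "shared_across_conditions":
        u = np.array([params.u[p] for p in arrays.participant_ids], float)
        s = s + u[arrays.part]
    elif spec.random_effect_structure == "per_condition":
        u = np.array(
            [[params.u[(p, c)] for c in arrays.conditions] for p in arrays.participant_ids],
            float,
        )
        s = s + u[arrays.part, arrays.cond]
    return s


def log_likelihood(params: ModelParameters, trials, spec: ModelSpec = ModelSpec()) -> float:
    """Summed beta log density of the final ratings given ``params``.

    ``trials`` is a transformed trial table (or a :class:`Dataset`, which is
    transformed on the fly).  Invariant to trial ordering.
    """
    frame = _transformed_frame(trials)
    conditions = [c for c in CONDITIONS if c in set(frame["condition"])]
    pids = list(dict.fromkeys(frame["participant_id"]))
    arrays = _TrialArrays(frame, conditions, pids)
    s = _slope_per_trial(arrays, params, spec)
    ll = arrays.loglik_vector(s, params.phi, spec.link_scale)
    if not np.all(np.isfinite(ll)):
        idx = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log likelihood at trial index {idx}")
    return float(ll.sum())


def log_prior(params: ModelParameters, spec: ModelSpec = ModelSpec()) -> float:
    """Joint log prior; returns -inf (not an exception) for phi <= 0 or sigma_u2 <= 0."""
    if params.phi <= 0:
        return -np.inf
    lp = 0.0
    var_b = spec.beta_var
    for b in params.beta.values():
        lp += -0.5 * np.log(2 * np.pi * var_b) - (b - spec.prior_beta_mean) ** 2 / (2 * var_b)
    if spec.random_effect_structure != "none":
        if params.sigma_u2 is None or params.sigma_u2 <= 0:
            return -np.inf
        s2 = params.sigma_u2
        for u in params.u.values():
            lp += -0.5 * np.log(2 * np.pi * s2) - u**2 / (2 * s2)
        rate = spec.prior_random_variance_rate
        lp += np.log(rate) - rate * s2
    rate_phi = spec.prior_precision_rate
    lp += np.log(rate_phi) - rate_phi * params.phi
    return float(lp)


# ---------------------------------------------------------------------------
# sampler

_ADAPT_INTERVAL = 25
_TARGET_ACCEPT = 0.44


def _run_chain(arrays: _TrialArrays, spec: ModelSpec, mcmc: MCMCConfig, rng):
    n_cond = len(arrays.conditions)
    n_part = len(arrays.participant_ids)
    per_cond = spec.random_effect_structure == "per_condition"
    has_u = spec.random_effect_structure != "none"
    n_u = (n_part * n_cond if per_cond else n_part) if has_u else 0
    u_index = (arrays.part * n_cond + arrays.cond) if per_cond else arrays.part
    link = spec.link_scale
    var_b = spec.beta_var
    rate_s2 = spec.prior_random_variance_rate
    rate_phi = spec.prior_precision_rate

    # Overdispersed initialisation from the chain's own stream.
    beta = rng.normal(spec.prior_beta_mean, np.sqrt(var_b if var_b <= 1 else 1.0), n_cond)
    u = np.zeros(n_u)
    eta = float(rng.normal(0.0, 0.3))  # log sigma_u^2
    lphi = float(rng.normal(0.0, 0.3))  # log phi

    def slopes():
        s = beta[arrays.cond]
        return s + u[u_index] if has_u else s

    s_cur = slopes()
    ll_cur = arrays.loglik_vector(s_cur, np.exp(lphi), link)

    step_beta = np.full(n_cond, 0.1)
    step_u = np.full(n_u, 0.3)
    step_eta, step_lphi, step_trans = 0.5, 0.3, 0.3
    acc_beta = np.zeros(n_cond)
    acc_u = np.zeros(n_u)
    acc_eta = acc_lphi = acc_trans = 0.0

    n_kept = mcmc.n_kept
    out = np.empty((n_kept, n_cond + n_u + (1 if has_u else 0) + 1))
    kept = 0

    for it in range(1, mcmc.n_iterations + 1):
        phi = np.exp(lphi)

        # --- condition effects: conditionally independent given u, phi ---
        prop = beta + step_beta * rng.standard_normal(n_cond)
        s_prop = s_cur + (prop - beta)[arrays.cond]
        ll_prop = arrays.loglik_vector(s_prop, phi, link)
        delta = np.bincount(arrays.cond, ll_prop - ll_cur, minlength=n_cond)
        delta += (beta**2 - prop**2 + 2 * spec.prior_beta_mean * (prop - beta)) / (2 * var_b)
        acc = np.log(rng.random(n_cond)) < delta
        if acc.any():
            beta = np.where(acc, prop, beta)
            take = acc[arrays.cond]
            s_cur = np.where(take, s_prop, s_cur)
            ll_cur = np.where(take, ll_prop, ll_cur)
        acc_beta += acc

        # --- participant slopes: conditionally independent given beta, phi ---
        if has_u:
            sig2 = np.exp(eta)
            prop_u = u + step_u * rng.standard_normal(n_u)
            s_prop = s_cur + (prop_u - u)[u_index]
            ll_prop = arrays.loglik_vector(s_prop, phi, link)
            delta_u = np.bincount(u_index, ll_prop - ll_cur, minlength=n_u)
            delta_u += (u**2 - prop_u**2) / (2 * sig2)
            acc = np.log(rng.random(n_u)) < delta_u
            if acc.any():
                u = np.where(acc, prop_u, u)
                take = acc[u_index]
                s_cur = np.where(take, s_prop, s_cur)
                ll_cur = np.where(take, ll_prop, ll_cur)
            acc_u += acc

            # --- random-slope variance on the log scale (prior-only move) ---
            prop_eta = eta + step_eta * rng.standard_normal()
            # N(u; 0, e^eta) product + Exp(rate) prior + log-scale Jacobian
            uu = float(u @ u)
            cur_lp = -0.5 * n_u * eta - 0.5 * uu * np.exp(-eta) - rate_s2 * np.exp(eta) + eta
            prop_lp = (
                -0.5 * n_u * prop_eta
                - 0.5 * uu * np.exp(-prop_eta)
                - rate_s2 * np.exp(prop_eta)
                + prop_eta
            )
            if np.log(rng.random()) < prop_lp - cur_lp:
                eta = prop_eta
                acc_eta += 1

        # --- translation along the beta/u ridge (likelihood-invariant) ---
        # Shifting every condition effect by +d and every participant slope
        # by -d leaves all per-trial slopes unchanged under the shared
        # structure (per condition, shift one beta_c and that condition's
        # column of u); only the priors move, so this mixes the weakly
        # identified common level cheaply.
        if has_u:
            sig2 = np.exp(eta)
            if per_cond:
                d_vec = step_trans * rng.standard_normal(n_cond)
                u_mat = u.reshape(n_part, n_cond)
                prop_b = beta + d_vec
                prop_u_mat = u_mat - d_vec[None, :]
                delta_t = (
                    beta**2 - prop_b**2 + 2 * spec.prior_beta_mean * (prop_b - beta)
                ) / (2 * var_b)
                delta_t += (u_mat**2 - prop_u_mat**2).sum(axis=0) / (2 * sig2)
                acc = np.log(rng.random(n_cond)) < delta_t
                if acc.any():
                    beta = np.where(acc, prop_b, beta)
                    u = np.where(acc[None, :], prop_u_mat, u_mat).reshape(-1)
                acc_trans += acc.mean()
            else:
                d = step_trans * rng.standard_normal()
                prop_b = beta + d
                prop_u = u - d
                delta_t = float(
                    (
                        (beta**2 - prop_b**2 + 2 * spec.prior_beta_mean * d).sum()
                        / (2 * var_b)
                    )
                    + (u @ u - prop_u @ prop_u) / (2 * sig2)
                )
                if np.log(rng.random()) < delta_t:
                    beta, u = prop_b, prop_u
                    acc_trans += 1

        # --- beta precision on the log scale ---
        prop_lphi = lphi + step_lphi * rng.standard_normal()
        ll_prop = arrays.loglik_vector(s_cur, np.exp(prop_lphi), link)
        delta_phi = (
            float(ll_prop.sum() - ll_cur.sum())
            - rate_phi * (np.exp(prop_lphi) - phi)
            + (prop_lphi - lphi)
        )
        if np.log(rng.random()) < delta_phi:
            lphi = prop_lphi
            ll_cur = ll_prop
            acc_lphi += 1

        # --- step-size adaptation, burn-in only (fixed kernel afterwards) ---
        if it <= mcmc.burn_in and it % _ADAPT_INTERVAL == 0:
            step_beta *= np.exp((acc_beta / _ADAPT_INTERVAL - _TARGET_ACCEPT))
            acc_beta[:] = 0
            if has_u:
                step_u *= np.exp((acc_u / _ADAPT_INTERVAL - _TARGET_ACCEPT))
                acc_u[:] = 0
                step_eta *= np.exp(acc_eta / _ADAPT_INTERVAL - _TARGET_ACCEPT)
                acc_eta = 0.0
            step_lphi *= np.exp(acc_lphi / _ADAPT_INTERVAL - _TARGET_ACCEPT)
            acc_lphi = 0.0
            np.clip(step_beta, 1e-4, 10.0, out=step_beta)
            if has_u:
                np.clip(step_u, 1e-4, 10.0, out=step_u)
                step_eta = float(np.clip(step_eta, 1e-4, 10.0))
                step_trans *= np.exp(acc_trans / _ADAPT_INTERVAL - _TARGET_ACCEPT)
                step_trans = float(np.clip(step_trans, 1e-4, 10.0))
                acc_trans = 0.0
            step_lphi = float(np.clip(step_lphi, 1e-4, 10.0))

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            cols = [beta]
            if has_u:
                cols += [u, [np.exp(eta)]]
            cols += [[np.exp(lphi)]]
            out[kept] = np.concatenate(cols)
            kept += 1

    return out[:kept]


def fit(dataset, spec: ModelSpec = ModelSpec(), mcmc: MCMCConfig = MCMCConfig()) -> PosteriorSamples:
    """Draw from the posterior by adaptive Metropolis-within-Gibbs.

    ``dataset`` may be a :class:`Dataset` or a transformed trial table.
    Chains are initialised independently from per-chain substreams of
    ``mcmc.seed``, so the result is reproducible bit-for-bit.
    """
    frame = _transformed_frame(dataset)
    if len(frame) == 0:
        raise ConfigError("empty dataset")
    conditions = [c for c in CONDITIONS if c in set(frame["condition"])]
    pids = list(dict.fromkeys(frame["participant_id"]))
    arrays = _TrialArrays(frame, conditions, pids)

    names = [f"beta[{c}]" for c in conditions]
    if spec.random_effect_structure == "shared_across_conditions":
        names += [f"u[{p}]" for p in pids] + ["sigma_u2"]
    elif spec.random_effect_structure == "per_condition":
        names += [f"u[{p},{c}]" for p in pids for c in conditions] + ["sigma_u2"]
    names += ["phi"]

    children = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = [
        _run_chain(arrays, spec, mcmc, np.random.default_rng(ss)) for ss in children
    ]
    draws = np.stack(chains)
    return PosteriorSamples(draws, names, spec, mcmc, conditions, pids)
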