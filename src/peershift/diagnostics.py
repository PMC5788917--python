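"""Convergence diagnostics, posterior summaries, contrasts and fit checks.

The potential scale reduction factor here is the original Gelman-Rubin
statistic (not the split-chain variant), matching how analyses of this kind
report "point estimate" and "upper C.I."; the effective sample size uses
Geyer's initial-positive-sequence truncation of the autocorrelation sum and
is summed across chains.  Summaries are medians with equal-tailed credible
intervals from pooled chains, using linear (type-7) quantile interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .model import ModelSpec, PosteriorSamples, _TrialArrays, _mu_from_slope

SUMMARY_COLUMNS = ["median", "lower", "upper", "psrf", "psrf_upper", "ess"]


class DiagnosticError(ValueError):
    """A diagnostic's preconditions are not met."""


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise DiagnosticError(f"expected (n_chains, n_draws) array, got shape {arr.shape}")
    return arr


def gelman_rubin(chains) -> tuple[float, float]:
    """Potential scale reduction factor R-hat and its 97.5% upper limit.

    R-hat = sqrt(V-hat / W) with V-hat = ((n-1)/n) W + B/n, where W is the
    mean within-chain variance and B/n the variance of the chain means; the
    upper limit scales the between-chain term by an F quantile.  Requires at
    least 2 chains of equal length >= 10.
    """
    arr = _as_chain_matrix(chains)
    m, n = arr.shape
    if m < 2:
        raise DiagnosticError("gelman_rubin needs at least 2 chains")
    if n < 10:
        raise DiagnosticError("gelman_rubin needs chains of length >= 10")
    s2 = arr.var(axis=1, ddof=1)
    w = s2.mean()
    b_over_n = arr.mean(axis=1).var(ddof=1)  # = B/n
    if w == 0.0:
        return (1.0, 1.0) if b_over_n == 0.0 else (np.inf, np.inf)
    r2_fixed = (n - 1) / n
    r2_random = b_over_n / w
    point = float(np.sqrt(r2_fixed + r2_random))
    var_w = s2.var(ddof=1) / m
    if var_w == 0.0 or r2_random == 0.0:
        return point, point
    w_df = 2.0 * w**2 / var_w
    upper = float(np.sqrt(r2_fixed + f_dist.ppf(0.975, m - 1, w_df) * r2_random))
    return point, upper


def _chain_ess(x: np.ndarray) -> float:
    n = x.size
    v = x.var()
    if v == 0.0:
        warnings.warn("constant chain: autocorrelation undefined, ESS set to n")
        return float(n)
    # autocorrelation via FFT
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(xc, nfft)) ** 2
    acov = np.fft.irfft(spec, nfft)[:n] / n
    rho = acov / acov[0]
    # Geyer initial positive sequence: add consecutive pairs while positive.
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        tau += 2.0 * pair
        t += 2
    return float(n / tau)


def effective_sample_size(chains) -> float:
    """Autocorrelation-based ESS, computed per chain and summed across chains."""
    arr = _as_chain_matrix(chains)
    return float(sum(_chain_ess(c) for c in arr))


def _summarize_array(chains: np.ndarray, level: float) -> dict:
    pooled = chains.reshape(-1)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(pooled, [alpha, 1.0 - alpha])
    if chains.shape[0] >= 2 and chains.shape[1] >= 10:
        psrf, psrf_upper = gelman_rubin(chains)
    else:
        psrf = psrf_upper = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = effective_sample_size(chains) if chains.shape[1] >= 2 else float(pooled.size)
    return {
        "median": float(np.median(pooled)),
        "lower": float(lower),
        "upper": float(upper),
        "psrf": psrf,
        "psrf_upper": psrf_upper,
        "ess": ess,
    }


def summarize(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Per-parameter median, equal-tailed credible interval, PSRF and ESS.

    Medians and intervals are computed on draws pooled across chains; the
    result is a DataFrame indexed by parameter name.
    """
    if not 0.0 < level < 1.0:
        raise DiagnosticError(f"level must be in (0, 1), got {level}")
    rows = {
        name: _summarize_array(samples.get(name), level) for name in samples.names
    }
    out = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    out.index.name = "parameter"
    return out


def contrast(
    samples: PosteriorSamples, condition_a: str, condition_b: str, level: float = 0.95
) -> pd.Series:
    """Summary of the draw-wise difference beta_a - beta_b (same chain & iteration)."""
    for c in (condition_a, condition_b):
        if f"beta[{c}]" not in samples.names:
            raise KeyError(f"condition {c!r} not among {samples.conditions}")
    diff = samples.get(f"beta[{condition_a}]") - samples.get(f"beta[{condition_b}]")
    row = _summarize_array(diff, level)
    return pd.Series(row, name=f"beta[{condition_a}]-beta[{condition_b}]")


def all_contrasts(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Summaries of all pairwise condition contrasts, in condition order."""
    rows = []
    conds = samples.conditions
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            rows.append(contrast(samples, a, b, level))
    out = pd.DataFrame(rows)
    out.index.name = "parameter"
    return out


@dataclass
class FitCheck:
    """In-sample fit: Pearson correlation of predicted vs observed final
    ratings and its square (the pseudo-R^2), plus per-trial posterior-mean
    predictions on the unit scale."""

    correlation: float
    pseudo_r2: float
    predictions: np.ndarray


def posterior_mean_predictions(
    samples: PosteriorSamples, dataset, chunk: int = 500
) -> np.ndarray:
    """Per-trial posterior mean of the predicted final rating (unit scale).

    Conditional (within-sample) predictions: each trial uses the posterior
    draws of its own participant's random slope.
    """
    from .model import _transformed_frame

    frame = _transformed_frame(dataset)
    arrays = _TrialArrays(frame, samples.conditions, samples.participant_ids)
    spec = samples.spec if samples.spec is not None else ModelSpec()
    per_cond = spec.random_effect_structure == "per_condition"
    has_u = spec.random_effect_structure != "none"

    beta_ix = np.array([samples._index[f"beta[{c}]"] for c in samples.conditions])
    if has_u:
        if per_cond:
            u_ix = np.array(
                [
                    [samples._index[f"u[{p},{c}]"] for c in samples.conditions]
                    for p in samples.participant_ids
                ]
            )
            trial_u_ix = u_ix[arrays.part, arrays.cond]
        else:
            u_ix = np.array([samples._index[f"u[{p}]"] for p in samples.participant_ids])
            trial_u_ix = u_ix[arrays.part]

    flat = samples.draws.reshape(-1, samples.draws.shape[2])
    total = np.zeros(arrays.n)
    for start in range(0, flat.shape[0], chunk):
        block = flat[start : start + chunk]
        s = block[:, beta_ix][:, arrays.cond]
        if has_u:
            s = s + block[:, trial_u_ix]
        mu = _mu_from_slope(
            arrays.logit_i, arrays.dlogit, arrays.init_u, arrays.social_u, s, spec.link_scale
        )
        total += mu.sum(axis=0)
    return total / flat.shape[0]


def fit_check(samples: PosteriorSamples, dataset) -> FitCheck:
    """Pearson correlation of posterior-mean predictions vs observed final
    ratings, and its square (both reported, as the two are distinct
    quantities even though pseudo-R^2 is often quoted for either)."""
    from .model import _transformed_frame

    frame = _transformed_frame(dataset)
    observed = frame["final_u"].to_numpy(dtype=float)
    if np.var(observed) == 0.0:
        raise DiagnosticError("observed final ratings have zero variance")
    preds = posterior_mean_predictions(samples, frame)
    if np.var(preds) == 0.0:
        raise DiagnosticError("predictions have zero variance")
    r = float(np.corrcoef(preds, observed)[0, 1])
    return FitCheck(correlation=r, pseudo_r2=r * r, predictions=preds)
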