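"""Hierarchical Bayesian estimation of medial-vs-lateral stepping weights.

Model (units: millimeters).  For participant k with single-condition
mean lateral COP excursions mu_SM(k) (medial target) and mu_SL(k)
(lateral target), and pooled dual-target trial values Y(k, i):

    alpha           ~ Normal(0, sd 10,000)          group logit weight
    sigma_alpha     ~ half-Cauchy(scale 25)          between-subject sd
    alpha_k         ~ Normal(alpha, sigma_alpha)
    theta_k         = invlogit(alpha_k)              in (0, 1)
    mu_D(k)         = theta_k mu_SM(k) + (1 - theta_k) mu_SL(k)
    sigma_k         ~ Uniform(0, 1000)
    Y(k, i)         ~ Normal(mu_D(k), sigma_k)

theta_k is the weight a participant gives the medial-stepping policy
when the target is uncertain: 1 means the anticipatory lateral COP
shift is scaled as if the medial target were certain, 0 as if the
lateral target were certain, and 0.5 is the midpoint (pure averaging).
mu_SM / mu_SL are plugged-in empirical participant means, not latent
parameters.

Sampling uses a blocked MCMC scheme vectorized across chains:
conjugate Gibbs draws for ``alpha`` (normal) and each ``sigma_k``
(inverse-gamma on the variance, truncated to the uniform prior's
support), and adaptive random-walk Metropolis steps for each
``alpha_k`` and for ``log sigma_alpha``.  Proposal scales adapt toward
a 44% acceptance rate during warmup only, so the post-warmup chain is
a valid fixed kernel.  Convergence is judged by split R-hat < 1.1 over
all parameters; non-convergence is reported as a warning flag, never
silently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

PRIOR_ALPHA_SD = 10_000.0
PRIOR_SIGMA_ALPHA_SCALE = 25.0
PRIOR_SIGMA_K_UPPER = 1_000.0


def invlogit(a):
    return expit(np.asarray(a, dtype=float))


@dataclass
class HierarchicalModel:
    """Data and fixed inputs of the hierarchical weighting model."""

    mu_sm_mm: np.ndarray
    mu_sl_mm: np.ndarray
    y_mm: list[np.ndarray]
    participants: list[str]

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def validate(self) -> "HierarchicalModel":
        k = self.n_participants
        if k < 1:
            raise ValueError("need at least one participant")
        if len(self.mu_sm_mm) != k or len(self.mu_sl_mm) != k or len(self.y_mm) != k:
            raise ValueError("inconsistent participant counts")
        for pid, y in zip(self.participants, self.y_mm):
            if len(y) < 2:
                raise ValueError(f"participant {pid}: need >= 2 dual trials")
        return self

    @classmethod
    def from_cohort(
        cls, table: pd.DataFrame, dv: str = "lateral_disp_mm", subject: str = "participant"
    ) -> "HierarchicalModel":
        """Build the model inputs from a cohort table: per-participant
        single-medial and single-lateral means plus pooled dual values."""
        mu_sm, mu_sl, ys, pids = [], [], [], []
        for pid, grp in table.groupby(subject, sort=True):
            single = grp[grp["n_targets"] == "single"]
            dual = grp[grp["n_targets"] == "dual"]
            m_sm = single.loc[single["side"] == "medial", dv].mean()
            m_sl = single.loc[single["side"] == "lateral", dv].mean()
            y = dual[dv].to_numpy(dtype=float)
            if np.isnan(m_sm) or np.isnan(m_sl) or y.size < 2:
                raise ValueError(f"participant {pid}: insufficient condition data")
            mu_sm.append(float(m_sm))
            mu_sl.append(float(m_sl))
            ys.append(y)
            pids.append(str(pid))
        return cls(
            mu_sm_mm=np.asarray(mu_sm),
            mu_sl_mm=np.asarray(mu_sl),
            y_mm=ys,
            participants=pids,
        ).validate()


def log_posterior(
    model: HierarchicalModel,
    alpha: float,
    sigma_alpha: float,
    alpha_k: np.ndarray,
    sigma_k: np.ndarray,
) -> float:
    """Joint log density (up to nothing - all normalizing constants of
    in-support densities included).  Returns -inf out of support."""
    alpha_k = np.asarray(alpha_k, dtype=float)
    sigma_k = np.asarray(sigma_k, dtype=float)
    if (
        not np.isfinite(alpha)
        or sigma_alpha <= 0
        or (sigma_k <= 0).any()
        or (sigma_k >= PRIOR_SIGMA_K_UPPER).any()
    ):
        return -math.inf
    lp = -0.5 * (alpha / PRIOR_ALPHA_SD) ** 2 - math.log(
        PRIOR_ALPHA_SD * math.sqrt(2 * math.pi)
    )
    # half-Cauchy(25) on sigma_alpha
    s = PRIOR_SIGMA_ALPHA_SCALE
    lp += math.log(2.0 / (math.pi * s)) - math.log1p((sigma_alpha / s) ** 2)
    # sigma_k ~ Uniform(0, 1000)
    lp += -model.n_participants * math.log(PRIOR_SIGMA_K_UPPER)
    # alpha_k ~ Normal(alpha, sigma_alpha)
    lp += float(
        np.sum(
            -0.5 * ((alpha_k - alpha) / sigma_alpha) ** 2
            - np.log(sigma_alpha * math.sqrt(2 * math.pi))
        )
    )
    # likelihood
    theta = invlogit(alpha_k)
    mu_d = theta * model.mu_sm_mm + (1.0 - theta) * model.mu_sl_mm
    for k, y in enumerate(model.y_mm):
        lp += float(
            np.sum(
                -0.5 * ((y - mu_d[k]) / sigma_k[k]) ** 2
                - np.log(sigma_k[k] * math.sqrt(2 * math.pi))
            )
        )
    return lp


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chains, n).  Each chain is halved, giving 2m
    half-chains of length L; R-hat = sqrt(((L-1)/L * W + B/L) / W)
    with W the mean within-half variance and B the between-half-means
    variance times L."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, n)")
    m, n = draws.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    L = n // 2
    halves = np.concatenate([draws[:, :L], draws[:, L : 2 * L]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = L * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else math.inf
    var_plus = (L - 1) / L * W + B / L
    return float(math.sqrt(var_plus / W))


@dataclass
class HierarchicalPosterior:
    """Posterior draws (post-warmup) and summaries.

    ``draws`` maps parameter names to arrays of shape (chains, n) for
    scalars and (chains, n, K) for vectors.  ``theta_group`` is
    invlogit(alpha) per draw; ``theta_k`` is invlogit(alpha_k).
    """

    draws: dict[str, np.ndarray]
    participants: list[str]
    converged: bool
    max_rhat: float

    def _flat_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                for k, pid in enumerate(self.participants):
                    out[f"{name}[{pid}]"] = arr[:, :, k]
        return out

    def summary(self) -> pd.DataFrame:
        """Posterior mean, median, 95% credible interval (2.5-97.5
        percentiles) and split R-hat per parameter."""
        rows = []
        for name, arr in self._flat_params().items():
            flat = arr.reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(flat.mean()),
                    "median": float(np.median(flat)),
                    "ci_low": float(np.percentile(flat, 2.5)),
                    "ci_high": float(np.percentile(flat, 97.5)),
                    "rhat": split_rhat(arr),
                }
            )
        return pd.DataFrame(rows)

    def rhat_table(self) -> pd.DataFrame:
        s = self.summary()
        return s[["parameter", "rhat"]]


def _halfcauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return -np.log1p((x / scale) ** 2)  # up to a constant


def fit(
    model: HierarchicalModel,
    chains: int = 4,
    iterations: int = 25_000,
    warmup: int = 5_000,
    seed: Optional[int] = None,
) -> HierarchicalPosterior:
    """Sample the posterior.

    ``iterations`` counts all steps per chain including the ``warmup``
    burn-in, which is discarded (the defaults keep 20,000 draws per
    chain).  Reproducible under a fixed ``seed``.  If any split R-hat
    is >= 1.1 a non-convergence warning is issued and the returned
    posterior carries ``converged=False``.
    """
    model.validate()
    if iterations <= warmup:
        raise ValueError("iterations must exceed warmup")
    rng = np.random.default_rng(seed)
    K = model.n_participants
    C = chains
    mu_sm = model.mu_sm_mm[None, :]
    mu_sl = model.mu_sl_mm[None, :]
    n_k = np.array([len(y) for y in model.y_mm], dtype=float)[None, :]
    sum_y = np.array([y.sum() for y in model.y_mm])[None, :]
    sum_y2 = np.array([(y**2).sum() for y in model.y_mm])[None, :]
    ybar = sum_y / n_k
    sd_k = np.sqrt(
        np.maximum((sum_y2 - n_k * ybar**2) / np.maximum(n_k - 1, 1), 0.25)
    )

    # overdispersed, data-informed initial states
    span = np.maximum(mu_sm - mu_sl, 1e-6)
    theta0 = np.clip((ybar - mu_sl) / span, 0.05, 0.95)
    alpha_k = np.log(theta0 / (1 - theta0)) + 0.5 * rng.standard_normal((C, K))
    alpha = alpha_k.mean(axis=1) + 0.3 * rng.standard_normal(C)
    sigma_alpha = np.exp(
        np.log(alpha_k.std(axis=1) + 0.3) + 0.3 * rng.standard_normal(C)
    )
    sigma_k = np.clip(sd_k * np.exp(0.2 * rng.standard_normal((C, K))), 0.3, 500.0)

    step_ak = np.full((C, K), 0.5)
    step_ls = np.full(C, 0.5)
    n_keep = iterations - warmup
    out_alpha = np.empty((C, n_keep))
    out_sigma_alpha = np.empty((C, n_keep))
    out_alpha_k = np.empty((C, n_keep, K))
    out_sigma_k = np.empty((C, n_keep, K))

    def loglike_alpha_k(a):
        theta = 1.0 / (1.0 + np.exp(-a))
        mu_d = theta * mu_sm + (1.0 - theta) * mu_sl
        ss = sum_y2 - 2.0 * mu_d * sum_y + n_k * mu_d**2
        return -ss / (2.0 * sigma_k**2)

    tau0_sq = PRIOR_ALPHA_SD**2
    for it in range(iterations):
        # -- alpha_k | rest : random-walk Metropolis, element-wise
        prop = alpha_k + step_ak * rng.standard_normal((C, K))
        logr = (
            loglike_alpha_k(prop)
            - loglike_alpha_k(alpha_k)
            - 0.5 * ((prop - alpha[:, None]) / sigma_alpha[:, None]) ** 2
            + 0.5 * ((alpha_k - alpha[:, None]) / sigma_alpha[:, None]) ** 2
        )
        accept = np.log(rng.random((C, K))) < logr
        alpha_k = np.where(accept, prop, alpha_k)

        # -- sigma_k | rest : conjugate inverse-gamma on the variance,
        #    truncated by the Uniform(0, 1000) prior support
        theta = 1.0 / (1.0 + np.exp(-alpha_k))
        mu_d = theta * mu_sm + (1.0 - theta) * mu_sl
        ss = sum_y2 - 2.0 * mu_d * sum_y + n_k * mu_d**2
        shape = (n_k - 1.0) / 2.0
        v = (ss / 2.0) / rng.gamma(np.broadcast_to(shape, (C, K)))
        for _ in range(100):
            bad = v >= PRIOR_SIGMA_K_UPPER**2
            if not bad.any():
                break
            v = np.where(
                bad, (ss / 2.0) / rng.gamma(np.broadcast_to(shape, (C, K))), v
            )
        sigma_k = np.sqrt(np.minimum(v, PRIOR_SIGMA_K_UPPER**2 * 0.999999))

        # -- alpha | rest : conjugate normal
        prec = K / sigma_alpha**2 + 1.0 / tau0_sq
        mean = (alpha_k.sum(axis=1) / sigma_alpha**2) / prec
        alpha = mean + rng.standard_normal(C) / np.sqrt(prec)

        # -- sigma_alpha | rest : random-walk Metropolis on the log scale
        resid = ((alpha_k - alpha[:, None]) ** 2).sum(axis=1)
        log_s = np.log(sigma_alpha)
        prop_ls = log_s + step_ls * rng.standard_normal(C)
        prop_s = np.exp(prop_ls)

        def logpost_s(s_val, log_s_val):
            return (
                -K * log_s_val
                - resid / (2.0 * s_val**2)
                + _halfcauchy_logpdf(s_val, PRIOR_SIGMA_ALPHA_SCALE)
                + log_s_val  # Jacobian of the log transform
            )

        logr_s = logpost_s(prop_s, prop_ls) - logpost_s(sigma_alpha, log_s)
        acc_s = np.log(rng.random(C)) < logr_s
        sigma_alpha = np.where(acc_s, prop_s, sigma_alpha)

        if it < warmup:
            gamma = (it + 1.0) ** -0.6
            step_ak *= np.exp(gamma * (accept.astype(float) - 0.44))
            step_ls *= np.exp(gamma * (acc_s.astype(float) - 0.44))
            step_ak = np.clip(step_ak, 1e-3, 10.0)
            step_ls = np.clip(step_ls, 1e-3, 10.0)
        else:
            j = it - warmup
            out_alpha[:, j] = alpha
            out_sigma_alpha[:, j] = sigma_alpha
            out_alpha_k[:, j, :] = alpha_k
            out_sigma_k[:, j, :] = sigma_k

    draws = {
        "alpha": out_alpha,
        "sigma_alpha": out_sigma_alpha,
        "alpha_k": out_alpha_k,
        "sigma_k": out_sigma_k,
        "theta_group": invlogit(out_alpha),
        "theta_k": invlogit(out_alpha_k),
    }
    base = ["alpha", "sigma_alpha", "alpha_k", "sigma_k"]
    rhats = []
    for name in base:
        arr = draws[name]
        if arr.ndim == 2:
            rhats.append(split_rhat(arr))
        else:
            rhats.extend(split_rhat(arr[:, :, k]) for k in range(K))
    max_rhat = float(max(rhats))
    converged = max_rhat < 1.1
    if not converged:
        warnings.warn(
            f"MCMC may not have converged: max split R-hat = {max_rhat:.3f} >= 1.1",
            RuntimeWarning,
            stacklevel=2,
        )
    return HierarchicalPosterior(
        draws=draws,
        participants=list(model.participants),
        converged=converged,
        max_rhat=max_rhat,
    )


def classify_strategy(posterior: HierarchicalPosterior) -> pd.DataFrame:
    """Label each participant's weighting pattern from the posterior
    mean of theta_k: >= 2/3 medial, <= 1/3 lateral, else intermediate
    (both boundaries closed toward the outer labels)."""
    theta = posterior.draws["theta_k"]
    rows = []
    for k, pid in enumerate(posterior.participants):
        flat = theta[:, :, k].reshape(-1)
        mean = float(flat.mean())
        if mean >= 2.0 / 3.0:
            label = "medial"
        elif mean <= 1.0 / 3.0:
            label = "lateral"
        else:
            label = "intermediate"
        rows.append(
            {
                "participant": pid,
                "theta_mean": mean,
                "theta_median": float(np.median(flat)),
                "ci_low": float(np.percentile(flat, 2.5)),
                "ci_high": float(np.percentile(flat, 97.5)),
                "label": label,
            }
        )
    return pd.DataFrame(rows)
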