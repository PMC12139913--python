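"""Bayesian Beta model for differential isoform usage.

Within each promoter group, an isoform's clipped usage proportions in one
condition are modelled as draws from Beta(alpha, beta) with weakly
informative Gamma(shape=5, scale=1) priors on both shape parameters. The
(alpha, beta) pair is fitted independently per isoform and condition by
random-walk Metropolis on (log alpha, log beta), with the proposal scale
adapted during burn-in toward a 20-40% acceptance rate. From matched
posteriors the per-draw log2 fold change of the usage mean
mu = alpha / (alpha + beta) (aged vs young) gives a posterior median, a 95%
highest-posterior-density interval and the posterior probability of an
increase; an isoform is called significant when the HPD interval excludes
zero AND max(P_up, 1 - P_up) > 0.95.

The sampler is vectorised across isoform/condition units and chains, so
hundreds of isoforms fit in seconds; a split-R-hat diagnostic is reported
per unit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

log = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    prior_shape: float = 5.0
    prior_scale: float = 1.0
    chains: int = 4
    draws: int = 5000          # retained draws per chain
    burn_in: int = 2000
    proposal_sd: float = 0.5   # initial; adapted during burn-in
    seed: int = 1337
    hpd_mass: float = 0.95
    prob_threshold: float = 0.95

    def __post_init__(self) -> None:
        for name in ("prior_shape", "prior_scale", "chains", "draws",
                     "burn_in", "proposal_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.hpd_mass < 1:
            raise ValueError("hpd_mass must lie in (0, 1)")


@dataclass
class BetaPosterior:
    isoform: str
    condition: str
    alpha: np.ndarray  # pooled draws, chains concatenated
    beta: np.ndarray
    rhat_alpha: float
    rhat_beta: float

    @property
    def mu(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class DifferentialCall:
    isoform: str
    log2fc: np.ndarray = field(repr=False)
    log2fc_median: float = 0.0
    hpd_low: float = 0.0
    hpd_high: float = 0.0
    p_up: float = 0.0
    significant: bool = False
    direction: str = "none"


def hpd_interval(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws.

    Ties between equally short windows resolve to the left-most, which keeps
    the result deterministic.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty draw set")
    w = int(math.ceil(mass * n))
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w:] - x[: n - w]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w])


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an array of shape (n_chains, n_draws)."""
    n_chains, n = chains.shape
    half = n // 2
    split = chains[:, : 2 * half].reshape(n_chains * 2, half)
    m, n_s = split.shape
    means = split.mean(axis=1)
    variances = split.var(axis=1, ddof=1)
    w = variances.mean()
    b = n_s * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n_s - 1) / n_s * w + b / n_s
    return float(np.sqrt(var_plus / w))


def _log_posterior(theta: np.ndarray, s1, s2, n, cfg: ModelConfig) -> np.ndarray:
    """Unnormalised log posterior on theta = (log alpha, log beta).

    Includes the log-Jacobian of the log transform, so the chain targets the
    Gamma priors exactly on the original scale.
    """
    la, lb = theta[..., 0], theta[..., 1]
    a, b = np.exp(la), np.exp(lb)
    loglik = (a - 1.0) * s1 + (b - 1.0) * s2 - n * (
        gammaln(a) + gammaln(b) - gammaln(a + b)
    )
    k, sc = cfg.prior_shape, cfg.prior_scale
    logprior = (k - 1.0) * (np.log(a) + np.log(b)) - (a + b) / sc
    return loglik + logprior + la + lb


def fit_beta_units(
    data: list[np.ndarray], cfg: ModelConfig, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Metropolis fit of independent Beta units.

    ``data[u]`` holds the clipped proportions of unit ``u`` (possibly empty,
    which samples the prior). Returns (alpha, beta) draw arrays of shape
    (units, chains * draws) plus per-unit split-R-hat for each parameter.
    """
    n_units = len(data)
    s1 = np.zeros(n_units)
    s2 = np.zeros(n_units)
    n_obs = np.zeros(n_units)
    for u, x in enumerate(data):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if np.any((x <= 0) | (x >= 1)):
            raise ValueError(
                f"unit {u}: proportions must lie strictly in (0, 1); clip first"
            )
        s1[u] = np.log(x).sum()
        s2[u] = np.log1p(-x).sum()
        n_obs[u] = len(x)

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = (cfg.chains, n_units, 2)
    # overdispersed start: prior draws on the log scale
    theta = np.log(rng.gamma(cfg.prior_shape, cfg.prior_scale, size=shape))
    logp = _log_posterior(theta, s1, s2, n_obs, cfg)
    step = np.full((cfg.chains, n_units), cfg.proposal_sd)
    accepted = np.zeros((cfg.chains, n_units))
    kept = np.empty((cfg.chains, cfg.draws, n_units, 2))

    total = cfg.burn_in + cfg.draws
    for it in range(total):
        prop = theta + step[..., None] * rng.standard_normal(shape)
        logp_prop = _log_posterior(prop, s1, s2, n_obs, cfg)
        accept = np.log(rng.random((cfg.chains, n_units))) < logp_prop - logp
        theta = np.where(accept[..., None], prop, theta)
        logp = np.where(accept, logp_prop, logp)
        accepted += accept
        if it < cfg.burn_in and (it + 1) % 100 == 0:
            rate = accepted / 100.0
            step = np.where(rate < 0.20, step * 0.7, step)
            step = np.where(rate > 0.40, step * 1.3, step)
            accepted[:] = 0.0
        if it >= cfg.burn_in:
            kept[:, it - cfg.burn_in] = theta

    draws = np.exp(kept)  # (chains, draws, units, 2)
    alpha = draws[..., 0]
    beta = draws[..., 1]
    rhat_a = np.array([split_rhat(alpha[:, :, u]) for u in range(n_units)])
    rhat_b = np.array([split_rhat(beta[:, :, u]) for u in range(n_units)])
    pooled_a = alpha.transpose(2, 0, 1).reshape(n_units, -1)
    pooled_b = beta.transpose(2, 0, 1).reshape(n_units, -1)
    return pooled_a, pooled_b, rhat_a, rhat_b


def fit_beta_model(
    matrix, cfg: ModelConfig | None = None, seed: int | None = None
) -> list[BetaPosterior]:
    """Fit the Beta model for every isoform x condition of one usage matrix.

    ``matrix`` is a :class:`~splicecraft.usage.PromoterUsageMatrix`. Draws
    are reproducible for a fixed seed.
    """
    cfg = cfg or ModelConfig()
    units: list[tuple[str, str]] = []
    data: list[np.ndarray] = []
    for iso in matrix.isoforms:
        for cond in matrix.conditions:
            units.append((iso, cond))
            data.append(matrix.values_for(iso, cond))
    alpha, beta, ra, rb = fit_beta_units(data, cfg, seed)
    out = []
    for u, (iso, cond) in enumerate(units):
        if ra[u] > 1.1 or rb[u] > 1.1:
            log.warning("isoform %s/%s: split-R-hat %.3f/%.3f above 1.1",
                        iso, cond, ra[u], rb[u])
        out.append(BetaPosterior(iso, cond, alpha[u], beta[u], float(ra[u]), float(rb[u])))
    return out


def call_differential(
    posteriors: list[BetaPosterior],
    cfg: ModelConfig | None = None,
    conditions: tuple[str, str] = ("young", "aged"),
) -> list[DifferentialCall]:
    """Pair condition posteriors per isoform and apply the decision rule.

    The fold change is log2(mu_aged / mu_young): positive values mean higher
    usage in the second (aged) condition.
    """
    cfg = cfg or ModelConfig()
    young, aged = conditions
    by_iso: dict[str, dict[str, BetaPosterior]] = {}
    for p in posteriors:
        by_iso.setdefault(p.isoform, {})[p.condition] = p
    calls = []
    for iso, conds in by_iso.items():
        if young not in conds or aged not in conds:
            raise ValueError(f"isoform {iso}: missing posterior for a condition")
        mu_y, mu_a = conds[young].mu, conds[aged].mu
        if len(mu_y) != len(mu_a):
            log.warning("isoform %s: unequal chain lengths, truncating", iso)
            m = min(len(mu_y), len(mu_a))
            mu_y, mu_a = mu_y[:m], mu_a[:m]
        l2 = np.log2(mu_a / mu_y)
        lo, hi = hpd_interval(l2, cfg.hpd_mass)
        p_up = float((l2 > 0).mean())
        significant = (lo > 0 or hi < 0) and max(p_up, 1 - p_up) > cfg.prob_threshold
        med = float(np.median(l2))
        calls.append(
            DifferentialCall(
                isoform=iso,
                log2fc=l2,
                log2fc_median=med,
                hpd_low=lo,
                hpd_high=hi,
                p_up=p_up,
                significant=bool(significant),
                direction="up" if med > 0 else ("down" if med < 0 else "none"),
            )
        )
    return calls
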