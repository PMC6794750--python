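"""Meta-QTL estimation: heteroscedastic Gaussian mixture over QTL peaks.

Co-located QTL observations on one linkage group are modelled as draws from
a mixture of K "true" loci:

    x_i ~ sum_k pi_k * N(mu_k, sigma_i^2)

where x_i is the projected peak of QTL i and sigma_i is known, derived from
its confidence interval (sigma_i = CI_i / 3.92 for a 95% interval).  Only
the K means and K-1 independent weights are free parameters (p = 2K - 1);
the per-observation variances are data, not parameters.  The fit uses EM:

    E-step:  z_ik  proportional to  pi_k * phi(x_i; mu_k, sigma_i^2)
    M-step:  mu_k = (sum_i z_ik x_i / sigma_i^2) / (sum_i z_ik / sigma_i^2)
             pi_k = mean_i z_ik

K is scanned from 1 to min(n, K_max) and the winner is chosen by majority
vote of five information criteria (AIC, AICc, AIC3, BIC, AWE), each voting
for the K it minimizes; vote ties go to the smaller K.  Each selected
cluster becomes a meta-QTL whose peak is mu_k and whose 95% CI combines the
members' precisions: sigma_meta^2 = 1 / sum_{i in k} sigma_i^-2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .colocalization import _qtl_overlaps, _single_linkage, prune_redundant
from .models import MetaQTL, ProjectedQTL

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2 * math.pi)


@dataclass(frozen=True)
class QTLObservation:
    """One projected QTL reduced to the mixture model's sufficient data."""

    qtl_id: str
    x: float
    sigma: float
    r2: Optional[float] = None
    study_ref: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"observation {self.qtl_id!r}: sigma must be > 0")


def sd_from_ci(ci_length: float, level: float = 0.95) -> float:
    """Standard deviation implied by a symmetric normal confidence interval.

    sigma = L / (2 * z_{(1+level)/2}); for a 95% interval, sigma = L / 3.92.
    """
    if ci_length <= 0:
        raise ValueError(f"CI length must be positive, got {ci_length}")
    z = stats.norm.ppf((1 + level) / 2)
    return ci_length / (2 * z)


def observation_from_projected(q: ProjectedQTL,
                               level: float = 0.95) -> QTLObservation:
    if q.ci_start_cm is None or q.peak_cm is None:
        raise ValueError(f"QTL {q.qtl_id!r} lacks projected peak or CI")
    return QTLObservation(
        qtl_id=q.qtl_id,
        x=q.peak_cm,
        sigma=sd_from_ci(q.ci_end_cm - q.ci_start_cm, level),
        r2=q.record.r2,
        study_ref=q.record.study_ref,
        trait=q.record.trait,
    )


@dataclass
class MixtureFit:
    """A converged EM fit for one candidate cluster count K."""

    K: int
    mu: np.ndarray          # (K,) sorted ascending
    pi: np.ndarray          # (K,)
    z: np.ndarray           # (n, K) posterior memberships
    log_likelihood: float
    n_iter: int
    converged: bool
    degenerate: bool = False
    criteria: dict[str, Optional[float]] = field(default_factory=dict)


def _log_components(x: np.ndarray, sigma: np.ndarray, mu: np.ndarray,
                    pi: np.ndarray) -> np.ndarray:
    """log(pi_k * phi(x_i; mu_k, sigma_i^2)), shape (n, K)."""
    resid = (x[:, None] - mu[None, :]) / sigma[:, None]
    log_phi = -0.5 * (resid ** 2) - np.log(sigma)[:, None] - 0.5 * _LOG_2PI
    return np.log(pi)[None, :] + log_phi


def _em_once(x: np.ndarray, sigma: np.ndarray, mu0: np.ndarray,
             tol: float, max_iter: int) -> MixtureFit:
    K = len(mu0)
    mu = mu0.astype(float).copy()
    pi = np.full(K, 1.0 / K)
    w = 1.0 / sigma ** 2
    prev = -np.inf
    converged = False
    z = np.full((len(x), K), 1.0 / K)
    for it in range(1, max_iter + 1):
        log_comp = _log_components(x, sigma, mu, pi)
        log_norm = logsumexp(log_comp, axis=1)
        log_likelihood = float(np.sum(log_norm))
        # EM guarantee: the observed-data log-likelihood never decreases
        assert log_likelihood >= prev - 1e-8, "EM log-likelihood decreased"
        z = np.exp(log_comp - log_norm[:, None])
        if log_likelihood - prev < tol and it > 1:
            converged = True
            prev = log_likelihood
            break
        prev = log_likelihood
        zw = z * w[:, None]
        denom = zw.sum(axis=0)
        mu = np.where(denom > 0, (zw * x[:, None]).sum(axis=0) / np.maximum(denom, 1e-300), mu)
        pi = np.clip(z.mean(axis=0), 1e-300, None)
        pi = pi / pi.sum()
    order = np.argsort(mu)
    hard = np.argmax(z, axis=1)
    degenerate = len(np.unique(hard)) < K
    return MixtureFit(K=K, mu=mu[order], pi=pi[order], z=z[:, order],
                      log_likelihood=prev, n_iter=it, converged=converged,
                      degenerate=degenerate)


def _init_means(x: np.ndarray, K: int, restart: int,
                rng: np.random.Generator) -> np.ndarray:
    """Seeding for one restart: quantile spread first, random picks after."""
    if restart == 0:
        qs = (np.arange(K) + 0.5) / K
        return np.quantile(x, qs)
    idx = rng.choice(len(x), size=K, replace=len(x) < K)
    return x[idx].astype(float)


def em_fit(obs: list[QTLObservation], K: int, restarts: int = 10,
           tol: float = 1e-8, seed: int = 0,
           max_iter: int = 500) -> MixtureFit:
    """Best-of-restarts EM fit of the K-component known-variance mixture.

    Restart 0 seeds means at the quantiles of the peaks; subsequent
    restarts draw K starting means from the observed peaks.  Fits ending
    with an empty hard cluster are retried; if every restart degenerates,
    the best-likelihood fit is returned flagged ``degenerate``.
    """
    n = len(obs)
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside 1..n={n}")
    x = np.array([o.x for o in obs], dtype=float)
    sigma = np.array([o.sigma for o in obs], dtype=float)
    rng = np.random.default_rng(seed)
    best: Optional[MixtureFit] = None
    best_clean: Optional[MixtureFit] = None
    for r in range(max(1, restarts)):
        fit = _em_once(x, sigma, _init_means(x, K, r, rng), tol, max_iter)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
        if not fit.degenerate and (
            best_clean is None or fit.log_likelihood > best_clean.log_likelihood
        ):
            best_clean = fit
    return best_clean if best_clean is not None else best


def model_criteria(fit: MixtureFit, obs: list[QTLObservation]
                   ) -> dict[str, Optional[float]]:
    """The five selection criteria for one fit.

    With p = 2K - 1 free parameters (variances are known):
      AIC  = -2 logL + 2p
      AICc = AIC + 2p(p+1)/(n-p-1)        (undefined when n-p-1 <= 0)
      AIC3 = -2 logL + 3p
      BIC  = -2 logL + p ln n
      AWE  = -2 logL_c + 2p(3/2 + ln n)   (classification likelihood,
                                           hard assignments)
    """
    n = len(obs)
    p = 2 * fit.K - 1
    ll = fit.log_likelihood
    x = np.array([o.x for o in obs])
    sigma = np.array([o.sigma for o in obs])
    log_comp = _log_components(x, sigma, fit.mu, fit.pi)
    hard = np.argmax(fit.z, axis=1)
    ll_c = float(log_comp[np.arange(n), hard].sum())
    aic = -2 * ll + 2 * p
    crit: dict[str, Optional[float]] = {
        "AIC": aic,
        "AICc": aic + 2 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else None,
        "AIC3": -2 * ll + 3 * p,
        "BIC": -2 * ll + p * math.log(n),
        "AWE": -2 * ll_c + 2 * p * (1.5 + math.log(n)),
    }
    fit.criteria = crit
    return crit


def select_model(fits: list[MixtureFit]) -> MixtureFit:
    """Majority vote of the criteria; each votes for the K it minimizes.

    Vote ties resolve to the smallest tied K, then to the smallest AIC.
    Fits must already carry their criteria values.
    """
    if not fits:
        raise ValueError("no fits to select from")
    names = ["AIC", "AICc", "AIC3", "BIC", "AWE"]
    votes: dict[int, int] = {}
    for name in names:
        defined = [f for f in fits if f.criteria.get(name) is not None]
        if not defined:
            continue
        winner = min(defined, key=lambda f: (f.criteria[name], f.K))
        votes[winner.K] = votes.get(winner.K, 0) + 1
    by_k = {f.K: f for f in fits}
    best_k = min(
        votes,
        key=lambda k: (-votes[k], k, by_k[k].criteria.get("AIC", math.inf)),
    )
    logger.debug("criterion votes: %s -> K*=%d", votes, best_k)
    return by_k[best_k]


def summarize_metaqtl(fit: MixtureFit, obs: list[QTLObservation], lg: str,
                      prefix: str = "mq", level: float = 0.95
                      ) -> list[MetaQTL]:
    """Turn a selected fit into named meta-QTL records.

    Members are the hard assignments; the meta CI combines member
    precisions (sigma_meta^2 = 1 / sum sigma_i^-2); mean R² is the
    unweighted mean over members reporting one.  Clusters left without
    members are dropped with a warning.
    """
    z_crit = stats.norm.ppf((1 + level) / 2)
    hard = np.argmax(fit.z, axis=1)
    out: list[MetaQTL] = []
    for k in range(fit.K):
        members = [o for o, h in zip(obs, hard) if h == k]
        if not members:
            logger.warning("LG %s: cluster %d empty after hard assignment", lg, k)
            continue
        sigma_meta = 1.0 / math.sqrt(sum(1.0 / o.sigma ** 2 for o in members))
        r2s = [o.r2 for o in members if o.r2 is not None]
        out.append(
            MetaQTL(
                name="",  # assigned after peak sort
                lg=lg,
                peak_cm=float(fit.mu[k]),
                ci_start_cm=float(fit.mu[k] - z_crit * sigma_meta),
                ci_end_cm=float(fit.mu[k] + z_crit * sigma_meta),
                mean_r2=float(np.mean(r2s)) if r2s else None,
                member_ids=[o.qtl_id for o in members],
                n_studies=len({o.study_ref for o in members}),
                traits=sorted({o.trait for o in members if o.trait}),
            )
        )
    out.sort(key=lambda m: m.peak_cm)
    for rank, m in enumerate(out, start=1):
        m.name = f"{prefix}_{lg}.{rank}"
    return out


def _has_overlapping_pair(qtls: list[ProjectedQTL]) -> bool:
    return any(len(c) >= 2 for c in _single_linkage(qtls))


def run_meta_analysis(projected: list[ProjectedQTL], focal_trait: str,
                      lg: str, mode: str = "single-trait",
                      other_traits: Optional[set[str]] = None,
                      prefix: Optional[str] = None, k_max: int = 10,
                      restarts: int = 10, tol: float = 1e-8,
                      seed: int = 0) -> list[MetaQTL]:
    """Meta-analysis of one trait's QTLs on one linkage group.

    ``single-trait`` mode clusters only the focal trait's projected QTLs;
    ``cross-trait`` mode pools them with QTLs of the given other traits
    whose CIs overlap a focal QTL.  Requires at least two overlapping
    focal-trait QTLs after same-study pruning; otherwise no meta-QTL is
    produced.
    """
    if mode not in ("single-trait", "cross-trait"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = [
        q for q in projected
        if q.projected and q.record.lg == lg and q.ci_start_cm is not None
    ]
    focal = prune_redundant([q for q in usable if q.record.trait == focal_trait])
    if len(focal) < 2 or not _has_overlapping_pair(focal):
        logger.info("LG %s / %s: <2 overlapping QTLs; no meta-analysis", lg,
                    focal_trait)
        return []
    pool = list(focal)
    if mode == "cross-trait":
        others = [
            q for q in usable
            if q.record.trait != focal_trait
            and (other_traits is None or q.record.trait in other_traits)
        ]
        others = prune_redundant(others)
        pool += [q for q in others if any(_qtl_overlaps(q, f) for f in focal)]
    obs = [observation_from_projected(q) for q in pool]
    n = len(obs)
    fits = []
    for K in range(1, min(n, k_max) + 1):
        fit = em_fit(obs, K, restarts=restarts, tol=tol, seed=seed + K)
        model_criteria(fit, obs)
        fits.append(fit)
    best = select_model(fits)
    if prefix is None:
        prefix = focal_trait if mode == "single-trait" else f"{focal_trait}/ph"
    result = summarize_metaqtl(best, obs, lg, prefix=prefix)
    logger.info("LG %s / %s (%s): n=%d QTLs -> K=%d meta-QTLs", lg,
                focal_trait, mode, n, best.K)
    return result
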