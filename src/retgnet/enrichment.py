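"""Bayesian network enrichment of GWAS summary statistics.

Per-SNP true effects follow a spike-and-slab prior whose inclusion
probability and slab variance shift for SNPs annotated to a regulatory
network:

    beta_j ~ pi_j N(0, sigma_j^2) + (1 - pi_j) delta_0
    pi_j      = theta0 + a_j * theta
    sigma_j^2 = sigma0^2 + a_j * sigma^2

with a_j = 1 iff SNP j lies within a +-window (default 50 kb, closed) of
any RE or target gene of the network. The prior is combined with the
multiple-regression summary-statistics likelihood

    betahat | beta ~ N(S R S^{-1} beta, S R S),   S = diag(se_j), R = LD,

fitted by mean-field coordinate-ascent variational inference over a grid
of hyperparameters. Enrichment strength is summarized as a Bayes factor
comparing enrichment models (M1: theta>0 or sigma^2>0; M11: theta>0 and
sigma^2=0; M12: theta>0 and sigma^2>0) against the baseline M0
(theta=0 and sigma^2=0), averaging marginal likelihoods uniformly over the
grid points each model allows.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import logsumexp

from .intervals import IntervalIndex, ValidationError
from .network import RETGNetwork

logger = logging.getLogger(__name__)

MODELS = ("M0", "M1", "M11", "M12")

try:  # numba accelerates the coordinate-ascent sweeps; numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def annotate_snps(
    snps: pd.DataFrame,
    network: RETGNetwork | None = None,
    genes: pd.DataFrame | None = None,
    window: int = 50_000,
    mode: str = "network",
) -> np.ndarray:
    """Per-SNP 0/1 annotation vector.

    mode='network': a_j = 1 iff the SNP is within the closed +-window of
    any RE interval of the network or the gene body of any target gene
    (genes linked through a loop anchor). mode='near_gene': within the
    window of any gene body in ``genes`` (the near-gene control network).
    ``snps`` needs columns chrom and pos. Unknown chromosomes get a_j = 0
    with a warning.
    """
    index = IntervalIndex()
    known_chroms: set[str] = set()
    if mode == "network":
        if network is None:
            raise ValidationError("mode='network' requires a network")
        for e in network.elements.values():
            index.add(e.interval)
            known_chroms.add(e.interval.chrom)
        targets = {
            g for g in network.genes if network.gene_category[g] != "NoLoop"
        }
        if genes is not None:
            for row in genes.itertuples(index=False):
                if row.gene in targets:
                    from .intervals import GenomicInterval

                    index.add(GenomicInterval(row.chrom, row.start, row.end))
                    known_chroms.add(row.chrom)
    elif mode == "near_gene":
        if genes is None:
            raise ValidationError("mode='near_gene' requires gene models")
        from .intervals import GenomicInterval

        for row in genes.itertuples(index=False):
            index.add(GenomicInterval(row.chrom, row.start, row.end))
            known_chroms.add(row.chrom)
    else:
        raise ValidationError(f"unknown annotation mode {mode!r}")

    a = np.zeros(len(snps), dtype=np.int8)
    warned: set[str] = set()
    for j, row in enumerate(snps.itertuples(index=False)):
        if known_chroms and row.chrom not in known_chroms:
            if row.chrom not in warned:
                warnings.warn(f"annotate_snps: unknown chromosome {row.chrom}")
                warned.add(row.chrom)
            continue
        if index.any_within(row.chrom, int(row.pos), window):
            a[j] = 1
    return a


# --------------------------------------------------------------------------
# prior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSizePrior:
    """Hyperparameters of the network-modulated spike-and-slab prior."""

    theta0: float
    theta: float
    sigma0sq: float
    sigmasq: float

    def __post_init__(self) -> None:
        if self.theta < 0 or self.sigmasq < 0 or self.sigma0sq < 0:
            raise ValidationError("theta, sigma0sq, sigmasq must be >= 0")


def prior_at(prior: EffectSizePrior, a_j: int) -> tuple[float, float]:
    """(pi_j, sigma_j^2) for a SNP with annotation ``a_j``."""
    pi = prior.theta0 + a_j * prior.theta
    if not 0.0 < pi < 1.0:
        raise ValidationError(
            f"pi_j = {pi} outside (0,1); the hyperparameter grid is misconfigured"
        )
    return pi, prior.sigma0sq + a_j * prior.sigmasq


def default_grid(n: int | float) -> pd.DataFrame:
    """Default hyperparameter grid.

    theta0 in {1e-4, 1e-3, 1e-2, 0.05}; theta in {0, 1e-3, 1e-2, 0.05};
    sigma0^2 in {0.01, 0.05, 0.1}/n; sigma^2 in {0, 0.5, 1, 2} * sigma0^2.
    Points with pi outside (0,1) are dropped.
    """
    rows = []
    for t0, t, s0_scale, s_mult in itertools.product(
        (1e-4, 1e-3, 1e-2, 0.05),
        (0.0, 1e-3, 1e-2, 0.05),
        (0.01, 0.05, 0.1),
        (0.0, 0.5, 1.0, 2.0),
    ):
        if not 0 < t0 + t < 1:
            continue
        s0 = s0_scale / n
        rows.append((t0, t, s0, s_mult * s0))
    return pd.DataFrame(
        rows, columns=["theta0", "theta", "sigma0sq", "sigmasq"]
    ).drop_duplicates(ignore_index=True)


def make_grid(theta0, theta, sigma0sq, sigmasq_mult) -> pd.DataFrame:
    """Cartesian grid from explicit value lists (sigma^2 as multiples of
    sigma0^2), filtered to pi in (0,1)."""
    rows = [
        (t0, t, s0, m * s0)
        for t0, t, s0, m in itertools.product(theta0, theta, sigma0sq, sigmasq_mult)
        if 0 < t0 + t < 1
    ]
    return pd.DataFrame(
        rows, columns=["theta0", "theta", "sigma0sq", "sigmasq"]
    ).drop_duplicates(ignore_index=True)


def model_mask(grid: pd.DataFrame, model: str) -> np.ndarray:
    """Grid points allowed by a model's (theta, sigma^2) constraint."""
    t = grid["theta"].to_numpy()
    s = grid["sigmasq"].to_numpy()
    if model == "M0":
        return (t == 0) & (s == 0)
    if model == "M11":
        return (t > 0) & (s == 0)
    if model == "M12":
        return (t > 0) & (s > 0)
    if model == "M1":
        return (t > 0) | (s > 0)
    raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")


# --------------------------------------------------------------------------
# variational inference
# --------------------------------------------------------------------------

@njit(cache=False)
def _ca_sweeps(A, q, logit_pi, sigma2, order, alpha, mu, max_iter, rtol):
    """Coordinate-ascent sweeps for the spike-and-slab posterior.

    Maximizes the ELBO of q(beta_j) = alpha_j N(mu_j, tau_j^2) +
    (1-alpha_j) delta_0 under loglik = const + q.beta - 0.5 beta' A beta.
    Returns (elbo_history, n_iter, converged).
    """
    p = A.shape[0]
    tau2 = np.empty(p)
    for j in range(p):
        if sigma2[j] > 0.0:
            tau2[j] = 1.0 / (A[j, j] + 1.0 / sigma2[j])
        else:
            tau2[j] = 0.0
            alpha[j] = 0.0
            mu[j] = 0.0
    elbo_hist = np.empty(max_iter)
    elbo_prev = -np.inf
    n_iter = 0
    converged = False
    for it in range(max_iter):
        r = alpha * mu
        Ar = A @ r
        for oi in range(p):
            j = order[oi]
            if sigma2[j] <= 0.0:
                continue
            r_j = alpha[j] * mu[j]
            mu_new = tau2[j] * (q[j] - (Ar[j] - A[j, j] * r_j))
            u = (
                logit_pi[j]
                + 0.5 * np.log(tau2[j] / sigma2[j])
                + mu_new * mu_new / (2.0 * tau2[j])
            )
            if u > 0:
                a_new = 1.0 / (1.0 + np.exp(-u))
            else:
                eu = np.exp(u)
                a_new = eu / (1.0 + eu)
            dr = a_new * mu_new - r_j
            if dr != 0.0:
                Ar += A[:, j] * dr
            alpha[j] = a_new
            mu[j] = mu_new
        # ELBO
        r = alpha * mu
        Ar = A @ r
        e_loglik = 0.0
        kl = 0.0
        for j in range(p):
            e_loglik += q[j] * r[j]
            if sigma2[j] <= 0.0:
                continue
            m2 = alpha[j] * (mu[j] * mu[j] + tau2[j])
            e_loglik -= 0.5 * A[j, j] * (m2 - r[j] * r[j])
            aj = alpha[j]
            pi_term = 1.0 / (1.0 + np.exp(-logit_pi[j]))
            if aj > 1e-300:
                kl += aj * np.log(aj / pi_term)
            if 1.0 - aj > 1e-300:
                kl += (1.0 - aj) * np.log((1.0 - aj) / (1.0 - pi_term))
            kl += 0.5 * aj * (
                np.log(sigma2[j] / tau2[j])
                + (tau2[j] + mu[j] * mu[j]) / sigma2[j]
                - 1.0
            )
        e_loglik -= 0.5 * (r @ Ar)
        elbo = e_loglik - kl
        elbo_hist[it] = elbo
        n_iter = it + 1
        if it > 0 and abs(elbo - elbo_prev) < rtol * max(1.0, abs(elbo)):
            converged = True
            break
        elbo_prev = elbo
    return elbo_hist[:n_iter], n_iter, converged


def _loglik_constant(betahat, se, R, cho) -> float:
    """log N(betahat; 0, S R S) evaluated pieces shared by all beta."""
    p = len(betahat)
    z = betahat / se
    quad = float(z @ sla.cho_solve(cho, z))
    logdet_R = 2.0 * np.sum(np.log(np.diag(cho[0])))
    logdet = logdet_R + 2.0 * np.sum(np.log(se))
    return -0.5 * (p * np.log(2 * np.pi) + logdet + quad)


def _prepare_ld(R: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Validate/regularize the LD matrix and return its Cholesky factor."""
    R = np.asarray(R, dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-8):
        raise ValidationError("LD matrix must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValidationError("LD matrix must have unit diagonal")
    try:
        cho = sla.cho_factor(R, lower=True)
    except sla.LinAlgError:
        logger.warning("LD matrix not PD; adding 1e-6 to the diagonal")
        R = R + 1e-6 * np.eye(R.shape[0])
        cho = sla.cho_factor(R, lower=True)
    return R, cho


@dataclass
class EnrichmentFit:
    """Grid of hyperparameter points with approximate log marginal
    likelihoods (converged ELBOs) and posterior inclusion probabilities."""

    grid: pd.DataFrame  # + columns logml, converged, n_iter
    pip: np.ndarray  # (n_points, p)
    elbo_histories: list = field(default_factory=list)

    def bayes_factor(self, model: str, baseline: str = "M0") -> float:
        return bayes_factor(self, model, baseline)


def fit_grid(
    stats: pd.DataFrame,
    ld: np.ndarray,
    annotation: np.ndarray,
    grid: pd.DataFrame,
    max_iter: int = 1000,
    rtol: float = 1e-7,
) -> EnrichmentFit:
    """Variational fit at every grid point.

    ``stats`` needs columns betahat and se; ``annotation`` is the 0/1
    vector a_j. Non-converged points are flagged and excluded from model
    averaging with a warning. SNPs are updated in descending |betahat/se|
    order (fixed, for determinism).
    """
    if len(grid) == 0:
        raise ValidationError("hyperparameter grid is empty")
    betahat = stats["betahat"].to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    if (se <= 0).any():
        raise ValidationError("standard errors must be > 0")
    a = np.asarray(annotation, dtype=np.int8)
    p = len(betahat)
    R, cho = _prepare_ld(ld)

    sinv = 1.0 / se
    A = (R * sinv[:, None]) * sinv[None, :]
    q = betahat / se**2
    order = np.argsort(-np.abs(betahat / se), kind="stable").astype(np.int64)
    const = _loglik_constant(betahat, se, R, cho)

    logml = np.empty(len(grid))
    conv = np.zeros(len(grid), dtype=bool)
    iters = np.zeros(len(grid), dtype=int)
    pips = np.empty((len(grid), p))
    histories = []
    for i, point in enumerate(grid.itertuples(index=False)):
        prior = EffectSizePrior(point.theta0, point.theta, point.sigma0sq, point.sigmasq)
        pi = np.empty(p)
        sigma2 = np.empty(p)
        for j in range(p):
            pi[j], sigma2[j] = prior_at(prior, int(a[j]))
        if np.all(sigma2 <= 0):
            # degenerate slab: beta = 0 a.s., evidence is the null likelihood
            logml[i] = const
            conv[i] = True
            pips[i] = pi
            histories.append(np.array([const]))
            continue
        alpha = pi.copy()
        mu = np.zeros(p)
        logit_pi = np.log(pi) - np.log1p(-pi)
        hist, n_it, ok = _ca_sweeps(
            A, q, logit_pi, sigma2, order, alpha, mu, max_iter, rtol
        )
        if np.any(np.diff(hist) < -1e-6 * np.maximum(1.0, np.abs(hist[:-1]))):
            raise AssertionError("ELBO decreased during coordinate ascent")
        logml[i] = const + hist[-1]
        conv[i] = ok
        iters[i] = n_it
        pips[i] = alpha
        histories.append(hist)
        if not ok:
            logger.warning(
                "fit_grid: point %d (theta0=%g, theta=%g) did not converge in "
                "%d iterations; excluded from model averaging",
                i, point.theta0, point.theta, max_iter,
            )
    out = grid.copy()
    out["logml"] = logml
    out["converged"] = conv
    out["n_iter"] = iters
    return EnrichmentFit(grid=out, pip=pips, elbo_histories=histories)


def bayes_factor(fit: EnrichmentFit, model: str, baseline: str = "M0") -> float:
    """BF = mean_{grid points allowed by model} exp(logml) over the same
    mean for the baseline, computed in log space. Non-converged points are
    excluded."""
    usable = fit.grid["converged"].to_numpy()
    lml = fit.grid["logml"].to_numpy()

    def log_mean(name: str) -> float:
        mask = model_mask(fit.grid, name) & usable
        if not mask.any():
            raise ValidationError(f"no converged grid points for model {name}")
        return float(logsumexp(lml[mask]) - np.log(mask.sum()))

    return float(np.exp(log_mean(model) - log_mean(baseline)))


# --------------------------------------------------------------------------
# exact oracle (small p)
# --------------------------------------------------------------------------

def exact_log_marginal(
    betahat, se, R, pi, sigma2
) -> float:
    """Exact log marginal likelihood by summing all 2^p inclusion
    configurations with analytic Gaussian integration (p <= 12)."""
    betahat = np.asarray(betahat, dtype=float)
    se = np.asarray(se, dtype=float)
    pi = np.asarray(pi, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    p = len(betahat)
    if p > 12:
        raise ValidationError("exact enumeration limited to p <= 12 SNPs")
    R, _ = _prepare_ld(np.asarray(R, dtype=float))
    S = np.diag(se)
    Sigma = S @ R @ S
    M = S @ R @ np.diag(1.0 / se)  # S R S^{-1}
    log_pi = np.log(pi)
    log_1mpi = np.log1p(-np.asarray(pi))
    terms = []
    for bits in itertools.product((0, 1), repeat=p):
        gamma = np.array(bits, dtype=bool)
        cov = Sigma.copy()
        if gamma.any():
            Mg = M[:, gamma]
            cov = cov + (Mg * sigma2[gamma]) @ Mg.T
        sign, logdet = np.linalg.slogdet(cov)
        quad = betahat @ np.linalg.solve(cov, betahat)
        logpdf = -0.5 * (p * np.log(2 * np.pi) + logdet + quad)
        logw = log_pi[gamma].sum() + log_1mpi[~gamma].sum()
        terms.append(logw + logpdf)
    return float(logsumexp(np.array(terms)))


def exact_bf_oracle(
    stats: pd.DataFrame,
    ld: np.ndarray,
    annotation: np.ndarray,
    grid: pd.DataFrame,
    model: str,
    baseline: str = "M0",
) -> float:
    """Model-level Bayes factor from exact per-point log marginals.

    Independent of the variational path: every 2^p configuration is
    enumerated analytically. Refuses p > 12.
    """
    betahat = stats["betahat"].to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    a = np.asarray(annotation, dtype=np.int8)
    p = len(betahat)
    logml = np.empty(len(grid))
    for i, point in enumerate(grid.itertuples(index=False)):
        prior = EffectSizePrior(point.theta0, point.theta, point.sigma0sq, point.sigmasq)
        pi = np.empty(p)
        sigma2 = np.empty(p)
        for j in range(p):
            pi[j], sigma2[j] = prior_at(prior, int(a[j]))
        logml[i] = exact_log_marginal(betahat, se, ld, pi, sigma2)

    def log_mean(name: str) -> float:
        mask = model_mask(grid, name)
        if not mask.any():
            raise ValidationError(f"no grid points for model {name}")
        return float(logsumexp(logml[mask]) - np.log(mask.sum()))

    return float(np.exp(log_mean(model) - log_mean(baseline)))


def exact_grid_logml(
    stats: pd.DataFrame, ld: np.ndarray, annotation: np.ndarray, grid: pd.DataFrame
) -> np.ndarray:
    """Exact per-grid-point log marginals (enumeration; p <= 12)."""
    betahat = stats["betahat"].to_numpy(dtype=float)
    se = stats["se"].to_numpy(dtype=float)
    a = np.asarray(annotation, dtype=np.int8)
    p = len(betahat)
    out = np.empty(len(grid))
    for i, point in enumerate(grid.itertuples(index=False)):
        prior = EffectSizePrior(point.theta0, point.theta, point.sigma0sq, point.sigmasq)
        pi = np.empty(p)
        sigma2 = np.empty(p)
        for j in range(p):
            pi[j], sigma2[j] = prior_at(prior, int(a[j]))
        out[i] = exact_log_marginal(betahat, se, ld, pi, sigma2)
    return out
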