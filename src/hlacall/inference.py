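"""Read-mixture abundance estimation over the allele panel.

Each sequenced fragment i is modelled as drawn from one (unknown) panel
allele z_i with mixing proportions theta ~ Dirichlet(alpha0); the observed
data enter through the per-fragment per-allele alignment log-likelihoods
ll_ij. Because HLA alleles of one gene are nearly identical, most fragments
are multi-mapped and the posterior over theta — not any single best hit —
carries the genotype signal.

Two fitting modes share one interface:

* **VB** — mean-field variational Bayes with q(theta) Dirichlet and q(z)
  categorical. Updates: z_ij ∝ exp(psi(alpha_j) - psi(sum alpha)) *
  exp(ll_ij) normalized per fragment; alpha_j = alpha0 + sum_i z_ij. The
  ELBO is monotone non-decreasing and convergence is on mean |Δalpha|.
  A sparse prior (alpha0 < 1) pushes mass onto few alleles, which is what a
  diploid sample should look like.
* **EM** — maximum-likelihood fit of theta (uniform prior over assignments),
  used as the cross-checking oracle: z_ij ∝ theta_j exp(ll_ij),
  theta_j = sum_i z_ij / N.

Both run in the log domain with per-fragment max subtraction (likelihood
ratios across alleles span hundreds of log units) and start from uniform
responsibilities, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import digamma, gammaln

from .evidence import EvidenceMatrix
from .panel import ReferencePanel

__all__ = ["MixtureConfig", "AbundanceEstimate", "vb_fit", "em_fit", "expected_depth"]

DEFAULT_ALPHA0 = 0.2
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class MixtureConfig:
    """Fit settings.

    alpha0
        Dirichlet prior concentration per allele. The default 0.2 favors
        sparse mixtures — a diploid sample uses at most two alleles per gene
        out of hundreds in the panel.
    tol
        Convergence threshold on the mean absolute change of the variational
        parameters (alpha for VB, N*theta for EM) between iterations.
    """

    alpha0: float = DEFAULT_ALPHA0
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    mode: str = "VB"

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.mode not in ("VB", "EM"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AbundanceEstimate:
    """Fitted per-allele abundances.

    ``alpha`` are posterior Dirichlet parameters (VB) or their EM analogue
    alpha0 + expected counts; ``expected_counts`` are summed responsibilities
    (they sum exactly to the number of fragments); ``theta_mean`` is the
    posterior-mean (VB) or maximum-likelihood (EM) mixing proportion;
    ``depth`` is filled by :func:`expected_depth`.
    """

    alleles: list[str]
    alpha: np.ndarray
    expected_counts: np.ndarray
    theta_mean: np.ndarray
    n_iter: int
    converged: bool
    elbo_trace: list[float]
    mode: str
    responsibilities: np.ndarray | None = None
    depth: np.ndarray | None = None

    def as_mapping(self, what: str = "theta_mean") -> dict[str, float]:
        values = getattr(self, what)
        if values is None:
            raise ValueError(f"{what} not computed")
        return dict(zip(self.alleles, map(float, values)))

    def to_frame(self):
        import pandas as pd

        data = {
            "allele": self.alleles,
            "alpha": self.alpha,
            "expected_count": self.expected_counts,
            "theta_mean": self.theta_mean,
        }
        if self.depth is not None:
            data["depth"] = self.depth
        return pd.DataFrame(data)


def _prepare(E: EvidenceMatrix) -> np.ndarray:
    if E.n_reads == 0:
        raise ValueError("empty evidence matrix")
    return E.to_dense()


def _normalize_rows(log_w: np.ndarray) -> np.ndarray:
    """exp-normalize each row of a log-weight matrix (rows with -inf allowed
    as long as one finite entry exists)."""
    shift = log_w.max(axis=1, keepdims=True)
    z = np.exp(log_w - shift)
    z /= z.sum(axis=1, keepdims=True)
    return z


def _dirichlet_kl(alpha: np.ndarray, alpha0: float) -> float:
    """KL(Dir(alpha) || Dir(alpha0 * 1))."""
    a0 = np.full_like(alpha, alpha0)
    s, s0 = alpha.sum(), a0.sum()
    return float(
        gammaln(s)
        - gammaln(s0)
        - np.sum(gammaln(alpha) - gammaln(a0))
        + np.sum((alpha - a0) * (digamma(alpha) - digamma(s)))
    )


def vb_fit(E: EvidenceMatrix, cfg: MixtureConfig | None = None) -> AbundanceEstimate:
    """Mean-field VB fit of the Dirichlet read mixture.

    Deterministic: responsibilities start uniform over each fragment's
    candidate alleles. Terminates when mean |Δalpha| < ``cfg.tol`` or at
    ``cfg.max_iter``. ``theta_mean`` is the posterior mean alpha / sum(alpha).
    """
    cfg = cfg or MixtureConfig()
    ll = _prepare(E)
    N, M = ll.shape
    z = _normalize_rows(np.where(np.isfinite(ll), 0.0, -np.inf))
    alpha = cfg.alpha0 + z.sum(axis=0)
    elbo_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        elogtheta = digamma(alpha) - digamma(alpha.sum())
        z = _normalize_rows(elogtheta[None, :] + ll)
        new_alpha = cfg.alpha0 + z.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            zlogz = np.where(z > 0, z * np.log(z), 0.0)
        elogtheta_new = digamma(new_alpha) - digamma(new_alpha.sum())
        elbo = (
            float(np.sum(z * np.where(np.isfinite(ll), ll, 0.0)))
            + float(z.sum(axis=0) @ elogtheta_new)
            - float(zlogz.sum())
            - _dirichlet_kl(new_alpha, cfg.alpha0)
        )
        elbo_trace.append(elbo)
        delta = float(np.abs(new_alpha - alpha).mean())
        alpha = new_alpha
        if delta < cfg.tol:
            converged = True
            break
    counts = alpha - cfg.alpha0
    return AbundanceEstimate(
        alleles=list(E.alleles),
        alpha=alpha,
        expected_counts=counts,
        theta_mean=alpha / alpha.sum(),
        n_iter=n_iter,
        converged=converged,
        elbo_trace=elbo_trace,
        mode="VB",
        responsibilities=z,
    )


def em_fit(E: EvidenceMatrix, cfg: MixtureConfig | None = None) -> AbundanceEstimate:
    """Maximum-likelihood EM fit; the observed-data log-likelihood is the
    recorded objective and is monotone non-decreasing."""
    cfg = cfg or MixtureConfig(mode="EM")
    ll = _prepare(E)
    N, M = ll.shape
    theta = np.full(M, 1.0 / M)
    loglik_trace: list[float] = []
    converged = False
    n_iter = 0
    z = _normalize_rows(np.where(np.isfinite(ll), 0.0, -np.inf))
    for n_iter in range(1, cfg.max_iter + 1):
        with np.errstate(divide="ignore"):
            log_w = np.log(theta)[None, :] + ll
        shift = log_w.max(axis=1, keepdims=True)
        w = np.exp(log_w - shift)
        row_sums = w.sum(axis=1, keepdims=True)
        loglik_trace.append(float(np.sum(np.log(row_sums) + shift)))
        z = w / row_sums
        new_theta = z.sum(axis=0) / N
        delta = float(np.abs(new_theta - theta).mean()) * N
        theta = new_theta
        if delta < cfg.tol:
            converged = True
            break
    counts = theta * N
    return AbundanceEstimate(
        alleles=list(E.alleles),
        alpha=cfg.alpha0 + counts,
        expected_counts=counts,
        theta_mean=theta,
        n_iter=n_iter,
        converged=converged,
        elbo_trace=loglik_trace,
        mode="EM",
        responsibilities=z,
    )


def expected_depth(
    est: AbundanceEstimate,
    E: EvidenceMatrix,
    panel: ReferencePanel,
    read_lengths: Mapping[str, int] | Sequence[int] | None = None,
) -> np.ndarray:
    """Normalized depth of coverage per allele.

    depth_j = sum_i z_ij * bases_i / L_j — expected aligned bases assigned to
    allele j divided by the allele length. For a single-allele panel this is
    total read bases over allele length. The result is also stored on
    ``est.depth``.
    """
    if est.responsibilities is None:
        raise ValueError("estimate carries no responsibilities")
    if read_lengths is None:
        bases = E.bases_per_read()
    elif isinstance(read_lengths, Mapping):
        bases = np.array([read_lengths[r] for r in E.reads], dtype=float)
    else:
        bases = np.asarray(read_lengths, dtype=float)
    if bases.shape[0] != E.n_reads:
        raise ValueError("read_lengths length mismatch")
    lengths = np.array([len(panel.by_name(a).seq) for a in est.alleles], dtype=float)
    if np.any(lengths == 0):
        raise ValueError("allele of length 0")
    depth = (est.responsibilities * bases[:, None]).sum(axis=0) / lengths
    est.depth = depth
    return depth
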