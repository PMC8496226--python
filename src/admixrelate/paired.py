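"""Paired ancestry proportions Phi from genotype likelihoods.

An admixed individual's two alleles at a site need not have independent
ancestries: alleles inherited together from a recently admixed parent are
correlated.  The K x K matrix ``phi`` captures this, with ``phi[a1, a2]``
the proportion of sites whose first allele has ancestry ``a1`` and second
allele ancestry ``a2``.  Phi is estimated per individual by an EM algorithm
over the latent ancestry pair, treating sites as independent and summing
over the unobserved genotype via the genotype likelihoods.

The independent-pairing alternative ``phi = outer(q, q)`` (alleles drawn
independently from the admixture proportions ``q``) is provided both as the
EM initialization and as a model variant in its own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import FreqPanel

__all__ = [
    "PairedAncestry",
    "site_pair_likelihood",
    "site_pair_likelihoods",
    "estimate_paired_ancestry",
    "independent_pairing",
    "paired_loglik",
    "paired_em_step",
]


@dataclass
class PairedAncestry:
    """Joint ancestry proportions of an individual's two alleles.

    ``phi`` lies on the K^2 simplex and is symmetric, since the data carry
    no information on allele order.
    """

    phi: np.ndarray  # (K, K) float64
    n_iter: int = 0
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.ndim != 2 or self.phi.shape[0] != self.phi.shape[1]:
            raise ValueError("phi must be a square K x K matrix")
        if np.any(self.phi < 0):
            raise ValueError("negative paired-ancestry proportion")
        if abs(self.phi.sum() - 1.0) > 1e-6:
            raise ValueError("phi does not sum to 1")
        if np.max(np.abs(self.phi - self.phi.T)) > 1e-9:
            raise ValueError("phi is not symmetric")

    @property
    def n_populations(self) -> int:
        return self.phi.shape[0]

    @property
    def marginal(self) -> np.ndarray:
        """Marginal ancestry proportions of the first allele slot."""
        return self.phi.sum(axis=1)


def independent_pairing(q: np.ndarray) -> PairedAncestry:
    """``phi = outer(q, q)``: the two allele ancestries drawn independently.

    This is the model without paired ancestry, appropriate when admixture
    is old enough that within-individual allele ancestries are uncorrelated.
    """
    q = np.asarray(q, dtype=np.float64)
    if q.ndim != 1:
        raise ValueError("q must be a vector")
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("q is not on the probability simplex")
    return PairedAncestry(np.outer(q, q) / q.sum() ** 2)


def site_pair_likelihoods(gl: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-site likelihood of every ordered ancestry pair.

    ``L[j, a1, a2] = sum_{g1,g2 in {0,1}} GL_j(g1+g2) p(g1|f[j,a1]) p(g2|f[j,a2])``
    with ``p(1|f) = f``.  Because the genotype likelihood depends only on
    the allele sum, ``L`` is symmetric in ``(a1, a2)``.

    Parameters
    ----------
    gl : (M, 3) unordered genotype-likelihood triples
    f : (M, K) clamped allele-1 frequencies
    """
    gl = np.asarray(gl, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if np.any(gl.max(axis=-1) <= 0):
        j = int(np.argmax(gl.max(axis=-1) <= 0))
        raise ValueError(f"all-zero genotype-likelihood triple at site {j}")
    # e[g1] = sum_{g2} GL(g1+g2) p(g2 | f_a2), per (site, a2)
    e0 = gl[:, 0:1] * (1.0 - f) + gl[:, 1:2] * f  # (M, K)
    e1 = gl[:, 1:2] * (1.0 - f) + gl[:, 2:3] * f
    return (1.0 - f)[:, :, None] * e0[:, None, :] + f[:, :, None] * e1[:, None, :]


def site_pair_likelihood(gl_site: np.ndarray, f_site: np.ndarray) -> np.ndarray:
    """Single-site K x K ancestry-pair likelihood (see :func:`site_pair_likelihoods`)."""
    return site_pair_likelihoods(
        np.asarray(gl_site, dtype=np.float64)[None, :],
        np.asarray(f_site, dtype=np.float64)[None, :],
    )[0]


def paired_loglik(phi: np.ndarray, L: np.ndarray) -> float:
    """``sum_j log sum_{a1,a2} phi[a1,a2] L[j,a1,a2]``."""
    s = np.einsum("ab,jab->j", phi, L)
    return float(np.log(s).sum())


def paired_em_step(phi: np.ndarray, L: np.ndarray) -> np.ndarray:
    """One EM update of phi: posterior-responsibility means over sites.

    Preserves symmetry and the simplex; the observed-data log-likelihood is
    non-decreasing under this map.
    """
    w = phi[None, :, :] * L
    s = w.sum(axis=(1, 2))
    if np.any(s <= 0):
        j = int(np.argmax(s <= 0))
        raise ValueError(f"zero likelihood under current phi at site {j}")
    new = (w / s[:, None, None]).mean(axis=0)
    return 0.5 * (new + new.T)  # kill float-level asymmetry drift


def estimate_paired_ancestry(
    gl_ind: np.ndarray,
    freqs: FreqPanel | np.ndarray,
    q_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
    accel: bool = True,
) -> PairedAncestry:
    """Maximum-likelihood phi for one individual by (accelerated) EM.

    Parameters
    ----------
    gl_ind : (M, 3) genotype-likelihood triples for the individual
    freqs : frequency panel (K populations x M sites)
    q_init : admixture proportions for the ``outer(q, q)`` initialization;
        uniform ``1/K`` when omitted
    tol : convergence threshold on the Euclidean distance between
        consecutive flattened phi estimates
    accel : use SQUAREM (S3) extrapolation between EM sweeps

    Hitting ``max_iter`` flags ``converged=False`` rather than raising.
    """
    gl_ind = np.asarray(gl_ind, dtype=np.float64)
    f = freqs.clamped.T if isinstance(freqs, FreqPanel) else np.asarray(freqs).T
    if gl_ind.ndim != 2 or gl_ind.shape[1] != 3:
        raise ValueError("gl_ind must be an M x 3 array")
    if gl_ind.shape[0] != f.shape[0]:
        raise ValueError("site count mismatch between GLs and frequencies")
    k = f.shape[1]
    if q_init is None:
        q_init = np.full(k, 1.0 / k)
    q_init = np.asarray(q_init, dtype=np.float64)
    if q_init.shape != (k,):
        raise ValueError("q_init has wrong length")
    if np.any(q_init < 0) or abs(q_init.sum() - 1.0) > 1e-6:
        raise ValueError("q_init is not on the probability simplex")

    if k == 1:
        return PairedAncestry(np.ones((1, 1)), n_iter=0, converged=True, loglik=0.0)

    L = site_pair_likelihoods(gl_ind, f)
    phi = np.outer(q_init, q_init)
    phi /= phi.sum()

    n_iter = 0
    converged = False
    while n_iter < max_iter:
        if accel:
            new = _squarem_phi(phi, L)
        else:
            new = paired_em_step(phi, L)
        n_iter += 1
        delta = float(np.linalg.norm(new - phi))
        phi = new
        if delta < tol:
            converged = True
            break
    return PairedAncestry(
        phi, n_iter=n_iter, converged=converged, loglik=paired_loglik(phi, L)
    )


def _squarem_phi(phi: np.ndarray, L: np.ndarray) -> np.ndarray:
    """One SQUAREM (S3) cycle on the phi EM map.

    Falls back to the plain double EM step whenever the extrapolated point
    leaves the simplex or lowers the log-likelihood, so the accelerated
    iteration is still monotone.
    """
    t1 = paired_em_step(phi, L)
    t2 = paired_em_step(t1, L)
    u = t1 - phi
    v = (t2 - t1) - u
    nv = float(np.linalg.norm(v))
    if nv == 0.0:
        return t2
    alpha = -float(np.linalg.norm(u)) / nv
    prop = phi - 2.0 * alpha * u + alpha * alpha * v
    if prop.min() < -1e-12:
        return t2
    prop = np.clip(prop, 0.0, None)
    prop /= prop.sum()
    prop = 0.5 * (prop + prop.T)
    stab = paired_em_step(prop, L)
    if paired_loglik(stab, L) < paired_loglik(t2, L):
        return t2
    return stab
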