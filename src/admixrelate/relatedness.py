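"""Maximum-likelihood IBD-sharing coefficients for a pair of admixed individuals.

The observed data are per-site genotype likelihoods for the two individuals
A and B.  The model sums, at every site, over the latent IBD state
``z = (z1, z2)`` (whether the pair's first alleles, and second alleles, are
identical by descent), over the ancestral population of each of the four
alleles ``a = (a1A, a2A, a1B, a2B)``, and over the ordered genotypes of both
individuals:

    P(X_A, X_B | R) = prod_j sum_z sum_a sum_{gA,gB}
        GL_A(gA) GL_B(gB) P(gA, gB | a, z) P(a | z) P(z | R)

with ``R = (k0, k1, k2)`` the genome fractions sharing 0, 1 or 2 alleles
IBD.  An IBD-shared allele slot is a single population-frequency draw whose
ancestry and allelic state appear in both individuals; non-shared alleles
are independent draws given their ancestry.  Ancestry priors come from each
individual's paired-ancestry matrix phi.

Because only ``P(z | R)`` depends on R, the per-site conditionals
``c[j, z] = P(X_jA, X_jB | Z_j = z)`` are computed once per pair and reused
by every EM iteration, which then costs O(M * 4).  EM is optionally
accelerated with the SQUAREM squared-extrapolation scheme (S3).

The model assumes no inbreeding and independent (LD-free) sites.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .formats import FreqPanel, RelatednessResult
from .paired import PairedAncestry

__all__ = [
    "IBD_STATES",
    "ibd_prior",
    "ancestry_prior",
    "genotype_pair_prior",
    "site_conditionals",
    "brute_force_site_likelihood",
    "em_step",
    "squarem_step",
    "relatedness_loglik",
    "estimate_relatedness",
    "kinship_from_R",
]

#: Fixed enumeration order of the four IBD states z = (z1, z2).
IBD_STATES: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (0, 1), (1, 1))

MODES = ("mean", "indA", "indB")


def _check_simplex(r: np.ndarray, name: str = "r", tol: float = 1e-9) -> np.ndarray:
    r = np.asarray(r, dtype=np.float64)
    if r.shape != (3,):
        raise ValueError(f"{name} must have 3 components")
    if r.min() < -tol or abs(r.sum() - 1.0) > tol:
        raise ValueError(f"{name} is not on the probability simplex: {r}")
    return r


def ibd_prior(r: np.ndarray) -> np.ndarray:
    """P(z | R) over :data:`IBD_STATES`: ``(k0, k1/2, k1/2, k2)``.

    k1 splits evenly over the two ordered one-allele-shared states.
    """
    k0, k1, k2 = _check_simplex(r)
    return np.array([k0, 0.5 * k1, 0.5 * k1, k2])


def _slot_weights(
    phiA: np.ndarray, phiB: np.ndarray, slot: int, mode: str
) -> np.ndarray:
    """Shared-ancestry weight s(c) for one allele slot.

    ``mode="mean"`` averages the two individuals' marginal slot ancestries;
    ``indA``/``indB`` use one individual's marginal alone.  All options
    coincide when the two phi matrices are equal.
    """
    axis = 1 - slot  # marginal of slot 0 sums over axis 1 and vice versa
    qA = phiA.sum(axis=axis)
    qB = phiB.sum(axis=axis)
    if mode == "mean":
        return 0.5 * (qA + qB)
    if mode == "indA":
        return qA.copy()
    if mode == "indB":
        return qB.copy()
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _slot_conditional(phi: np.ndarray, slot: int) -> np.ndarray:
    """P(other-slot ancestry | this-slot ancestry) from a phi matrix.

    Row ``c`` is the conditional distribution of the partner allele's
    ancestry given this slot has ancestry ``c``.  Rows with zero marginal
    mass are left at zero (the individual cannot have that slot ancestry,
    so no probability flows through them).
    """
    joint = phi if slot == 0 else phi.T
    q = joint.sum(axis=1)
    out = np.zeros_like(joint)
    np.divide(joint, q[:, None], out=out, where=q[:, None] > 0)
    return out


def ancestry_prior(
    z: tuple[int, int],
    phiA: PairedAncestry | np.ndarray,
    phiB: PairedAncestry | np.ndarray,
    mode: str = "mean",
) -> np.ndarray:
    """P(a | z) over all K^4 ancestry configurations ``(a1A, a2A, a1B, a2B)``.

    With no sharing, the two individuals' allele-pair ancestries are drawn
    from their own phi matrices independently.  A shared slot (z = 1)
    carries a single ancestry ``c`` drawn with weight ``s(c)`` (see
    :func:`_slot_weights`); each individual's other allele then follows its
    phi conditional on ``c``.  Configurations violating the sharing
    equality constraints have probability 0.
    """
    pA = phiA.phi if isinstance(phiA, PairedAncestry) else np.asarray(phiA)
    pB = phiB.phi if isinstance(phiB, PairedAncestry) else np.asarray(phiB)
    k = pA.shape[0]
    z1, z2 = z
    out = np.zeros((k, k, k, k))
    if (z1, z2) == (0, 0):
        out = np.einsum("ab,cd->abcd", pA, pB)
    elif (z1, z2) == (1, 0):
        s = _slot_weights(pA, pB, 0, mode)
        cA = _slot_conditional(pA, 0)  # [c, a2A]
        cB = _slot_conditional(pB, 0)  # [c, a2B]
        for c in range(k):
            out[c, :, c, :] = s[c] * np.outer(cA[c], cB[c])
    elif (z1, z2) == (0, 1):
        s = _slot_weights(pA, pB, 1, mode)
        cA = _slot_conditional(pA, 1)  # [c, a1A]
        cB = _slot_conditional(pB, 1)  # [c, a1B]
        for c in range(k):
            out[:, c, :, c] = s[c] * np.outer(cA[c], cB[c])
    elif (z1, z2) == (1, 1):
        s1 = _slot_weights(pA, pB, 0, mode)
        s2 = _slot_weights(pA, pB, 1, mode)
        for c1 in range(k):
            for c2 in range(k):
                out[c1, c2, c1, c2] = s1[c1] * s2[c2]
    else:
        raise ValueError(f"invalid IBD state {z!r}")
    return out


def genotype_pair_prior(
    a: tuple[int, int, int, int],
    z: tuple[int, int],
    f_site: np.ndarray,
) -> np.ndarray:
    """P(gA, gB | a, z) over the 16 ordered genotype pairs.

    Indexed ``[g1A, g2A, g1B, g2B]``.  Non-shared slots are independent
    Bernoulli(f) draws of their ancestry's allele frequency; a shared slot
    is one draw whose allelic state appears in both individuals, so pairs
    with differing states in a shared slot have probability 0.
    """
    f_site = np.asarray(f_site, dtype=np.float64)
    a1A, a2A, a1B, a2B = a
    z1, z2 = z
    if z1 and a1A != a1B:
        raise ValueError("ancestry config inconsistent with z: a1A != a1B under z1=1")
    if z2 and a2A != a2B:
        raise ValueError("ancestry config inconsistent with z: a2A != a2B under z2=1")

    def p(g: int, anc: int) -> float:
        f = f_site[anc]
        return f if g == 1 else 1.0 - f

    out = np.zeros((2, 2, 2, 2))
    for g1A, g2A, g1B, g2B in product((0, 1), repeat=4):
        if z1:
            if g1A != g1B:
                continue
            pr = p(g1A, a1A)
        else:
            pr = p(g1A, a1A) * p(g1B, a1B)
        if z2:
            if g2A != g2B:
                continue
            pr *= p(g2A, a2A)
        else:
            pr *= p(g2A, a2A) * p(g2B, a2B)
        out[g1A, g2A, g1B, g2B] = pr
    return out


def _ordered_gl(triple: np.ndarray) -> np.ndarray:
    """Ordered-genotype GL table ``[g1, g2]`` from an unordered triple.

    The likelihood of the sequencing data depends only on the allele sum,
    so both heterozygote orderings share the middle value.
    """
    t = np.asarray(triple, dtype=np.float64)
    return np.array([[t[0], t[1]], [t[1], t[2]]])


def brute_force_site_likelihood(
    glA_site: np.ndarray,
    glB_site: np.ndarray,
    f_site: np.ndarray,
    phiA: PairedAncestry | np.ndarray,
    phiB: PairedAncestry | np.ndarray,
    z: tuple[int, int],
    mode: str = "mean",
) -> float:
    """P(X_A, X_B | z) at one site by explicit enumeration (testing oracle).

    Sums over all K^4 ancestry configurations and all 16 ordered genotype
    pairs with no factorization tricks; intended for small K only.
    """
    pa = ancestry_prior(z, phiA, phiB, mode)
    k = pa.shape[0]
    gA = _ordered_gl(glA_site)
    gB = _ordered_gl(glB_site)
    z1, z2 = z
    total = 0.0
    for a in product(range(k), repeat=4):
        if (z1 and a[0] != a[2]) or (z2 and a[1] != a[3]):
            continue
        w = pa[a]
        if w == 0.0:
            continue
        gp = genotype_pair_prior(a, z, np.asarray(f_site))
        for g1A, g2A, g1B, g2B in product((0, 1), repeat=4):
            total += (
                w * gp[g1A, g2A, g1B, g2B] * gA[g1A, g2A] * gB[g1B, g2B]
            )
    return total


def site_conditionals(
    glA: np.ndarray,
    glB: np.ndarray,
    freqs: FreqPanel | np.ndarray,
    phiA: PairedAncestry | np.ndarray,
    phiB: PairedAncestry | np.ndarray,
    mode: str = "mean",
) -> np.ndarray:
    """``c[j, z] = P(X_jA, X_jB | Z_j = z)`` for all M sites and 4 IBD states.

    Vectorized factorization of the triple sum; agrees with
    :func:`brute_force_site_likelihood` to float precision.  Computed once
    per pair and reused across all EM iterations.
    """
    glA = np.asarray(glA, dtype=np.float64)
    glB = np.asarray(glB, dtype=np.float64)
    if glA.shape != glB.shape or glA.ndim != 2 or glA.shape[1] != 3:
        raise ValueError("glA and glB must both be M x 3 arrays")
    f = freqs.clamped.T if isinstance(freqs, FreqPanel) else np.asarray(freqs).T
    if f.shape[0] != glA.shape[0]:
        raise ValueError("site count mismatch between GLs and frequencies")
    pA = phiA.phi if isinstance(phiA, PairedAncestry) else np.asarray(phiA)
    pB = phiB.phi if isinstance(phiB, PairedAncestry) else np.asarray(phiB)
    if pA.shape != pB.shape or pA.shape[0] != f.shape[1]:
        raise ValueError("phi dimensions inconsistent with the frequency panel")

    one_m_f = 1.0 - f

    # Partner-summed GLs: e[g1][j, a2] = sum_{g2} GL(g1+g2) p(g2 | f[j, a2])
    eA0 = glA[:, 0:1] * one_m_f + glA[:, 1:2] * f
    eA1 = glA[:, 1:2] * one_m_f + glA[:, 2:3] * f
    eB0 = glB[:, 0:1] * one_m_f + glB[:, 1:2] * f
    eB1 = glB[:, 1:2] * one_m_f + glB[:, 2:3] * f

    # z = (0,0): the pair factorizes into two single-individual likelihoods
    hA = one_m_f[:, :, None] * eA0[:, None, :] + f[:, :, None] * eA1[:, None, :]
    hB = one_m_f[:, :, None] * eB0[:, None, :] + f[:, :, None] * eB1[:, None, :]
    c00 = np.einsum("ab,jab->j", pA, hA) * np.einsum("ab,jab->j", pB, hB)

    # z = (1,0): slot-1 ancestry c shared; each individual's second allele
    # follows its phi conditional on c.
    s1 = _slot_weights(pA, pB, 0, mode)
    cA1 = _slot_conditional(pA, 0)
    cB1 = _slot_conditional(pB, 0)
    uA0, uA1 = eA0 @ cA1.T, eA1 @ cA1.T  # (M, K): partner sum given shared c
    uB0, uB1 = eB0 @ cB1.T, eB1 @ cB1.T
    c10 = (one_m_f * uA0 * uB0 + f * uA1 * uB1) @ s1

    # z = (0,1): same with the slots swapped
    s2 = _slot_weights(pA, pB, 1, mode)
    cA2 = _slot_conditional(pA, 1)
    cB2 = _slot_conditional(pB, 1)
    vA0, vA1 = eA0 @ cA2.T, eA1 @ cA2.T
    vB0, vB1 = eB0 @ cB2.T, eB1 @ cB2.T
    c01 = (one_m_f * vA0 * vB0 + f * vA1 * vB1) @ s2

    # z = (1,1): two shared draws; only the genotype-sum products of the two
    # GL triples and the slot-weighted frequency moments remain.
    p0_1, p1_1 = one_m_f @ s1, f @ s1
    p0_2, p1_2 = one_m_f @ s2, f @ s2
    w00 = glA[:, 0] * glB[:, 0]
    w01 = glA[:, 1] * glB[:, 1]
    w11 = glA[:, 2] * glB[:, 2]
    c11 = (
        p0_1 * p0_2 * w00
        + (p0_1 * p1_2 + p1_1 * p0_2) * w01
        + p1_1 * p1_2 * w11
    )

    c = np.stack([c00, c10, c01, c11], axis=1)
    bad = c.max(axis=1) <= 0
    if np.any(bad):
        j = int(np.argmax(bad))
        raise ValueError(f"zero likelihood mass under every IBD state at site {j}")
    return c


# ---------------------------------------------------------------------------
# EM on R
# ---------------------------------------------------------------------------


def relatedness_loglik(c: np.ndarray, r: np.ndarray) -> float:
    """``sum_j log sum_z P(z|R) c[j, z]``."""
    return float(np.log(c @ ibd_prior(r)).sum())


def em_step(c: np.ndarray, r: np.ndarray) -> np.ndarray:
    """One EM update of R from precomputed site conditionals.

    E-step: posterior of z per site under the current R.  M-step: k0, k1,
    k2 are the mean posterior masses of the 0-, 1- and 2-shared states
    (the two ordered one-shared states pool into k1).
    """
    w = c * ibd_prior(r)
    tot = w.sum(axis=1)
    if np.any(tot <= 0):
        j = int(np.argmax(tot <= 0))
        raise ValueError(f"zero posterior normalizer at site {j}")
    g = (w / tot[:, None]).mean(axis=0)
    return np.array([g[0], g[1] + g[2], g[3]])


def squarem_step(c: np.ndarray, r: np.ndarray) -> np.ndarray:
    """One SQUAREM (S3) cycle on the R EM map.

    Two EM steps give the secant vectors u and v; the squared-extrapolation
    proposal ``r - 2*alpha*u + alpha^2*v`` with ``alpha = -|u|/|v|`` is
    stabilized by one further EM step.  If the proposal leaves the simplex
    or the stabilized point lowers the log-likelihood, the plain double EM
    step is returned instead, so the iteration never loses likelihood.
    """
    r = _check_simplex(r)
    t1 = em_step(c, r)
    t2 = em_step(c, t1)
    u = t1 - r
    v = (t2 - t1) - u
    nv = float(np.linalg.norm(v))
    if nv == 0.0:
        return t2
    alpha = -float(np.linalg.norm(u)) / nv
    prop = r - 2.0 * alpha * u + alpha * alpha * v
    if prop.min() < -1e-12:
        return t2
    prop = np.clip(prop, 0.0, None)
    prop /= prop.sum()
    stab = em_step(c, prop)
    if relatedness_loglik(c, stab) < relatedness_loglik(c, t2):
        return t2
    return stab


def estimate_relatedness(
    glA: np.ndarray,
    glB: np.ndarray,
    freqs: FreqPanel | np.ndarray,
    phiA: PairedAncestry | np.ndarray,
    phiB: PairedAncestry | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 5000,
    accel: bool = True,
    mode: str = "mean",
    r_init: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    id_a: str = "A",
    id_b: str = "B",
) -> RelatednessResult:
    """Maximum-likelihood ``R = (k0, k1, k2)`` for one pair of individuals.

    Precomputes the per-site IBD-state conditionals once, then iterates
    (SQUAREM-accelerated) EM until the Euclidean distance between
    consecutive R estimates drops below ``tol`` or ``max_iter`` is hit
    (flagged, not raised).  Estimates may legitimately sit on the simplex
    boundary (parent-offspring pairs have k0 = k2 = 0).
    """
    glA = np.asarray(glA, dtype=np.float64)
    if glA.shape[0] == 0:
        raise ValueError("no sites to analyse (M = 0)")
    c = site_conditionals(glA, glB, freqs, phiA, phiB, mode=mode)
    r = _check_simplex(np.asarray(r_init, dtype=np.float64), "r_init")

    n_iter = 0
    converged = False
    while n_iter < max_iter:
        new = squarem_step(c, r) if accel else em_step(c, r)
        n_iter += 1
        delta = float(np.linalg.norm(new - r))
        r = new
        if delta < tol:
            converged = True
            break

    k0, k1, k2 = (float(x) for x in r)
    return RelatednessResult(
        id_a=id_a,
        id_b=id_b,
        k0=k0,
        k1=k1,
        k2=k2,
        kinship=kinship_from_R(r),
        loglik=relatedness_loglik(c, r),
        n_iter=n_iter,
        converged=converged,
        n_sites_used=int(glA.shape[0]),
    )


def kinship_from_R(r: np.ndarray) -> float:
    """Kinship coefficient ``phi = k1/4 + k2/2``.

    The probability that one allele drawn from each individual at random is
    IBD: a single shared allele is picked with probability 1/4, either of
    two shared pairs with probability 1/2.
    """
    r = _check_simplex(r)
    return float(r[1] / 4.0 + r[2] / 2.0)
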