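"""Synthetic data generator: admixed pedigrees, low-depth reads, GLs.

The generator reproduces a standard validation design for admixture-aware
relatedness estimation:

1. Ancestral allele frequencies for K populations are drawn from a
   Balding-Nichols model around a shared ancestral frequency, so the
   populations are differentiated at a chosen Fst (default 0.15, roughly
   continental-scale, standing in for a European/West-African panel pair).
2. Founder individuals receive admixture proportions from a coarse grid
   (default {0, 0.25, 0.5, 0.75, 1}); at every site each of their two
   alleles independently draws an ancestry from those proportions and then
   an allelic state from that population's frequency.
3. Related pairs descend from founders through explicit pedigrees
   (unrelated, parent-offspring, full/half siblings, first/second cousins):
   an offspring samples one allele from each parent at each site
   independently (sites are unlinked -- no recombination map, no LD).
   Founder alleles carry unique integer tags, so the realized IBD count per
   site is read off as the number of tag matches between the pair.
4. Sequencing reads per site are Poisson-distributed around the target
   depth; each read picks one of the two alleles uniformly and is flipped
   to the other allele with error probability eps (two-allele error model).
5. Genotype likelihoods follow the standard read-product formula:
   GL(g1, g2) = prod_i (P(b_i|g1) + P(b_i|g2)) / 2 with P(b|g) = 1 - eps
   on a match and eps otherwise.

Everything is driven by a single :class:`numpy.random.Generator`, so a seed
reproduces the experiment byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .formats import FreqPanel, GLDataset, atomic_write, write_matrix

__all__ = [
    "RELATIONSHIPS",
    "SimulatedPair",
    "ReadCounts",
    "SimConfig",
    "gen_ancestral_freqs",
    "sim_admixed_individual",
    "sim_relative_pair",
    "sim_reads",
    "genotype_likelihoods",
    "simulate_dataset",
    "simulate_experiment",
]

#: Pedigree expectations of R = (k0, k1, k2) and founder counts.
RELATIONSHIPS: dict[str, tuple[tuple[float, float, float], int]] = {
    "unrelated": ((1.0, 0.0, 0.0), 2),
    "parent_offspring": ((0.0, 1.0, 0.0), 2),
    "full_sib": ((0.25, 0.5, 0.25), 2),
    "half_sib": ((0.5, 0.5, 0.0), 3),
    "first_cousin": ((0.75, 0.25, 0.0), 4),
    "second_cousin": ((0.9375, 0.0625, 0.0), 6),
}


@dataclass
class ReadCounts:
    """Per-site counts of reads supporting allele 0 and allele 1."""

    n0: np.ndarray
    n1: np.ndarray

    def __post_init__(self) -> None:
        self.n0 = np.asarray(self.n0)
        self.n1 = np.asarray(self.n1)
        if self.n0.shape != self.n1.shape:
            raise ValueError("n0 and n1 must have the same shape")
        if np.any(self.n0 < 0) or np.any(self.n1 < 0):
            raise ValueError("negative read count")

    @property
    def depth(self) -> np.ndarray:
        return self.n0 + self.n1


@dataclass
class _Member:
    """One pedigree member: per-site alleles with ancestry and descent tags."""

    geno: np.ndarray  # (M, 2) allele states in {0, 1}
    anc: np.ndarray  # (M, 2) ancestry labels in {0..K-1}
    tag: np.ndarray  # (M, 2) founder-allele tags (unique per founder allele)
    q: np.ndarray  # expected admixture proportions (K,)


@dataclass
class SimulatedPair:
    """A simulated pair with realized IBD tracking.

    ``realized_r`` is the empirical fraction of sites sharing 0/1/2 founder
    alleles and is the actual estimand for this pair; ``true_r`` is the
    pedigree expectation it fluctuates around.
    """

    genotypes_a: np.ndarray  # (M, 2)
    genotypes_b: np.ndarray
    ancestry_a: np.ndarray  # (M, 2)
    ancestry_b: np.ndarray
    ibd: np.ndarray  # (M,) realized IBD-allele count in {0, 1, 2}
    true_r: np.ndarray
    realized_r: np.ndarray
    qa: np.ndarray
    qb: np.ndarray
    relationship: str = ""


@dataclass
class SimConfig:
    """Full experiment configuration (defaults reproduce the standard design:
    10 pairs for each of 6 relationship types, 100,000 unlinked diallelic
    sites, 4x mean depth, 0.5% base error, two Fst=0.15 populations)."""

    relationships: tuple[str, ...] = tuple(RELATIONSHIPS)
    n_pairs_per_relationship: int = 10
    m_sites: int = 100_000
    mean_depth: float = 4.0
    eps: float = 0.005
    fst: float = 0.15
    k: int = 2
    admixture_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    seed: int = 0

    def validate(self) -> None:
        for rel in self.relationships:
            if rel not in RELATIONSHIPS:
                raise ValueError(
                    f"unknown relationship {rel!r}; valid: {sorted(RELATIONSHIPS)}"
                )
        if self.n_pairs_per_relationship < 1 or self.m_sites < 1:
            raise ValueError("n_pairs_per_relationship and m_sites must be >= 1")
        if not 0 <= self.eps < 0.5:
            raise ValueError("eps must be in [0, 0.5)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_ancestral_freqs(m: int, k: int, fst: float, seed=None) -> FreqPanel:
    """Balding-Nichols frequency panel: K populations x M sites.

    A shared ancestral frequency p ~ Uniform(0.05, 0.95) per site; each
    population then draws ``f ~ Beta(p (1-fst)/fst, (1-p)(1-fst)/fst)``,
    giving E[f] = p and Var[f] = fst p (1-p).  ``fst = 0`` returns the
    ancestral frequency in every population.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    rng = _as_rng(seed)
    p = rng.uniform(0.05, 0.95, size=m)
    if fst == 0.0:
        f = np.tile(p, (k, 1))
    else:
        ratio = (1.0 - fst) / fst
        f = rng.beta(p * ratio, (1.0 - p) * ratio, size=(k, m))
    return FreqPanel(f)


def _sample_ancestries(q: np.ndarray, size, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(q)
    cum[-1] = 1.0  # guard float round-off at the top bin
    return np.searchsorted(cum, rng.random(size), side="right").astype(np.int64)


def sim_admixed_individual(
    q: np.ndarray, freqs: FreqPanel, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes and ancestry labels of one admixed founder.

    At each site, each of the two alleles independently draws an ancestry
    from ``q`` and then an allelic state Bernoulli(f) from that
    population's frequency.  Returns ``(genotypes, ancestries)``, both
    (M, 2).
    """
    member = _sim_founder(np.asarray(q, float), freqs, _as_rng(seed), tag_base=0)
    return member.geno, member.anc


def _sim_founder(
    q: np.ndarray, freqs: FreqPanel, rng: np.random.Generator, tag_base: int
) -> _Member:
    if np.any(q < 0) or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("q is not on the probability simplex")
    m = freqs.n_sites
    anc = _sample_ancestries(q / q.sum(), (m, 2), rng)
    f = freqs.freqs  # raw frequencies define the generating process
    site = np.arange(m)
    geno = np.empty((m, 2), dtype=np.int8)
    for slot in (0, 1):
        geno[:, slot] = rng.random(m) < f[anc[:, slot], site]
    tag = np.empty((m, 2), dtype=np.int64)
    tag[:, 0] = tag_base
    tag[:, 1] = tag_base + 1
    return _Member(geno=geno, anc=anc, tag=tag, q=q)


def _mate(p1: _Member, p2: _Member, rng: np.random.Generator) -> _Member:
    """Offspring: one uniformly chosen allele from each parent per site."""
    m = p1.geno.shape[0]
    site = np.arange(m)
    child = _Member(
        geno=np.empty((m, 2), dtype=np.int8),
        anc=np.empty((m, 2), dtype=np.int64),
        tag=np.empty((m, 2), dtype=np.int64),
        q=0.5 * (p1.q + p2.q),
    )
    for slot, parent in enumerate((p1, p2)):
        pick = rng.integers(0, 2, size=m)
        child.geno[:, slot] = parent.geno[site, pick]
        child.anc[:, slot] = parent.anc[site, pick]
        child.tag[:, slot] = parent.tag[site, pick]
    return child


def _build_pedigree(
    relationship: str, founders: list[_Member], rng: np.random.Generator
) -> tuple[_Member, _Member]:
    f = founders
    if relationship == "unrelated":
        return f[0], f[1]
    if relationship == "parent_offspring":
        return f[0], _mate(f[0], f[1], rng)
    if relationship == "full_sib":
        return _mate(f[0], f[1], rng), _mate(f[0], f[1], rng)
    if relationship == "half_sib":
        return _mate(f[0], f[1], rng), _mate(f[1], f[2], rng)
    if relationship == "first_cousin":
        s1 = _mate(f[0], f[1], rng)
        s2 = _mate(f[0], f[1], rng)
        return _mate(s1, f[2], rng), _mate(s2, f[3], rng)
    if relationship == "second_cousin":
        s1 = _mate(f[0], f[1], rng)
        s2 = _mate(f[0], f[1], rng)
        c1 = _mate(s1, f[2], rng)
        c2 = _mate(s2, f[3], rng)
        return _mate(c1, f[4], rng), _mate(c2, f[5], rng)
    raise ValueError(
        f"unknown relationship {relationship!r}; valid: {sorted(RELATIONSHIPS)}"
    )


def sim_relative_pair(
    relationship: str,
    founder_qs: list[np.ndarray],
    freqs: FreqPanel,
    seed=None,
) -> SimulatedPair:
    """Simulate a pair with the given pedigree relationship.

    ``founder_qs`` supplies one admixture vector per required founder
    (2 for unrelated/parent-offspring/full siblings, 3 for half siblings,
    4 for first cousins, 6 for second cousins).  Founder alleles carry
    unique tags; the per-site IBD count is the number of tag matches
    between the pair, from which ``realized_r`` is computed.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(
            f"unknown relationship {relationship!r}; valid: {sorted(RELATIONSHIPS)}"
        )
    true_r, n_founders = RELATIONSHIPS[relationship]
    if len(founder_qs) < n_founders:
        raise ValueError(
            f"{relationship} needs {n_founders} founders, got {len(founder_qs)}"
        )
    rng = _as_rng(seed)
    founders = [
        _sim_founder(np.asarray(q, float), freqs, rng, tag_base=2 * i)
        for i, q in enumerate(founder_qs[:n_founders])
    ]
    a, b = _build_pedigree(relationship, founders, rng)

    # Each member's two tags are always distinct (no inbreeding in these
    # pedigrees), so the multiset intersection is a plain match count.
    ibd = np.zeros(freqs.n_sites, dtype=np.int8)
    for i in (0, 1):
        for j in (0, 1):
            ibd += a.tag[:, i] == b.tag[:, j]
    realized = np.array([(ibd == c).mean() for c in (0, 1, 2)])

    return SimulatedPair(
        genotypes_a=a.geno,
        genotypes_b=b.geno,
        ancestry_a=a.anc,
        ancestry_b=b.anc,
        ibd=ibd,
        true_r=np.asarray(true_r),
        realized_r=realized,
        qa=a.q,
        qb=b.q,
        relationship=relationship,
    )


def sim_reads(
    genotypes: np.ndarray, mean_depth: float, eps: float, seed=None
) -> ReadCounts:
    """Poisson-depth reads with symmetric two-allele base error.

    Depth d ~ Poisson(mean_depth) per site; each read copies a uniformly
    chosen allele of the genotype and is flipped with probability eps.
    The allele-1 read count is therefore Binomial(d, p) with p = eps, 1/2,
    1 - eps for genotypes 0/0, 0/1, 1/1, which is how it is drawn here.
    """
    genotypes = np.atleast_2d(np.asarray(genotypes))
    if genotypes.shape[1] != 2:
        raise ValueError("genotypes must be (M, 2) allele states")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    rng = _as_rng(seed)
    m = genotypes.shape[0]
    depth = rng.poisson(mean_depth, size=m)
    p1 = np.array([eps, 0.5, 1.0 - eps])[genotypes.sum(axis=1)]
    n1 = rng.binomial(depth, p1)
    return ReadCounts(n0=depth - n1, n1=n1)


def genotype_likelihoods(reads: ReadCounts, eps: float) -> np.ndarray:
    """(M, 3) GL triples for the unordered genotypes (00, 01, 11).

    ``GL(hom0) = (1-eps)^n0 eps^n1``, ``GL(het) = 0.5^(n0+n1)``,
    ``GL(hom1) = eps^n0 (1-eps)^n1`` -- the read-product formula with each
    read drawn from one of the two alleles uniformly.  Zero depth yields
    the uninformative triple (1, 1, 1).
    """
    if not 0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    n0 = np.asarray(reads.n0, dtype=np.float64)
    n1 = np.asarray(reads.n1, dtype=np.float64)
    gl = np.empty(n0.shape + (3,), dtype=np.float64)
    gl[..., 0] = (1.0 - eps) ** n0 * eps**n1
    gl[..., 1] = 0.5 ** (n0 + n1)
    gl[..., 2] = eps**n0 * (1.0 - eps) ** n1
    return gl


# ---------------------------------------------------------------------------
# Whole-experiment assembly
# ---------------------------------------------------------------------------


@dataclass
class PairRecord:
    """Bookkeeping for one simulated pair inside a dataset."""

    index_a: int
    index_b: int
    pair: SimulatedPair


def _draw_founder_q(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.k == 2:
        w = rng.choice(np.asarray(cfg.admixture_grid, dtype=np.float64))
        return np.array([w, 1.0 - w])
    # the grid is defined for two-way admixture; otherwise draw a flat
    # Dirichlet so founders span the simplex
    return rng.dirichlet(np.ones(cfg.k))


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[GLDataset, FreqPanel, list[PairRecord]]:
    """Simulate the full experiment in memory.

    Returns the Beagle-style GL dataset over all simulated individuals
    (pair members only, founders are discarded), the true frequency panel,
    and per-pair truth records.
    """
    cfg.validate()
    rng = _as_rng(cfg.seed)
    freqs = gen_ancestral_freqs(cfg.m_sites, cfg.k, cfg.fst, rng)

    records: list[PairRecord] = []
    gl_cols: list[np.ndarray] = []
    sample_ids: list[str] = []
    for rel in cfg.relationships:
        _, n_founders = RELATIONSHIPS[rel]
        for p in range(cfg.n_pairs_per_relationship):
            founder_qs = [_draw_founder_q(cfg, rng) for _ in range(n_founders)]
            pair = sim_relative_pair(rel, founder_qs, freqs, rng)
            idx = []
            for geno in (pair.genotypes_a, pair.genotypes_b):
                reads = sim_reads(geno, cfg.mean_depth, cfg.eps, rng)
                gl_cols.append(genotype_likelihoods(reads, cfg.eps))
                idx.append(len(gl_cols) - 1)
                sample_ids.append(f"{rel}_p{p}_{'ab'[len(idx) - 1]}")
            records.append(PairRecord(index_a=idx[0], index_b=idx[1], pair=pair))

    gl = np.stack(gl_cols, axis=1)  # (M, N, 3)
    markers = [f"site_{j}" for j in range(cfg.m_sites)]
    data = GLDataset(
        markers=markers,
        allele_a=["0"] * cfg.m_sites,
        allele_b=["1"] * cfg.m_sites,
        gl=gl,
        sample_ids=sample_ids,
    )
    return data, freqs, records


def simulate_experiment(cfg: SimConfig, out_prefix: str) -> dict[str, str]:
    """Run :func:`simulate_dataset` and write the three output files.

    ``<prefix>.beagle.gz`` (GLs), ``<prefix>.freq`` (true frequencies,
    sites x populations) and ``<prefix>.truth.tsv`` (per pair: ids,
    relationship, expected and realized R, founder-derived admixture
    proportions).  Byte-identical for a fixed seed.
    """
    from .formats import write_beagle

    data, freqs, records = simulate_dataset(cfg)
    paths = {
        "beagle": f"{out_prefix}.beagle.gz",
        "freq": f"{out_prefix}.freq",
        "truth": f"{out_prefix}.truth.tsv",
    }
    d = os.path.dirname(out_prefix)
    if d:
        os.makedirs(d, exist_ok=True)
    write_beagle(data, paths["beagle"])
    write_matrix(freqs.freqs.T, paths["freq"])
    with atomic_write(paths["truth"]) as fh:
        fh.write(
            "ida\tidb\trelationship\tk0_true\tk1_true\tk2_true\t"
            "k0_real\tk1_real\tk2_real\tqa\tqb\n"
        )
        for rec in records:
            p = rec.pair
            fh.write(
                f"{data.sample_ids[rec.index_a]}\t{data.sample_ids[rec.index_b]}\t"
                f"{p.relationship}\t"
                + "\t".join(f"{v:.6f}" for v in p.true_r)
                + "\t"
                + "\t".join(f"{v:.6f}" for v in p.realized_r)
                + "\t"
                + ",".join(f"{v:.4f}" for v in p.qa)
                + "\t"
                + ",".join(f"{v:.4f}" for v in p.qb)
                + "\n"
            )
    return paths
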