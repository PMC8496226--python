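# Methods

## Model

For a pair of individuals A and B with ancestry from `K` populations,
observed at `M` diallelic sites through sequencing reads `X_A`, `X_B`, the
likelihood of the IBD-sharing coefficients `R = (k0, k1, k2)` is

```
P(X_A, X_B | R) = ∏_{j=1}^{M} Σ_{z ∈ {0,1}²} Σ_{a ∈ {1..K}⁴} Σ_{g_A, g_B ∈ {0,1}²}
    P(X_jA | G_jA = g_A) P(X_jB | G_jB = g_B)
    P(g_A, g_B | a, z) P(a | z) P(z | R)
```

with latent variables per site:

* `z = (z1, z2)` — whether the pair's first alleles, and second alleles,
  are IBD.  Enumeration order `(0,0), (1,0), (0,1), (1,1)`; prior
  `P(z | R) = (k0, k1/2, k1/2, k2)` (the single-shared state is split
  evenly over its two orderings).
* `a = (a1A, a2A, a1B, a2B)` — the ancestral population of each of the
  four alleles.
* `g_A = (g1A, g2A)`, `g_B` — ordered genotypes.  Ordering is purely
  formal: the genotype likelihood of sequencing data depends only on the
  allele sum, so both heterozygote orderings carry the unordered
  heterozygote GL, and no phasing is required.

Genotype prior `P(g_A, g_B | a, z)`: every non-shared allele slot is an
independent Bernoulli(`f`) draw from its ancestry's allele frequency; an
IBD-shared slot is a *single* draw whose ancestry and allelic state appear
in both individuals, so configurations with differing states (or
ancestries) in a shared slot have probability zero.

Ancestry prior `P(a | z)`: under `z = (0,0)` each individual's allele-pair
ancestry is drawn from its own paired-ancestry matrix,
`P(a) = Φ_A[a1A, a2A] · Φ_B[a1B, a2B]`.  For a shared slot with ancestry
`c`, the draw has weight `s(c)` and each individual's *other* allele
follows its Φ conditional on `c`; with both slots shared,
`P(c1, c2) = s1(c1) · s2(c2)` from the per-slot weights alone.

Assumptions inherited from the model class: no inbreeding, no linkage
disequilibrium (independent sites), known ancestral allele frequencies
`F` and known (or separately estimated) paired ancestries.  On unpruned
data the product over sites is a composite likelihood; the point estimate
is unaffected but the likelihood values lose their literal interpretation.

### The shared-ancestry weight s(c)

The construction of `P(a | z)` for shared slots is the one genuinely open
design point in this model family.  We use the symmetric average of the
two individuals' marginal slot ancestries,

```
s(c) = (q_A(c) + q_B(c)) / 2,      q_X(c) = Σ_l Φ_X[c, l]
```

exposed as `mode="mean"`, with `indA` / `indB` selecting one individual's
marginal alone.  The average is exact whenever the pair shares admixture
proportions — there all three options coincide, which the tests use to
fence the choice — and symmetric in the pair, so estimates cannot depend
on input order.  When an individual has zero marginal mass on some
ancestry, sharing through that ancestry is impossible and those
configurations correctly contribute nothing (in the estimation pipeline Φ
is estimated from data and is interior, so this arises only with
hand-constructed vertex inputs).

## Paired ancestry Φ

`Φ[a1, a2]` is the proportion of an individual's genome whose two alleles
have ancestries `(a1, a2)`.  Recent admixture makes the two allele
ancestries positively dependent (a first-generation CEU×YRI offspring has
Φ concentrated on the off-diagonal, not Φ = qqᵀ), and modelling this
dependence is what reduces estimator variance for closely related admixed
pairs.  Φ is estimated per individual by EM over the latent ancestry pair:

* site likelihood `L_j(a1, a2) = Σ_{g1,g2} GL_j(g1+g2) p(g1|f_{a1}) p(g2|f_{a2})`,
* E-step responsibilities `γ_j ∝ Φ[a1,a2] L_j(a1,a2)`, M-step Φ′ = mean_j γ_j,
* initialised at Φ0 = qqᵀ from the admixture input, or uniform `1/K²`
  when none is supplied.

Symmetry is preserved structurally (L is symmetric, updates of symmetric
starts stay symmetric; a final 0.5(Φ+Φᵀ) guards float drift).  Sites with
constant L (e.g. missing data) contribute nothing to the update and are
retained.

## Estimation of R

Only `P(z | R)` depends on `R`, so the four per-site conditionals
`c[j, z] = P(X_jA, X_jB | Z_j = z)` are precomputed once per pair.  The
triple sum factorizes: partner-summed GL vectors collapse the genotype
sums, and the ancestry sums reduce to Φ-contractions (no-sharing), slot
conditionals (one shared), or frequency moments under the slot weights
(both shared).  This makes the precompute O(M·K²) and each EM iteration
O(4M); an explicit-enumeration oracle (`brute_force_site_likelihood`,
O(K⁴·16) per site) verifies the factorization to 1e-12 on randomized
instances.

EM on `R`: `γ_j(z) ∝ P(z|R) c[j,z]`; `k0, k1, k2` update to the mean
posterior masses of the 0/1/2-shared states.  Acceleration uses the
SQUAREM squared-extrapolation scheme (S3): from two EM steps form
`u = θ1 − θ0`, `v = θ2 − θ1 − u`, step length `α = −‖u‖/‖v‖`, proposal
`θ0 − 2αu + α²v` stabilized by one further EM step; if the proposal
leaves the simplex (tolerance 1e-12 before clamping) or the stabilized
point lowers the log-likelihood, the plain double step is used, so the
accelerated iteration remains monotone and always returns a valid simplex
point.  The same scheme accelerates the Φ EM.

Numerical choices:

* **Convergence**: Euclidean distance between consecutive parameter
  vectors < `tol` (default 1e-6), for both Φ and R; hitting `max_iter`
  (default 5000) flags `converged=False` rather than raising.  Note the
  step size understates the remaining distance to the optimum for slowly
  contracting plain EM; comparisons between accelerated and plain runs
  should drive both to a tighter `tol`.
* **Initialisation**: R starts at (1/3, 1/3, 1/3), deterministic, no
  restarts — the likelihood is a mixture-weight problem in R and interior
  starts are well behaved; boundary starts would stall (EM cannot leave a
  zero weight).
* **Boundaries**: estimates may sit on the simplex boundary
  (parent–offspring pairs have k0 = k2 = 0); no interior forcing and no
  triangle constraint `k1² ≥ 4 k0 k2` is imposed.
* **Frequency clamp**: working frequencies are clipped to
  [1e-5, 1−1e-5].  The model multiplies `f` and `1−f`; exactly fixed
  sites would assign zero likelihood to heterozygote evidence that
  sequencing error can legitimately produce.  Raw values are preserved
  for output.
* **Scale invariance**: GL triples are used exactly as read; all
  estimates are invariant to positive per-triple rescaling (asserted
  end-to-end in the tests), so no renormalization is applied on input.
* **Degenerate inputs**: an all-zero GL triple, a site with zero
  likelihood mass under every z, M = 0, or misaligned site counts raise
  errors naming the offending site/file; sites missing in both
  individuals are retained and contribute a flat factor.

Kinship is reported as φ = k1/4 + k2/2 — the probability that one allele
drawn at random from each individual is IBD.  (Some texts quote the
full-sibling value 0.5, which is the relatedness coefficient
r = k1/2 + k2, not φ = 0.25; this package reports φ.)

## Simulator

The generator emulates the standard validation design for this estimator
class; its defaults are the study conditions and are not tuned:

| parameter | default | meaning |
|---|---|---|
| `m_sites` | 100,000 | unlinked diallelic sites |
| `k` | 2 | ancestral populations |
| `fst` | 0.15 | Balding–Nichols differentiation (continental scale) |
| `admixture_grid` | {0, 0.25, 0.5, 0.75, 1} | founder admixture proportions |
| `mean_depth` | 4.0 | Poisson mean sequencing depth |
| `eps` | 0.005 | per-base error probability |
| `n_pairs_per_relationship` | 10 | pairs per relationship type |

Ancestral frequencies: per site an ancestral `p ~ U(0.05, 0.95)`, then per
population `f ~ Beta(p(1−fst)/fst, (1−p)(1−fst)/fst)` — mean `p`,
variance `fst·p(1−p)`.  The synthetic panel replaces real
continental reference frequencies so the package is self-contained.

Pedigrees: founders draw each allele's ancestry from their `q` and its
state from that population's frequency; offspring take one uniformly
chosen allele per parent per site.  Six relationship types are built from
2–6 founders; the second-cousin expectation (0.9375, 0.0625, 0) follows
from the standard four-generation pedigree.  Founder alleles carry unique
integer tags, so per-site IBD counts are exact tag-match counts (the
pedigrees contain no inbreeding, so each individual's two tags are always
distinct and the match count equals the multiset intersection).
`realized_r` — the empirical fraction of sites with 0/1/2 matches — is
recorded alongside the pedigree expectation because it, not the
expectation, is the estimand for a given pair.

Reads: depth `d ~ Poisson(mean_depth)`; each read copies a uniformly
chosen allele and flips with probability `eps`.  The allele-1 read count
is therefore exactly Binomial(`d`, `p`) with `p = eps, 1/2, 1−eps` by
genotype, and is sampled as such.  GLs use the two-allele read-product
formula, so `GL = ((1−ε)^{n0} ε^{n1}, 0.5^{n0+n1}, ε^{n0} (1−ε)^{n1})`.

What the simulator does *not* emulate — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium and recombination
(sites are iid, so realized-IBD variance is far smaller than on real
chromosomes, and there are no IBD segments), frequency- and
admixture-estimation error (validation supplies the true `F`; real
pipelines estimate `F` and `Q` with NGSadmix-style tools, whose error adds
bias when panels are small or differentiation is low), quality-score
variation, mapping artefacts, and 4-base error structure (errors can only
flip between the two segregating alleles).

## Validation design

The acceptance run (`scripts/acceptance.py`, mirrored by the end-to-end
test) simulates 10 pairs per relationship at the default conditions above,
estimates Φ per individual from uniform initialisation and then R per
pair, and reports the mean coefficient per relationship type.  Problem
sizes (100,000 sites, 10 pairs, 60 pairs total) are the simulator
defaults; the run takes about a minute on one CPU.  Supporting checks:
factorized-vs-enumerated likelihood equality on 1000 randomized instances,
per-iteration EM monotonicity, SQUAREM/plain-EM agreement at the optimum,
prior normalizations, closed-form collapses at K = 1 and for
certainty-encoded GLs, and byte-level determinism of the CLI under seed
and thread-count changes.

## Known limitations

* The `s(c)` construction above is a modelling choice among several
  defensible ones; all of them agree when the pair shares admixture
  proportions, and the default is the symmetric average.  Do not compare
  likelihood *values* across modes.
* Accuracy degrades when Φ or `F` are themselves poorly estimated (few
  reference individuals, weak differentiation, very low depth); below ~1x
  little pairwise information remains at typical panel sizes.
* No inbreeding: the four-state z model cannot represent the condensed
  identity states of inbred pairs.
* Composite-likelihood caveat on unpruned (LD-correlated) data: point
  estimates stand, standard errors and likelihood-ratio tests do not.
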