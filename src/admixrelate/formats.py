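"""On-disk formats for genotype-likelihood relatedness analysis.

Three input formats are supported:

* **Beagle genotype-likelihood files** (gzip or plain text): a header row
  ``marker allele1 allele2 Ind0 Ind0 Ind0 ...`` followed by one row per
  diallelic site with three likelihood columns per individual, one for each
  unordered genotype (aa, ab, bb).
* **Frequency matrices** (NGSadmix ``.fopt`` style): whitespace-delimited,
  one row per site, one column per ancestral population.  Entries are the
  frequencies of the allele coded internally as ``1`` (the Beagle
  ``allele2`` column).
* **Admixture matrices** (NGSadmix ``.qopt`` style): one row per individual,
  one column per population; rows must lie on the probability simplex.

plus a tab-separated results table for pairwise relatedness estimates.

Allele coding convention: the Beagle ``allele1`` column maps to internal
allele 0 and ``allele2`` to internal allele 1; frequency panels hold the
frequency of allele 1.  This matches the NGSadmix convention the inputs are
produced with.
"""

from __future__ import annotations

import gzip
import os
import tempfile
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "FormatError",
    "GLDataset",
    "FreqPanel",
    "AdmixturePanel",
    "RelatednessResult",
    "read_beagle",
    "write_beagle",
    "read_matrix",
    "write_matrix",
    "read_relatedness_table",
    "write_relatedness_table",
]

#: Working-copy clamp for allele frequencies.  The model multiplies f and
#: 1-f; exactly fixed sites would zero out genuine heterozygote evidence
#: that sequencing error can produce, so the working copy is kept strictly
#: inside (0, 1).  Raw values are preserved for output.
FREQ_CLAMP = 1e-5


class FormatError(ValueError):
    """Malformed input file (wrong column counts, non-numeric tokens, ...)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class GLDataset:
    """Genotype likelihoods for M sites x N individuals.

    ``gl[j, i]`` holds the three nonnegative likelihoods of the unordered
    genotypes (aa, ab, bb) of individual ``i`` at site ``j``.  Likelihoods
    are kept exactly as read -- per-triple positive scale factors are
    irrelevant to every downstream computation and are not normalized away.
    """

    markers: list[str]
    allele_a: list[str]
    allele_b: list[str]
    gl: np.ndarray  # (M, N, 3) float64
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.gl = np.asarray(self.gl, dtype=np.float64)
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError(f"gl must have shape (M, N, 3), got {self.gl.shape}")
        m, n, _ = self.gl.shape
        if not (len(self.markers) == len(self.allele_a) == len(self.allele_b) == m):
            raise ValueError("marker/allele metadata length does not match gl")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match gl")
        if np.any(self.gl < 0):
            raise ValueError("negative genotype likelihood")
        if m and n and np.any(self.gl.max(axis=2) <= 0):
            j, i = np.argwhere(self.gl.max(axis=2) <= 0)[0]
            raise ValueError(
                f"all three genotype likelihoods are zero for sample "
                f"{self.sample_ids[i]!r} at site {self.markers[j]!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_samples(self) -> int:
        return self.gl.shape[1]

    def sample_gl(self, i: int) -> np.ndarray:
        """(M, 3) view of individual ``i``'s likelihoods."""
        return self.gl[:, i, :]


@dataclass
class FreqPanel:
    """Ancestral allele-1 frequencies, K populations x M sites."""

    freqs: np.ndarray  # (K, M) float64, raw values in [0, 1]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.ndim != 2:
            raise ValueError("freqs must be a K x M matrix")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ValueError("allele frequency outside [0, 1]")

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]

    @property
    def clamped(self) -> np.ndarray:
        """Working copy strictly inside (0, 1); see :data:`FREQ_CLAMP`."""
        return np.clip(self.freqs, FREQ_CLAMP, 1.0 - FREQ_CLAMP)


@dataclass
class AdmixturePanel:
    """Admixture proportions, N individuals x K populations (rows on simplex)."""

    q: np.ndarray  # (N, K) float64

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=np.float64)
        if self.q.ndim != 2:
            raise ValueError("q must be an N x K matrix")
        if np.any(self.q < 0):
            raise ValueError("negative admixture proportion")
        sums = self.q.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("admixture row does not sum to 1")

    @property
    def n_individuals(self) -> int:
        return self.q.shape[0]

    @property
    def n_populations(self) -> int:
        return self.q.shape[1]


@dataclass
class RelatednessResult:
    """Estimated IBD-sharing coefficients for one pair of individuals.

    ``(k0, k1, k2)`` are the genome fractions where the pair shares 0, 1 or
    2 alleles identical by descent; ``kinship`` is k1/4 + k2/2.
    """

    id_a: str
    id_b: str
    k0: float
    k1: float
    k2: float
    kinship: float
    loglik: float
    n_iter: int
    converged: bool
    n_sites_used: int

    def __post_init__(self) -> None:
        k = (self.k0, self.k1, self.k2)
        if min(k) < -1e-12:
            raise ValueError("negative IBD coefficient")
        # 2e-6 leaves room for the 6-decimal rounding of the on-disk table
        if abs(sum(k) - 1.0) > 2e-6:
            raise ValueError("IBD coefficients do not sum to 1")
        if abs(self.kinship - (self.k1 / 4 + self.k2 / 2)) > 2e-6:
            raise ValueError("kinship inconsistent with k1/4 + k2/2")

    @property
    def r(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2])


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _open_text(path: str | os.PathLike) -> IO[str]:
    """Open plain or gzip text transparently (sniffs the gzip magic)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _fmt(x: float) -> str:
    """Shortest decimal string that parses back to exactly ``x``."""
    return repr(float(x))


class atomic_write:
    """Context manager writing to a temp file, renamed into place on success.

    Guarantees no partial output is left behind on error.  ``binary=True``
    plus ``gz=True`` layers gzip (with fixed mtime, for byte-reproducible
    output) on top.
    """

    def __init__(self, path: str | os.PathLike, gz: bool = False):
        self.path = os.fspath(path)
        self.gz = gz

    def __enter__(self) -> IO[str]:
        d = os.path.dirname(self.path) or "."
        fd, self._tmp = tempfile.mkstemp(dir=d, prefix=".tmp.", suffix="~")
        raw = os.fdopen(fd, "wb")
        if self.gz:
            self._fh = gzip.GzipFile(fileobj=raw, mode="wb", mtime=0)
            self._raw = raw
            import io

            self._txt = io.TextIOWrapper(self._fh, encoding="ascii", newline="\n")
        else:
            import io

            self._fh = raw
            self._raw = raw
            self._txt = io.TextIOWrapper(raw, encoding="ascii", newline="\n")
        return self._txt

    def __exit__(self, exc_type, exc, tb) -> None:
        try:
            self._txt.flush()
            if self.gz:
                self._txt.detach()
                self._fh.close()
            self._raw.close()
        except Exception:
            exc_type = exc_type or Exception
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            try:
                os.unlink(self._tmp)
            except OSError:
                pass


# ---------------------------------------------------------------------------
# Beagle genotype-likelihood files
# ---------------------------------------------------------------------------


def read_beagle(path: str | os.PathLike) -> GLDataset:
    """Read a Beagle genotype-likelihood file (gzip or plain text).

    The header must be ``marker allele1 allele2`` followed by three columns
    per individual.  Likelihood triples are preserved exactly as written --
    no renormalization is applied, since every downstream quantity is
    invariant to a positive per-triple scale factor.
    """
    with _open_text(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty Beagle file")
        cols = header.split()
        if len(cols) < 3 or (len(cols) - 3) % 3 != 0:
            raise FormatError(
                f"{path}: header has {len(cols)} columns; expected 3 metadata "
                "columns plus 3 per individual"
            )
        sample_ids = cols[3::3]
        n = len(sample_ids)
        n_cols = 3 + 3 * n
        markers: list[str] = []
        allele_a: list[str] = []
        allele_b: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            markers.append(parts[0])
            allele_a.append(parts[1])
            allele_b.append(parts[2])
            try:
                rows.append([float(t) for t in parts[3:]])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric likelihood") from e
    gl = np.asarray(rows, dtype=np.float64).reshape(len(rows), n, 3)
    return GLDataset(markers, allele_a, allele_b, gl, sample_ids)


def write_beagle(data: GLDataset, path: str | os.PathLike) -> None:
    """Write a Beagle file; gzip iff ``path`` ends with ``.gz``.

    Values are written with full round-trip precision, so
    ``read_beagle(write_beagle(x)) == x`` exactly.
    """
    gz = os.fspath(path).endswith(".gz")
    with atomic_write(path, gz=gz) as fh:
        header = ["marker", "allele1", "allele2"]
        for sid in data.sample_ids:
            header += [sid] * 3
        fh.write("\t".join(header) + "\n")
        flat = data.gl.reshape(data.n_sites, 3 * data.n_samples)
        for j in range(data.n_sites):
            fields = [data.markers[j], data.allele_a[j], data.allele_b[j]]
            fields += [_fmt(v) for v in flat[j]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Whitespace numeric matrices (.fopt / .qopt style)
# ---------------------------------------------------------------------------


def _read_numeric_matrix(path: str | os.PathLike) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            try:
                row = [float(t) for t in parts]
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from e
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(row)} != {width} columns)"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=np.float64)


def read_matrix(path: str | os.PathLike, kind: str) -> FreqPanel | AdmixturePanel:
    """Read an NGSadmix-style whitespace matrix.

    ``kind="freq"``: one row per site, one column per population; returned
    as a :class:`FreqPanel` (populations x sites).  ``kind="admixture"``:
    one row per individual; rows are renormalized when their sum is within
    1e-4 of 1, otherwise a :class:`ValueError` is raised.
    """
    mat = _read_numeric_matrix(path)
    if kind == "freq":
        if np.any(mat < 0) or np.any(mat > 1):
            raise ValueError(f"{path}: frequency outside [0, 1]")
        return FreqPanel(mat.T)
    if kind == "admixture":
        if np.any(mat < 0):
            raise ValueError(f"{path}: negative admixture proportion")
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-4
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"{path}: admixture row {i + 1} sums to {sums[i]:.6f}, not 1"
            )
        return AdmixturePanel(mat / sums[:, None])
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(mat: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 2-D array as whitespace text with round-trip precision."""
    mat = np.asarray(mat, dtype=np.float64)
    with atomic_write(path) as fh:
        for row in mat:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

_TABLE_HEADER = "ida\tidb\tk0\tk1\tk2\tkinship\tloglik\tniter\tconverged\tnSites"


def write_relatedness_table(
    results: Iterable[RelatednessResult], path: str | os.PathLike
) -> None:
    """Write pairwise results as TSV (floats with 6 decimals)."""
    with atomic_write(path) as fh:
        fh.write(_TABLE_HEADER + "\n")
        for r in results:
            fh.write(
                f"{r.id_a}\t{r.id_b}\t{r.k0:.6f}\t{r.k1:.6f}\t{r.k2:.6f}\t"
                f"{r.kinship:.6f}\t{r.loglik:.6f}\t{r.n_iter}\t"
                f"{int(r.converged)}\t{r.n_sites_used}\n"
            )


def read_relatedness_table(path: str | os.PathLike) -> list[RelatednessResult]:
    """Parse a table written by :func:`write_relatedness_table`."""
    out: list[RelatednessResult] = []
    with _open_text(path) as fh:
        header = fh.readline().strip()
        if header.split() != _TABLE_HEADER.split():
            raise FormatError(f"{path}: unexpected results-table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            p = line.split()
            if len(p) != 10:
                raise FormatError(f"{path}:{lineno}: expected 10 columns")
            out.append(
                RelatednessResult(
                    id_a=p[0],
                    id_b=p[1],
                    k0=float(p[2]),
                    k1=float(p[3]),
                    k2=float(p[4]),
                    kinship=float(p[5]),
                    loglik=float(p[6]),
                    n_iter=int(p[7]),
                    converged=bool(int(p[8])),
                    n_sites_used=int(p[9]),
                )
            )
    return out


def check_alignment(data: GLDataset, freqs: FreqPanel) -> None:
    """Require the GL file and frequency panel to cover the same sites.

    Silent intersection would hide upstream misalignment, so a mismatch in
    the number of sites is an error.
    """
    if data.n_sites != freqs.n_sites:
        raise ValueError(
            f"site count mismatch: {data.n_sites} sites in GL data vs "
            f"{freqs.n_sites} in the frequency panel"
        )
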