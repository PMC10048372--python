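"""Population structure: LD pruning, raw Hamming (allele-mismatch) distances
and classical multidimensional scaling (PCoA).

LD pruning slides a window of ``window_size`` markers advancing by ``step``
within each chromosome; inside a window, whenever two retained markers show
squared Pearson correlation of dosages above ``r2_max`` (computed over
pairwise-complete observations), the *later* marker is removed.  Processing
markers in ascending order makes the retained set deterministic and leaves no
violating pair within any window.

Distances are raw allele-mismatch counts: opposite homozygotes differ by 2,
het vs hom by 1, summed over sites called in both samples (no normalisation;
the pairwise complete-site count is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class PruneParams:
    window_size: int = 1000
    step: int = 100
    r2_max: float = 0.8

    def __post_init__(self) -> None:
        if self.step <= 0 or self.window_size <= 0 or self.step > self.window_size:
            raise ValueError("need 0 < step <= window_size")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray          # symmetric, zero diagonal
    n_complete: np.ndarray  # pairwise complete-site counts

    def __post_init__(self) -> None:
        d = self.d
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distances must be symmetric, non-negative, zero diagonal")


@dataclass(frozen=True)
class MDSResult:
    coordinates: np.ndarray  # n_samples x k
    eigenvalues: np.ndarray  # descending


def pairwise_r2(x: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns of ``x`` (NaN = missing),
    each pair over its complete observations.  Pairs with <2 complete rows or
    zero variance get r2 = 0."""
    x = np.asarray(x, dtype=float)
    present = np.isfinite(x)
    x0 = np.where(present, x, 0.0)
    mf = present.astype(float)
    n = mf.T @ mf
    sx = x0.T @ mf          # sum of x over rows complete in both
    sy = sx.T
    sxy = x0.T @ x0
    sxx = (x0 ** 2).T @ mf
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sxx - sx ** 2
        var_y = n * syy - sy ** 2
        r2 = cov ** 2 / (var_x * var_y)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(m: GenotypeMatrix, p: PruneParams = PruneParams()) -> np.ndarray:
    """Deterministic LD pruning; returns retained site indices into
    ``m.sites``.  Monomorphic markers count as uncorrelated (r2 = 0)."""
    x_all = m.calls.astype(float)
    x_all[m.calls == MISSING] = np.nan
    retained = np.ones(m.n_sites, dtype=bool)
    for chrom in m.chromosomes():
        sl = m.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        n = idx.size
        for s in range(0, n, p.step):
            win = idx[s: s + p.window_size]
            live = win[retained[win]]
            if live.size < 2:
                continue
            r2 = pairwise_r2(x_all[:, live])
            keep = np.ones(live.size, dtype=bool)
            for j in range(1, live.size):
                if (r2[:j, j][keep[:j]] > p.r2_max).any():
                    keep[j] = False
            retained[live[~keep]] = False
            if s + p.window_size >= n:
                break
    return np.flatnonzero(retained)


def hamming_distance(m: GenotypeMatrix,
                     sites: np.ndarray | None = None) -> DistanceMatrix:
    """Raw pairwise allele-mismatch distances over sites called in both
    samples of each pair.  A pair with zero mutually called sites is an
    error."""
    if m.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = m.calls if sites is None else m.calls[:, np.asarray(sites)]
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    n = m.n_samples
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=np.int64)
    nc[np.diag_indices(n)] = (calls != MISSING).sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            both = np.isfinite(x[i]) & np.isfinite(x[j])
            cnt = int(both.sum())
            if cnt == 0:
                raise ValueError(
                    f"samples {m.samples[i]} and {m.samples[j]} share no "
                    "called sites")
            d[i, j] = d[j, i] = float(np.abs(x[i, both] - x[j, both]).sum())
            nc[i, j] = nc[j, i] = cnt
    return DistanceMatrix(labels=tuple(m.samples), d=d, n_complete=nc)


def classical_mds(dm: DistanceMatrix, k: int = 3) -> MDSResult:
    """Classical MDS / principal coordinates: double-centre -1/2 D^2,
    eigendecompose, scale the top-k nonnegative eigenvectors by sqrt(lambda).
    Sign convention: the first nonzero loading of each component is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = dm.d
    n = d.shape[0]
    k = min(k, n - 1)
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d ** 2) @ j_mat
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    for c in range(k):
        lam = eigval[c]
        if lam > 0:
            v = eigvec[:, c] * np.sqrt(lam)
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            if nz.size and v[nz[0]] < 0:
                v = -v
            coords[:, c] = v
    return MDSResult(coordinates=coords, eigenvalues=eigval[:k])
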