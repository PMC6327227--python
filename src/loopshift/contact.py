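"""Binned intra-chromosomal contact matrices: I/O, IPF normalization, distance decay.

Counts from chromosome-conformation capture (TCC / in situ Hi-C style) are
binned into fixed-size genomic intervals; the entry (i, j) of the per-chromosome
contact matrix counts ligation products linking bins i and j.  Raw counts are
confounded by per-bin "visibility" (accessibility, restriction-site density,
mappability), modelled multiplicatively as C_ij ~ b_i * b_j * (true contact
propensity).  Iterative proportional fitting (IPF) estimates the per-bin bias
coefficients b_i by alternately equalizing the marginals of the rescaled
matrix; the normalized count is N_ij = C_ij / (b_i * b_j).

The expected signal at genomic distance r is summarized by a per-chromosome
distance-decay curve E(r) (the mean normalized count over all bin pairs at
distance r, lightly smoothed), so that the expected count for a pair is
S_ij = b_i * b_j * E(|i - j|).

Conventions
-----------
* Genomic intervals are 0-based, half-open; bin i spans
  [i * bin_size, (i + 1) * bin_size).
* Matrices are stored strictly upper-triangular-plus-diagonal (i <= j);
  symmetry is implicit.
* Bins with zero marginal count are masked: IPF does not attempt to balance
  them and no normalized entry touches them.
* Bias coefficients are reported with geometric mean 1 over unmasked bins,
  which makes them comparable across samples.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "BiasVector",
    "NormalizedMatrix",
    "ExpectedModel",
    "read_contacts",
    "ipf_normalize",
    "fit_expected",
    "write_bias_tsv",
    "write_expected_tsv",
]


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Sparse symmetric contact matrix for one chromosome.

    Entries are stored as parallel arrays ``rows``, ``cols``, ``vals`` with
    ``rows <= cols`` (upper triangle plus diagonal).  Duplicate coordinates
    are summed at construction.
    """

    chromosome: str
    bin_size: int
    n_bins: int
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    replicate_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        self.vals = np.asarray(self.vals)
        if np.any(self.vals < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.vals, np.round(self.vals)):
            raise ValueError("contact counts must be integral")
        self.vals = np.round(self.vals).astype(np.int64)
        # fold lower triangle onto upper, then sum duplicates
        lower = self.rows > self.cols
        if np.any(lower):
            r = np.where(lower, self.cols, self.rows)
            c = np.where(lower, self.rows, self.cols)
            self.rows, self.cols = r, c
        if np.any((self.rows < 0) | (self.cols >= self.n_bins)):
            raise ValueError("bin index out of range")
        key = self.rows * self.n_bins + self.cols
        uniq, inv = np.unique(key, return_inverse=True)
        if uniq.size != key.size:
            vals = np.bincount(inv, weights=self.vals).astype(np.int64)
            self.rows = (uniq // self.n_bins).astype(np.int64)
            self.cols = (uniq % self.n_bins).astype(np.int64)
            self.vals = vals
        else:
            order = np.argsort(key)
            self.rows = self.rows[order]
            self.cols = self.cols[order]
            self.vals = self.vals[order]

    @property
    def entries(self) -> dict[tuple[int, int], int]:
        return {
            (int(i), int(j)): int(v)
            for i, j, v in zip(self.rows, self.cols, self.vals)
        }

    def coverage(self) -> np.ndarray:
        """Per-bin marginal count of the symmetric matrix (diagonal once)."""
        cov = np.bincount(self.rows, weights=self.vals, minlength=self.n_bins)
        off = self.rows != self.cols
        cov += np.bincount(
            self.cols[off], weights=self.vals[off], minlength=self.n_bins
        )
        return cov

    def band(self, max_dist: int) -> np.ndarray:
        """Dense diagonal-band view: ``band[i, d]`` is the count at (i, i+d).

        Cells with i + d >= n_bins are NaN; absent entries are 0 (structural
        zeros are genuine observations in count data).
        """
        return _band(self.rows, self.cols, self.vals, self.n_bins, max_dist)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.rows, self.cols] = self.vals
        m[self.cols, self.rows] = self.vals
        return m

    def total(self) -> int:
        return int(self.vals.sum())


@dataclass
class BiasVector:
    """Per-bin IPF bias coefficients; masked (unmappable) bins are NaN."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the bin is masked."""
        return np.isnan(self.values)

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class NormalizedMatrix:
    """IPF-normalized contact matrix N_ij = C_ij / (b_i * b_j)."""

    chromosome: str
    bin_size: int
    n_bins: int
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    bias: BiasVector
    source: str = ""

    def band(self, max_dist: int) -> np.ndarray:
        """Band view with masked bins set to NaN on both axes."""
        b = _band(self.rows, self.cols, self.vals, self.n_bins, max_dist)
        masked = np.flatnonzero(self.bias.mask)
        if masked.size:
            b[masked, :] = np.nan
            for d in range(b.shape[1]):
                hit = masked - d
                hit = hit[(hit >= 0) & (hit < self.n_bins)]
                b[hit, d] = np.nan
        return b

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.rows, self.cols] = self.vals
        m[self.cols, self.rows] = self.vals
        masked = self.bias.mask
        m[masked, :] = np.nan
        m[:, masked] = np.nan
        return m


@dataclass
class ExpectedModel:
    """Distance-decay curve E(r) plus bias vector: S_ij = b_i * b_j * E(|i-j|)."""

    chromosome: str
    bin_size: int
    decay: np.ndarray  # decay[r] = E(r), r in bins, 0..r_max
    bias: BiasVector
    smoothing_half_window: float = 1.5

    def expected_count(self, i: int, j: int) -> float:
        """Expected count S_ij = b_i * b_j * E(|i - j|); not integral."""
        bi, bj = self.bias.values[i], self.bias.values[j]
        if np.isnan(bi) or np.isnan(bj):
            raise ValueError("masked bin")
        r = abs(int(j) - int(i))
        if r >= self.decay.size:
            raise ValueError(f"distance {r} outside fitted range")
        return float(bi * bj * self.decay[r])

    def expected_band(self, max_dist: int) -> np.ndarray:
        """Band array of S_ij; NaN at masked bins / distances beyond the fit."""
        n = self.bias.n_bins
        D = max_dist + 1
        dec = np.full(D, np.nan)
        upto = min(D, self.decay.size)
        dec[:upto] = self.decay[:upto]
        b = self.bias.values
        out = b[:, None] * dec[None, :]
        for d in range(D):
            out[: n - d, d] *= b[d:]
            out[n - d :, d] = np.nan
        return out


def _band(rows, cols, vals, n_bins, max_dist) -> np.ndarray:
    out = np.zeros((n_bins, max_dist + 1))
    for d in range(max_dist + 1):
        out[n_bins - d :, d] = np.nan
    d = cols - rows
    keep = d <= max_dist
    out[rows[keep], d[keep]] = vals[keep]
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_contacts(
    path,
    bin_size: int,
    n_bins: int,
    coords: str = "bp",
    chromosome: str = "",
    replicate_label: str = "",
    condition_label: str = "",
) -> ContactMatrix:
    """Read whitespace-separated contact triples into a :class:`ContactMatrix`.

    Parameters
    ----------
    path
        Text file (gzip transparent) with three columns per line:
        ``start_i start_j count``.  With ``coords="bp"`` the first two columns
        are bin start coordinates in base pairs; with ``coords="bins"`` they
        are bin indices.
    bin_size, n_bins
        Geometry of the binning; coordinates beyond ``n_bins * bin_size``
        are rejected with the offending line number.

    Records with swapped coordinates (j, i) are folded onto (i, j) and
    duplicates are summed.
    """
    if coords not in ("bp", "bins"):
        raise ValueError(f"unknown coordinate dialect {coords!r}")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+", header=None, comment="#")
    if df.shape[1] != 3:
        raise ValueError(f"expected 3 columns, found {df.shape[1]}")
    a = df.iloc[:, 0].to_numpy()
    b = df.iloc[:, 1].to_numpy()
    v = df.iloc[:, 2].to_numpy()
    bad = np.flatnonzero(v < 0)
    if bad.size:
        raise ValueError(f"negative count on line {bad[0] + 1}")
    if coords == "bp":
        limit = n_bins * bin_size
        bad = np.flatnonzero((a < 0) | (b < 0) | (a >= limit) | (b >= limit))
        if bad.size:
            raise ValueError(f"coordinate out of range on line {bad[0] + 1}")
        a = a // bin_size
        b = b // bin_size
    else:
        bad = np.flatnonzero((a < 0) | (b < 0) | (a >= n_bins) | (b >= n_bins))
        if bad.size:
            raise ValueError(f"bin index out of range on line {bad[0] + 1}")
    return ContactMatrix(
        chromosome=chromosome,
        bin_size=bin_size,
        n_bins=n_bins,
        rows=a,
        cols=b,
        vals=v,
        replicate_label=replicate_label,
        condition_label=condition_label,
    )


def pool_replicates(matrices: list[ContactMatrix]) -> ContactMatrix:
    """Sum counts over replicates of one condition."""
    first = matrices[0]
    if any(m.n_bins != first.n_bins or m.bin_size != first.bin_size for m in matrices):
        raise ValueError("replicates must share binning")
    return ContactMatrix(
        chromosome=first.chromosome,
        bin_size=first.bin_size,
        n_bins=first.n_bins,
        rows=np.concatenate([m.rows for m in matrices]),
        cols=np.concatenate([m.cols for m in matrices]),
        vals=np.concatenate([m.vals for m in matrices]),
        replicate_label="pooled",
        condition_label=first.condition_label,
    )


def write_contacts(matrix: ContactMatrix, path, coords: str = "bp") -> None:
    """Write contact triples in the same dialects :func:`read_contacts` accepts."""
    a, b = matrix.rows, matrix.cols
    if coords == "bp":
        a = a * matrix.bin_size
        b = b * matrix.bin_size
    pd.DataFrame({"a": a, "b": b, "count": matrix.vals}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bias_tsv(bias: BiasVector, path) -> None:
    pd.DataFrame({"bin": np.arange(bias.n_bins), "bias": bias.values}).to_csv(
        path, sep="\t", index=False
    )


def write_expected_tsv(model: ExpectedModel, path) -> None:
    pd.DataFrame(
        {"distance_bins": np.arange(model.decay.size), "expected": model.decay}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# IPF normalization
# ---------------------------------------------------------------------------


def ipf_normalize(
    matrix: ContactMatrix, iterations: int = 20
) -> tuple[BiasVector, NormalizedMatrix]:
    """Estimate per-bin biases by iterative proportional fitting.

    Each iteration rescales the bias vector by the current relative coverage
    of the normalized matrix, so that the marginals of N = C / (b b^T)
    approach uniformity over unmasked bins.  Bins with zero raw coverage are
    masked before fitting (IPF cannot balance an empty marginal) and excluded
    from all downstream statistics.

    Returns the bias vector (geometric mean 1 over unmasked bins) and the
    normalized matrix.  Guarantees that the coefficient of variation of the
    per-bin coverages does not increase.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    cov0 = matrix.coverage()
    unmasked = cov0 > 0
    if not np.any(unmasked):
        raise ValueError("empty matrix")
    n = matrix.n_bins
    rows, cols, vals = matrix.rows, matrix.cols, matrix.vals.astype(float)
    b = np.ones(n)
    off = rows != cols
    for _ in range(iterations):
        w = vals / (b[rows] * b[cols])
        cov = np.bincount(rows, weights=w, minlength=n)
        cov += np.bincount(cols[off], weights=w[off], minlength=n)
        mean_cov = cov[unmasked].mean()
        update = np.ones(n)
        update[unmasked] = cov[unmasked] / mean_cov
        b *= update
    # geometric-mean-1 convention over unmasked bins
    b /= np.exp(np.mean(np.log(b[unmasked])))
    bias_values = np.where(unmasked, b, np.nan)
    bias = BiasVector(bias_values)
    keep = unmasked[rows] & unmasked[cols]
    nvals = vals[keep] / (b[rows[keep]] * b[cols[keep]])
    normalized = NormalizedMatrix(
        chromosome=matrix.chromosome,
        bin_size=matrix.bin_size,
        n_bins=n,
        rows=rows[keep],
        cols=cols[keep],
        vals=nvals,
        bias=bias,
        source=f"{matrix.condition_label}/{matrix.replicate_label}",
    )
    return bias, normalized


# ---------------------------------------------------------------------------
# Distance-decay expected model
# ---------------------------------------------------------------------------


def fit_expected(
    normalized: NormalizedMatrix, smoothing_half_window: float = 1.5
) -> ExpectedModel:
    """Fit the distance-decay curve E(r) from a normalized matrix.

    For each distance r (in bins) the mean of N_ij over all unmasked bin
    pairs at that distance is computed, counting structural zeros.  The
    per-distance means are then smoothed with an unweighted running average
    over the integer distances within ``smoothing_half_window`` of r
    (window {r-1, r, r+1} at the default 1.5), truncated to the available
    range at the curve ends.
    """
    n = normalized.n_bins
    unmasked = ~normalized.bias.mask
    d = normalized.cols - normalized.rows
    if not np.any(d > 0):
        raise ValueError("normalized matrix has no off-diagonal entries")
    r_max = int(d.max())
    sums = np.bincount(d, weights=normalized.vals, minlength=r_max + 1)
    # number of unmasked pairs per distance (structural zeros included)
    um = unmasked.astype(float)
    pair_counts = np.empty(r_max + 1)
    pair_counts[0] = um.sum()
    for r in range(1, r_max + 1):
        pair_counts[r] = float(um[:-r] @ um[r:])
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(pair_counts > 0, sums / pair_counts, np.nan)
    if np.all(np.isnan(means)):
        raise ValueError("no unmasked pairs at any distance")
    half = int(np.floor(smoothing_half_window))
    decay = _running_mean_nan(means, half)
    return ExpectedModel(
        chromosome=normalized.chromosome,
        bin_size=normalized.bin_size,
        decay=decay,
        bias=normalized.bias,
        smoothing_half_window=smoothing_half_window,
    )


def _running_mean_nan(x: np.ndarray, half: int) -> np.ndarray:
    """Truncated running mean over a +/- half window, ignoring NaN."""
    n = x.size
    out = np.full(n, np.nan)
    finite = np.isfinite(x)
    xs = np.where(finite, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    ccnt = np.concatenate([[0.0], np.cumsum(finite.astype(float))])
    for r in range(n):
        lo = max(0, r - half)
        hi = min(n - 1, r + half)
        cnt = ccnt[hi + 1] - ccnt[lo]
        if cnt > 0:
            out[r] = (csum[hi + 1] - csum[lo]) / cnt
    return out
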