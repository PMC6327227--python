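"""Domain-topology metrics: directionality index, insulation, compartments, domains.

The directionality index (DI) asks whether a bin interacts predominantly with
loci to its left or right.  With A_i and B_i the summed normalized signal in a
2 Mb window to the left and right of bin i, and E_i = (A_i + B_i)/2,

    DI_i = sign(B_i - A_i) * ((A_i - E_i)^2 / E_i + (B_i - E_i)^2 / E_i)
         = sign(B_i - A_i) * (A_i - B_i)^2 / (A_i + B_i),

a chi-square-like statistic whose sign marks the preferred direction.

The insulation score (IS) of a bin measures its ability to block contacts:
the 5x5 pixel square centered on (b - Z, b + Z) sums signal crossing the bin
at off-diagonal distance 2Z ("between", X'); translating the square by D bins
toward 5' and 3' yields within-domain aggregates L' and R' ("inside"), and

    IS_b = log2( 0.5 * (L' + R') / X' ).

Positive IS marks strong insulators.  Defaults Z = 5 and D = 15 are tuned to
10-kb bins: D is large enough to escape the ~5-pixel stripe a loop anchor
projects into the domain, yet small enough to stay inside the flanking
domains.

A/B compartments come from the sign structure of long-range contacts at 50-kb
resolution: the coverage-normalized matrix is detrended by a smoothed
per-distance mode, the correlation matrix of the result is eigendecomposed,
and among the first three eigenvectors the one that best separates the matrix
into two blocks is taken.  The sign convention is fixed by expression: the
bin group with higher aggregate expression is compartment A (positive).

Contact domains (inputs, called externally) are classified into loop domains
(both boundaries joined by one loop), ordinary domains (no internal loop, not
nested in a loop domain), and other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .contact import ContactMatrix, NormalizedMatrix
from .loops import LoopRecord, neighborhood_sum

__all__ = [
    "DirectionalityTrack",
    "InsulationProfile",
    "CompartmentTrack",
    "DomainRecord",
    "directionality_index",
    "insulation_score",
    "call_compartments",
    "classify_domains",
    "annotate_domains",
]


@dataclass
class DirectionalityTrack:
    di: np.ndarray  # NaN where undefined
    a: np.ndarray
    b: np.ndarray
    window: int  # bp
    bin_size: int

    @property
    def e(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)

    @property
    def undefined(self) -> np.ndarray:
        return ~np.isfinite(self.di)


@dataclass
class InsulationProfile:
    score: np.ndarray  # per-bin IS, NaN where undefined
    x_prime: np.ndarray
    l_prime: np.ndarray
    r_prime: np.ndarray
    z: int
    d: int
    half_width: int
    bin_size: int


@dataclass
class CompartmentTrack:
    values: np.ndarray  # signed eigenvector entries, NaN for masked bins
    labels: np.ndarray  # "A" / "B" / "" per bin
    eigenvector_index: int  # 1-based rank among the top three
    bin_size: int


@dataclass
class DomainRecord:
    chromosome: str
    start: int
    end: int
    domain_type: str = ""  # loop | ordinary | other
    compartment: str = ""
    boundary5: tuple[int, int] | None = None
    boundary3: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# Directionality index
# ---------------------------------------------------------------------------


def directionality_index(
    normalized: NormalizedMatrix, window: int = 2_000_000
) -> DirectionalityTrack:
    """Per-bin directionality index over a left/right window of ``window`` bp."""
    bs = normalized.bin_size
    if window % bs:
        raise ValueError("window must be a multiple of the bin size")
    w = window // bs
    n = normalized.n_bins
    band = normalized.band(w)
    A = np.zeros(n)
    B = np.zeros(n)
    for d in range(1, w + 1):
        B[: n - d] += band[: n - d, d]
        B[n - d :] = np.nan
        A[d:] += band[: n - d, d]
        A[:d] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.sign(B - A) * (A - B) ** 2 / (A + B)
    di[~np.isfinite(di)] = np.nan
    di[np.isfinite(A) & np.isfinite(B) & (A == B)] = 0.0
    # window truncated at the chromosome ends -> undefined
    di[:w] = np.nan
    di[n - w :] = np.nan
    return DirectionalityTrack(di=di, a=A, b=B, window=window, bin_size=bs)


# ---------------------------------------------------------------------------
# Insulation score
# ---------------------------------------------------------------------------


def insulation_score(
    normalized: NormalizedMatrix, z: int = 5, d: int = 15, half_width: int = 2
) -> InsulationProfile:
    """Insulation score per bin from 5x5 square aggregates at distance 2Z.

    Bins whose central or translated squares leave the matrix (or touch a
    masked bin, or have X' = 0) are flagged undefined (NaN), not fatal.
    """
    n = normalized.n_bins
    two_z = 2 * z
    dmax = two_z + 2 * half_width
    band = normalized.band(dmax)
    sq = neighborhood_sum(band, radius=half_width)
    center_col = sq[:, two_z]  # indexed by square-center row i
    X = np.full(n, np.nan)
    L = np.full(n, np.nan)
    R = np.full(n, np.nan)
    for b in range(n):
        i = b - z
        if 0 <= i < n:
            X[b] = center_col[i]
        if 0 <= i - d < n:
            L[b] = center_col[i - d]
        if 0 <= i + d < n:
            R[b] = center_col[i + d]
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.log2(0.5 * (L + R) / X)
    score[~np.isfinite(score)] = np.nan
    return InsulationProfile(
        score=score,
        x_prime=X,
        l_prime=L,
        r_prime=R,
        z=z,
        d=d,
        half_width=half_width,
        bin_size=normalized.bin_size,
    )


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------


def _distance_mode(values: np.ndarray) -> float:
    """Histogram mode over nonzero values (Freedman-Diaconis bin width)."""
    v = values[values > 0]
    if v.size == 0:
        return np.nan
    if v.size < 5 or np.ptp(v) == 0:
        return float(np.mean(v))
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    width = 2 * iqr / v.size ** (1 / 3)
    if width <= 0:
        return float(np.mean(v))
    nbins = max(1, int(np.ceil(np.ptp(v) / width)))
    hist, edges = np.histogram(v, bins=min(nbins, 200))
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def call_compartments(
    raw: ContactMatrix, expression: np.ndarray
) -> CompartmentTrack:
    """A/B compartment assignment from a 50-kb contact matrix.

    Steps: coverage normalization; per-distance mode estimation smoothed by a
    spline into a trend d(|i-j|); detrending N = W/d; eigendecomposition of
    the correlation matrix of N; among the first three eigenvectors the one
    maximizing (mean within-sign-group correlation - mean between-group
    correlation) defines the partition; the sign is fixed so the group with
    higher aggregate ``expression`` is positive and labelled A.
    """
    n = raw.n_bins
    if n < 20:
        raise ValueError("too short for compartment analysis")
    expression = np.asarray(expression, dtype=float)
    if expression.size != n:
        raise ValueError("expression scores must have one value per bin")
    W = raw.to_dense().astype(float)
    cov = W.sum(axis=0)
    unmasked = cov > 0
    idx = np.flatnonzero(unmasked)
    Wn = W[np.ix_(idx, idx)] / np.outer(cov[idx], cov[idx])
    m = idx.size
    # per-distance mode, spline-smoothed into a decay trend
    rs, modes = [], []
    for r in range(1, m):
        diag = np.diagonal(Wn, offset=r)
        mode = _distance_mode(np.asarray(diag))
        if np.isfinite(mode) and mode > 0:
            rs.append(r)
            modes.append(mode)
    if len(rs) < 4:
        raise ValueError("not enough distances with signal")
    rs = np.asarray(rs, dtype=float)
    modes = np.asarray(modes)
    spl = UnivariateSpline(np.log(rs), np.log(modes), k=3, s=len(rs))
    trend = np.exp(spl(np.log(np.arange(1, m))))
    N = np.ones_like(Wn)
    for r in range(1, m):
        t = max(trend[r - 1], 1e-300)
        ii = np.arange(m - r)
        N[ii, ii + r] = Wn[ii, ii + r] / t
        N[ii + r, ii] = N[ii, ii + r]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(N)
    corr = np.nan_to_num(corr, nan=0.0)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1][:3]
    best, best_score, best_rank = None, -np.inf, 0
    for rank, k in enumerate(order, start=1):
        v = evecs[:, k]
        pos, neg = v > 0, v <= 0
        if pos.sum() == 0 or neg.sum() == 0:
            continue
        within = 0.5 * (corr[np.ix_(pos, pos)].mean() + corr[np.ix_(neg, neg)].mean())
        between = corr[np.ix_(pos, neg)].mean()
        score = within - between
        if score > best_score:
            best, best_score, best_rank = v, score, rank
    if best is None:
        best, best_rank = evecs[:, order[0]], 1
    expr = expression[idx]
    pos = best > 0
    if expr[pos].sum() < expr[~pos].sum():
        best = -best
    values = np.full(n, np.nan)
    values[idx] = best
    labels = np.full(n, "", dtype=object)
    labels[idx] = np.where(best > 0, "A", "B")
    return CompartmentTrack(
        values=values,
        labels=labels,
        eigenvector_index=best_rank,
        bin_size=raw.bin_size,
    )


# ---------------------------------------------------------------------------
# Domain classification and annotation
# ---------------------------------------------------------------------------


def _intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_domains(
    domains, loops: list[LoopRecord], extension: int = 20_000
) -> list[DomainRecord]:
    """Type contact domains as loop / ordinary / other.

    A loop domain's start and end boundaries (each extended by ``extension``
    on both sides) intersect the two anchors (likewise extended) of a single
    loop.  An ordinary domain contains no internal loop (both anchor
    midpoints strictly inside) and is not nested inside a loop domain.
    Malformed intervals (end <= start) are rejected (skipped).
    """
    recs = []
    for dom in domains:
        chrom, start, end = dom
        if end <= start:
            continue
        recs.append(DomainRecord(chromosome=chrom, start=int(start), end=int(end)))

    def ext(iv):
        return (iv[0] - extension, iv[1] + extension)

    loop_domain_ivals = []
    for rec in recs:
        b5 = (rec.start - extension, rec.start + extension)
        b3 = (rec.end - extension, rec.end + extension)
        is_loop = any(
            lp.chromosome == rec.chromosome
            and _intersects(b5, ext(lp.anchor5))
            and _intersects(b3, ext(lp.anchor3))
            for lp in loops
        )
        if is_loop:
            rec.domain_type = "loop"
            loop_domain_ivals.append((rec.chromosome, rec.start, rec.end))
    for rec in recs:
        if rec.domain_type == "loop":
            continue
        internal = any(
            lp.chromosome == rec.chromosome
            and rec.start < (lp.anchor5[0] + lp.anchor5[1]) // 2 < rec.end
            and rec.start < (lp.anchor3[0] + lp.anchor3[1]) // 2 < rec.end
            for lp in loops
        )
        nested = any(
            c == rec.chromosome and s <= rec.start and rec.end <= e and (s, e) != (rec.start, rec.end)
            for c, s, e in loop_domain_ivals
        )
        rec.domain_type = "other" if (internal or nested) else "ordinary"
    return recs


def track_to_bedgraph(
    values: np.ndarray, chromosome: str, bin_size: int, path
) -> None:
    """Write a per-bin signed track as bedGraph (0-based half-open); NaN bins skipped."""
    with open(path, "w") as fh:
        for b, v in enumerate(np.asarray(values, dtype=float)):
            if np.isfinite(v):
                fh.write(f"{chromosome}\t{b * bin_size}\t{(b + 1) * bin_size}\t{v:.6g}\n")


def domains_to_bed(records: list[DomainRecord], path) -> None:
    """Write domain records as BED with the name carrying type and compartment."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t"
                f"{r.domain_type or 'NA'}|{r.compartment or 'NA'}\n"
            )


def annotate_domains(
    records: list[DomainRecord],
    compartments: CompartmentTrack,
    boundary_half: int = 15_000,
) -> list[DomainRecord]:
    """Attach 30-kb boundary intervals and A/B compartment labels in place.

    A domain is in compartment A when strictly more than 50% of its
    constituent compartment-resolution bins are labelled A (ties go to B);
    constituent bins are those fully contained in the domain, falling back to
    overlapping bins for domains shorter than one compartment bin.
    """
    cbs = compartments.bin_size
    for rec in records:
        rec.boundary5 = (rec.start - boundary_half, rec.start + boundary_half)
        rec.boundary3 = (rec.end - boundary_half, rec.end + boundary_half)
        first = -(-rec.start // cbs)  # first bin fully inside
        last = rec.end // cbs  # one-past-last fully inside
        if last <= first:  # short domain: use overlapping bins
            first, last = rec.start // cbs, -(-rec.end // cbs)
        lab = compartments.labels[first:last]
        lab = lab[lab != ""]
        if lab.size:
            frac_a = float(np.mean(lab == "A"))
            rec.compartment = "A" if frac_a > 0.5 else "B"
    return records
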