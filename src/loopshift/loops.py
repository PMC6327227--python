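"""Significant-interaction testing, loop detection, and differential loop strength.

Interaction calling treats each bin pair (pixel) within 2 Mb of the diagonal
as a count observation.  Raw counts are aggregated over the 3x3 pixel square
centered on the pixel (sums, not means, so the aggregate remains a count) and
compared against the matching aggregate of expected counts S'_ij via an
intercept-only negative-binomial regression with log link and offset log S':

    C'_k ~ NB(mu_k, alpha),   log mu_k = beta + log S'_k

so exp(beta) is the fold enrichment of observed over expected.  A one-sided
Wald test of H0: beta <= 0 flags pixels with evidence of a specific
interaction; Benjamini-Hochberg adjustment is applied over all tested pixels
and calls require adjusted p < 0.20 and fold change > 1.5.

Loops are then distilled from significant pixels by a local-background filter
(the center normalized value must exceed donut, lower-left-quadrant, and
stripe neighborhood means, in the spirit of focal-enrichment loop callers),
8-connectivity clustering of surviving pixels, and a minimum anchor
separation of 120 kb.

Differential loop strength between two conditions reuses the same machinery
with a condition coefficient gamma (log2 fold change of condition 2 over
condition 1, each sample carrying its own expected offsets) and a two-sided
Wald test.  Dispersions are estimated by conditional maximum likelihood
within mean-rank bins, smoothed with a moving average — a deliberately
conservative (upward-biased) estimate.

Variance convention throughout: Var = mu + alpha * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .contact import ContactMatrix, ExpectedModel, NormalizedMatrix

__all__ = [
    "NeighborhoodAggregate",
    "InteractionCall",
    "LoopRecord",
    "DispersionEstimate",
    "UntestablePixel",
    "aggregate_neighborhood",
    "neighborhood_sum",
    "estimate_dispersions",
    "nb_fit_intercept",
    "test_interactions",
    "call_interactions",
    "detect_loops",
    "test_differential_loops",
]

ALPHA_FLOOR = 1e-8


class UntestablePixel(ValueError):
    """The 3x3 neighborhood crosses the diagonal or the matrix edge."""


@dataclass
class NeighborhoodAggregate:
    """Summed raw and expected counts over the 3x3 square B around a pixel."""

    center: tuple[int, int]
    c_prime: np.ndarray  # per replicate
    s_prime: np.ndarray  # per replicate
    neighborhood_size: int = 9


@dataclass
class InteractionCall:
    center: tuple[int, int]
    beta: float
    wald_p: float
    adj_p: float
    fold_change: float

    @property
    def significant(self) -> bool:
        return self.adj_p < 0.20 and self.fold_change > 1.5


@dataclass
class LoopRecord:
    """A called loop: two anchor intervals joined by a cluster of pixels."""

    chromosome: str
    anchor5: tuple[int, int]  # bp, half-open
    anchor3: tuple[int, int]
    pixel_cluster: frozenset
    condition_of_discovery: str = ""
    best_p: float = np.nan

    def midpoint_separation(self) -> int:
        m5 = (self.anchor5[0] + self.anchor5[1]) // 2
        m3 = (self.anchor3[0] + self.anchor3[1]) // 2
        return abs(m3 - m5)


@dataclass
class DispersionEstimate:
    alpha: np.ndarray  # per pixel
    descriptor: str = ""


# ---------------------------------------------------------------------------
# Neighborhood aggregation
# ---------------------------------------------------------------------------


def neighborhood_sum(band: np.ndarray, radius: int = 1) -> np.ndarray:
    """(2r+1)x(2r+1) square sums on a diagonal-band matrix view.

    ``band[i, d]`` holds the value at matrix pixel (i, i + d).  The square
    around (i, j) in matrix coordinates maps to band cells
    (i + di, d + dj - di).  Cells whose square leaves the band, the matrix,
    or touches/crosses the diagonal (any member at distance < 1) are NaN.
    """
    n, D = band.shape
    pad = np.full((n + 2 * radius, D + 4 * radius), np.nan)
    pad[radius : radius + n, 2 * radius : 2 * radius + D] = band
    out = np.zeros((n, D))
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            s = dj - di
            out += pad[radius + di : radius + di + n, 2 * radius + s : 2 * radius + s + D]
    out[:, : 2 * radius + 1] = np.nan  # square would touch or cross the diagonal
    return out


def aggregate_neighborhood(
    raw, model, center: tuple[int, int], radius: int = 1
) -> NeighborhoodAggregate:
    """Sum raw and expected counts over the 3x3 square B centered on a pixel.

    ``raw`` and ``model`` may be single objects or per-replicate sequences.
    Sums (not means) are returned so the aggregates remain interpretable as
    sequencing counts.
    """
    raws = [raw] if isinstance(raw, ContactMatrix) else list(raw)
    models = [model] if isinstance(model, ExpectedModel) else list(model)
    if len(models) == 1 and len(raws) > 1:
        models = models * len(raws)
    i, j = center
    n = raws[0].n_bins
    if not (radius <= i and j + radius < n and (j - i) - 2 * radius >= 1):
        raise UntestablePixel(f"untestable pixel ({i}, {j})")
    offs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    c_prime = np.zeros(len(raws))
    s_prime = np.zeros(len(raws))
    for k, (m, em) in enumerate(zip(raws, models)):
        ent = {}
        for r, c, v in zip(m.rows, m.cols, m.vals):
            ent[(r, c)] = v
        for di, dj in offs:
            c_prime[k] += ent.get((i + di, j + dj), 0)
            s_prime[k] += em.expected_count(i + di, j + dj)
    return NeighborhoodAggregate(center=(i, j), c_prime=c_prime, s_prime=s_prime)


# ---------------------------------------------------------------------------
# Negative-binomial machinery
# ---------------------------------------------------------------------------


def nb_fit_intercept(
    counts: np.ndarray, offsets: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ML fit of the intercept-only NB regression per pixel.

    counts, offsets : (P, R) arrays; offsets are log expected counts.
    alpha : (P,) dispersions (fixed and known during testing; two-stage).

    Returns (beta_hat, se) where se comes from the observed Fisher
    information at the maximum.  Solved by a damped Newton iteration on the
    score  U(b) = sum_k theta (C_k - mu_k) / (mu_k + theta),
    with  I(b) = sum_k theta mu_k (C_k + theta) / (mu_k + theta)^2.
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    alpha = np.maximum(np.asarray(alpha, dtype=float), ALPHA_FLOOR)
    theta = (1.0 / alpha)[:, None]
    S = np.exp(offsets)
    tot_c = counts.sum(axis=1)
    tot_s = S.sum(axis=1)
    beta = np.log(np.maximum(tot_c, 0.5) / tot_s)
    for _ in range(100):
        mu = np.exp(beta)[:, None] * S
        U = (theta * (counts - mu) / (mu + theta)).sum(axis=1)
        info = (theta * mu * (counts + theta) / (mu + theta) ** 2).sum(axis=1)
        step = np.clip(U / np.maximum(info, 1e-300), -3.0, 3.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(beta)[:, None] * S
    info = (theta * mu * (counts + theta) / (mu + theta) ** 2).sum(axis=1)
    se = 1.0 / np.sqrt(np.maximum(info, 1e-300))
    return beta, se


def _cml_loglik(log_alpha: float, counts: np.ndarray, groups: np.ndarray) -> float:
    """Conditional NB log-likelihood given per-group replicate sums.

    Exact for equal within-group means (the classic-mode setting); the
    condition effect drops out by conditioning on each group's sum.
    """
    theta = np.exp(-log_alpha)
    ll = 0.0
    for g in np.unique(groups):
        C = counts[:, groups == g]
        R = C.shape[1]
        z = C.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(C + theta))
            - C.shape[0] * R * special.gammaln(theta)
            + np.sum(special.gammaln(R * theta) - special.gammaln(z + R * theta))
        )
    return ll


def estimate_dispersions(
    counts: np.ndarray,
    groups: np.ndarray | None = None,
    n_mean_bins: int = 50,
    ma_window: int = 5,
    floor: float = ALPHA_FLOOR,
    max_pixels_per_bin: int = 50_000,
    rng_seed: int = 0,
) -> DispersionEstimate:
    """Per-pixel NB dispersion by binned conditional ML with moving-average smoothing.

    Pixels are ranked by mean count and split into ~``n_mean_bins`` equal-size
    bins; a common dispersion is fit in each bin by maximizing the
    conditional likelihood (which eliminates the per-pixel mean), then the
    per-bin estimates are smoothed with a centered moving average over
    ``ma_window`` bins and assigned back to pixels.

    Requires at least two replicates per group.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    P, R = counts.shape
    if groups is None:
        groups = np.zeros(R, dtype=int)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        if np.sum(groups == g) < 2:
            raise ValueError("dispersion requires replicates")
    mean = counts.mean(axis=1)
    order = np.argsort(mean, kind="stable")
    n_bins = max(1, min(n_mean_bins, P // 2 if P >= 2 else 1))
    bin_edges = np.linspace(0, P, n_bins + 1).astype(int)
    rng = np.random.default_rng(rng_seed)
    per_bin = np.empty(n_bins)
    for b in range(n_bins):
        idx = order[bin_edges[b] : bin_edges[b + 1]]
        if idx.size > max_pixels_per_bin:
            idx = rng.choice(idx, max_pixels_per_bin, replace=False)
        sub = counts[idx]
        res = optimize.minimize_scalar(
            lambda la: -_cml_loglik(la, sub, groups),
            bounds=(np.log(1e-8), np.log(30.0)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        per_bin[b] = np.exp(res.x)
    # moving-average smoothing across mean-ordered bins
    half = ma_window // 2
    smoothed = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = max(0, b - half), min(n_bins, b + half + 1)
        smoothed[b] = per_bin[lo:hi].mean()
    alpha = np.empty(P)
    for b in range(n_bins):
        alpha[order[bin_edges[b] : bin_edges[b + 1]]] = smoothed[b]
    alpha = np.maximum(alpha, floor)
    return DispersionEstimate(
        alpha=alpha,
        descriptor=f"binned-CML(bins={n_bins}, ma={ma_window})",
    )


# ---------------------------------------------------------------------------
# Interaction testing
# ---------------------------------------------------------------------------


def _interaction_table(c_prime, s_prime, alpha, i_idx, j_idx, one_sided=True):
    beta, se = nb_fit_intercept(c_prime, np.log(s_prime), alpha)
    z = beta / se
    if one_sided:
        p = stats.norm.sf(z)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    fc = c_prime.sum(axis=1) / s_prime.sum(axis=1)
    return pd.DataFrame(
        {
            "i": i_idx,
            "j": j_idx,
            "beta": beta,
            "se": se,
            "wald_p": p,
            "fold_change": fc,
        }
    )


def test_interactions(
    aggregates,
    dispersions: DispersionEstimate,
    fdr: float = 0.20,
    fc: float = 1.5,
) -> pd.DataFrame:
    """One-sided Wald test (H0: beta <= 0) on a collection of aggregates.

    BH adjustment is pooled over all tested pixels with no independent
    filtering; a call is significant when adjusted p < ``fdr`` and fold
    change > ``fc``.
    """
    aggs = list(aggregates)
    if not aggs:
        return pd.DataFrame(
            columns=["i", "j", "beta", "se", "wald_p", "adj_p", "fold_change", "significant"]
        )
    C = np.stack([a.c_prime for a in aggs])
    S = np.stack([a.s_prime for a in aggs])
    if np.any(S <= 0):
        raise UntestablePixel("aggregate with non-positive expected count")
    alpha = np.atleast_1d(np.asarray(dispersions.alpha, dtype=float))
    if alpha.size == 1:
        alpha = np.full(len(aggs), alpha[0])
    df = _interaction_table(
        C, S, alpha, [a.center[0] for a in aggs], [a.center[1] for a in aggs]
    )
    df["adj_p"] = multipletests(df["wald_p"], method="fdr_bh")[1]
    df["significant"] = (df["adj_p"] < fdr) & (df["fold_change"] > fc)
    return df


def call_interactions(
    raw_maps: list[ContactMatrix],
    models: list[ExpectedModel],
    max_distance: int = 2_000_000,
    min_support: int = 1,
    fdr: float = 0.20,
    fc: float = 1.5,
    dispersions: DispersionEstimate | None = None,
) -> pd.DataFrame:
    """Genome-scale interaction calling over all testable pixels of one condition.

    ``raw_maps`` are the biological replicates of one condition,
    ``models`` the matching per-replicate expected models.  Pixels are
    prefiltered to raw count >= ``min_support`` in every replicate (putative
    interactions) and to genomic distance <= ``max_distance``; the 3x3
    aggregate test of :func:`test_interactions` is then applied.  When
    ``dispersions`` is None they are estimated from the aggregates.
    """
    if len(raw_maps) < 2:
        raise ValueError("interaction calling requires >= 2 replicates")
    if len(models) != len(raw_maps):
        raise ValueError("one expected model per replicate required")
    n = raw_maps[0].n_bins
    Dmax = max_distance // raw_maps[0].bin_size
    raw_bands = np.stack([m.band(Dmax + 1) for m in raw_maps])
    exp_bands = np.stack([em.expected_band(Dmax + 1) for em in models])
    Cp = np.stack([neighborhood_sum(rb) for rb in raw_bands])[:, :, : Dmax + 1]
    Sp = np.stack([neighborhood_sum(eb) for eb in exp_bands])[:, :, : Dmax + 1]
    support = np.min(raw_bands[:, :, : Dmax + 1], axis=0) >= min_support
    testable = (
        support
        & np.all(np.isfinite(Cp), axis=0)
        & np.all(np.isfinite(Sp), axis=0)
        & np.all(Sp > 0, axis=0)
    )
    ii, dd = np.nonzero(testable)
    if ii.size == 0:
        return pd.DataFrame(
            columns=["i", "j", "beta", "se", "wald_p", "adj_p", "fold_change", "significant"]
        )
    C = Cp[:, ii, dd].T  # (P, R)
    S = Sp[:, ii, dd].T
    if dispersions is None:
        dispersions = estimate_dispersions(C)
    df = _interaction_table(C, S, dispersions.alpha, ii, ii + dd)
    df["adj_p"] = multipletests(df["wald_p"], method="fdr_bh")[1]
    df["significant"] = (df["adj_p"] < fdr) & (df["fold_change"] > fc)
    return df


# ---------------------------------------------------------------------------
# Loop detection
# ---------------------------------------------------------------------------


def _local_background_ok(
    nband, rawband, sband, i, d, ratio, p_local, r_in=2, r_out=5,
    donut_ratio=None,
):
    """Focal-enrichment filter against four local background regions.

    The center pixel must exceed ``ratio`` times the normalized mean of the
    horizontal/vertical stripes and ``donut_ratio`` (default 1.75, the
    focal-loop-caller convention) times the donut (Chebyshev radii
    ``r_in``..``r_out``) and lower-left quadrant means, all
    diagonal-truncated.  In addition its raw count must clear a Poisson
    upper tail at ``p_local`` against each region-rescaled local expected
    lambda_f = S_center * (sum_f raw / sum_f S).  Rescaling by the
    observed/expected ratio of the surrounding region makes the test robust
    to smooth position-dependent error in the expected field.
    """
    if donut_ratio is None:
        donut_ratio = max(1.75, ratio)
    n, D = nband.shape
    center = nband[i, d]
    if not np.isfinite(center):
        return False
    raw_c = rawband[i, d]
    s_c = sband[i, d]
    if not (np.isfinite(raw_c) and np.isfinite(s_c) and s_c > 0):
        return False
    vals = {k: [] for k in ("donut", "ll", "h", "v")}
    raw_sum = dict.fromkeys(vals, 0.0)
    s_sum = dict.fromkeys(vals, 0.0)
    for di in range(-r_out, r_out + 1):
        for dj in range(-r_out, r_out + 1):
            cheb = max(abs(di), abs(dj))
            ii, dd2 = i + di, d + dj - di
            if not (0 <= ii < n and 1 <= dd2 < D):
                continue
            v = nband[ii, dd2]
            rw = rawband[ii, dd2]
            sv = sband[ii, dd2]
            if not (np.isfinite(v) and np.isfinite(rw) and np.isfinite(sv)):
                continue
            members = []
            if r_in <= cheb <= r_out:
                members.append("donut")
                if di == 0:
                    members.append("h")
                if dj == 0:
                    members.append("v")
            if 1 <= di <= r_out and -r_out <= dj <= -1:
                members.append("ll")
            for k in members:
                vals[k].append(v)
                raw_sum[k] += rw
                s_sum[k] += sv
    for k in vals:
        if not vals[k]:
            continue
        r_k = donut_ratio if k in ("donut", "ll") else ratio
        if center <= r_k * float(np.mean(vals[k])):
            return False
        if s_sum[k] > 0:
            lam = s_c * max(raw_sum[k] / s_sum[k], 1e-12)
            if raw_c <= r_k * lam:
                return False
            if stats.poisson.sf(raw_c - 1, lam) >= p_local:
                return False
    return True


def _cluster_pixels(pixels):
    """8-connectivity clustering via union-find on a sparse pixel set."""
    parent = {p: p for p in pixels}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    pixset = set(pixels)
    for (i, j) in pixels:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                q = (i + di, j + dj)
                if q in pixset and q != (i, j):
                    ra, rb = find((i, j)), find(q)
                    if ra != rb:
                        parent[ra] = rb
    clusters = {}
    for p in pixels:
        clusters.setdefault(find(p), []).append(p)
    return list(clusters.values())


def detect_loops(
    calls: pd.DataFrame,
    normalized: NormalizedMatrix,
    min_separation: int = 120_000,
    anchor_extension: int = 10_000,
    background_ratio: float = 1.5,
    background_p: float = 1e-3,
    min_cluster_size: int = 2,
    singleton_p: float = 1e-10,
    condition_of_discovery: str = "",
) -> list[LoopRecord]:
    """Distill loop records from significant interaction calls.

    Significant pixels must additionally pass the local-background
    enrichment filter of :func:`_local_background_ok` (donut, lower-left
    quadrant, horizontal and vertical stripes, each by ``background_ratio``
    with a Poisson tail at ``background_p``) evaluated on the supplied
    (typically replicate-pooled) normalized matrix.  Survivors are clustered
    with 8-connectivity; one record is emitted per cluster, with anchors
    spanning the constituent bins extended by ``anchor_extension`` on both
    sides.  Clusters whose anchor midpoints are closer than
    ``min_separation`` are dropped; records whose anchors occupy consecutive
    bins of another record's anchors are merged and counted as a single
    instance.  Clusters smaller than ``min_cluster_size`` are kept only when
    their best p-value falls below ``singleton_p`` — genuine focal loops
    enrich a whole 3x3 footprint and rarely surface as isolated pixels,
    whereas count noise does.
    """
    sig = calls[calls.get("significant", pd.Series(dtype=bool))] if len(calls) else calls
    if len(sig) == 0:
        return []
    bs = normalized.bin_size
    Dmax = int((sig["j"] - sig["i"]).max()) + 7
    nband = normalized.band(Dmax)
    from .contact import fit_expected  # local import to avoid a cycle

    model = fit_expected(normalized)
    sband = model.expected_band(Dmax)
    bvals = normalized.bias.values
    rawband = nband.copy()
    for dcol in range(rawband.shape[1]):
        upto = normalized.n_bins - dcol
        rawband[:upto, dcol] *= bvals[:upto] * bvals[dcol:]
    pvals = {}
    retained = []
    for _, row in sig.iterrows():
        i, j = int(row["i"]), int(row["j"])
        if _local_background_ok(
            nband, rawband, sband, i, j - i, background_ratio, background_p
        ):
            retained.append((i, j))
            pvals[(i, j)] = float(row["wald_p"])
    if not retained:
        return []
    records = []
    for cluster in _cluster_pixels(retained):
        i_bins = [p[0] for p in cluster]
        j_bins = [p[1] for p in cluster]
        rec = LoopRecord(
            chromosome=normalized.chromosome,
            anchor5=(min(i_bins) * bs - anchor_extension, (max(i_bins) + 1) * bs + anchor_extension),
            anchor3=(min(j_bins) * bs - anchor_extension, (max(j_bins) + 1) * bs + anchor_extension),
            pixel_cluster=frozenset(cluster),
            condition_of_discovery=condition_of_discovery,
            best_p=min(pvals[p] for p in cluster),
        )
        if rec.midpoint_separation() < min_separation:
            continue
        if len(cluster) < min_cluster_size and rec.best_p >= singleton_p:
            continue
        records.append(rec)
    return _merge_adjacent_loops(records)


def _anchors_adjacent(a: LoopRecord, b: LoopRecord) -> bool:
    """True when both anchor bin spans overlap or sit on consecutive bins."""
    for axis in (0, 1):
        lo_a = min(p[axis] for p in a.pixel_cluster)
        hi_a = max(p[axis] for p in a.pixel_cluster)
        lo_b = min(p[axis] for p in b.pixel_cluster)
        hi_b = max(p[axis] for p in b.pixel_cluster)
        if lo_a > hi_b + 1 or lo_b > hi_a + 1:
            return False
    return True


def _merge_adjacent_loops(records: list[LoopRecord]) -> list[LoopRecord]:
    if not records:
        return []
    parent = list(range(len(records)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            if _anchors_adjacent(records[a], records[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for k in range(len(records)):
        groups.setdefault(find(k), []).append(records[k])
    merged = []
    for recs in groups.values():
        if len(recs) == 1:
            merged.append(recs[0])
            continue
        merged.append(
            LoopRecord(
                chromosome=recs[0].chromosome,
                anchor5=(min(r.anchor5[0] for r in recs), max(r.anchor5[1] for r in recs)),
                anchor3=(min(r.anchor3[0] for r in recs), max(r.anchor3[1] for r in recs)),
                pixel_cluster=frozenset().union(*[r.pixel_cluster for r in recs]),
                condition_of_discovery=recs[0].condition_of_discovery,
                best_p=min(r.best_p for r in recs),
            )
        )
    return merged


def call_loops(
    raw_maps: list[ContactMatrix],
    max_distance: int = 2_000_000,
    min_support: int = 1,
    fdr: float = 0.20,
    fc: float = 1.5,
    min_separation: int = 120_000,
    condition_of_discovery: str = "",
) -> tuple[list[LoopRecord], pd.DataFrame]:
    """End-to-end loop calling for one condition's replicates.

    Normalizes each replicate, fits per-replicate expected models, tests
    interactions, and distills loops against the replicate-pooled normalized
    matrix.  Returns (loop records, interaction-call table).
    """
    from .contact import fit_expected, ipf_normalize, pool_replicates

    models = [fit_expected(ipf_normalize(m)[1]) for m in raw_maps]
    calls = call_interactions(
        raw_maps, models, max_distance=max_distance, min_support=min_support,
        fdr=fdr, fc=fc,
    )
    _, pooled_n = ipf_normalize(pool_replicates(raw_maps))
    records = detect_loops(
        calls,
        pooled_n,
        min_separation=min_separation,
        condition_of_discovery=condition_of_discovery,
    )
    return records, calls


# ---------------------------------------------------------------------------
# Differential loop strength
# ---------------------------------------------------------------------------


def _loop_areas(loops: list[LoopRecord]):
    """3x3 interaction areas per loop, merged when they overlap."""
    areas = []
    for rec in loops:
        pix = set()
        for (i, j) in rec.pixel_cluster:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    pix.add((i + di, j + dj))
        areas.append(pix)
    parent = list(range(len(areas)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(areas)):
        for b in range(a + 1, len(areas)):
            if areas[a] & areas[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for k in range(len(areas)):
        groups.setdefault(find(k), set()).update(areas[k])
    members = {}
    for k in range(len(areas)):
        members.setdefault(find(k), []).append(k)
    roots = sorted(groups)
    return [sorted(groups[r]) for r in roots], [members[r] for r in roots]


def test_differential_loops(
    loops: list[LoopRecord],
    raw_maps: dict,
    models: dict,
    fdr: float = 0.1,
    fc: float = 1.5,
    common_fc: float = 1.25,
    dispersions: DispersionEstimate | None = None,
) -> pd.DataFrame:
    """Two-sided Wald test of loop-strength change between two conditions.

    ``raw_maps`` and ``models`` map each condition label to its per-replicate
    :class:`ContactMatrix` / :class:`ExpectedModel` lists.  For every loop in
    the union, counts and expected counts are aggregated over its 3x3
    interaction area per sample; overlapping areas are merged before testing.
    The log2 fold-change coefficient gamma (condition 2 over condition 1)
    comes from per-condition intercept-only NB fits with per-sample offsets;
    with a saturated per-condition mean this equals the full two-parameter ML
    fit, and the Wald variance is the sum of the per-condition inverses of
    the observed information.

    Classification: induced (adj_p < fdr and 2^gamma > fc), reduced
    (symmetric), common (2^|gamma| < common_fc), else indeterminate.
    """
    conds = sorted(raw_maps)
    if len(conds) != 2:
        raise ValueError("exactly two conditions required")
    reps = {c: len(raw_maps[c]) for c in conds}
    if len(set(reps.values())) != 1:
        raise ValueError("replicate count mismatch between conditions")
    if not loops:
        return pd.DataFrame(
            columns=["area_id", "gamma", "wald_p", "adj_p", "class", "loop_members"]
        )
    areas, members = _loop_areas(loops)
    n_area = len(areas)
    Cs, Ss, labels = [], [], []
    for c in conds:
        for m, em in zip(raw_maps[c], models[c]):
            ent = {(r, cc): v for r, cc, v in zip(m.rows, m.cols, m.vals)}
            bias = em.bias.values
            cvec = np.zeros(n_area)
            svec = np.zeros(n_area)
            for a, pix in enumerate(areas):
                for (i, j) in pix:
                    if 0 <= i <= j < m.n_bins and j - i < em.decay.size:
                        bi, bj = bias[i], bias[j]
                        if np.isnan(bi) or np.isnan(bj):
                            continue
                        cvec[a] += ent.get((i, j), 0)
                        svec[a] += bi * bj * em.decay[j - i]
            Cs.append(cvec)
            Ss.append(svec)
            labels.append(c)
    C = np.stack(Cs, axis=1)  # (areas, samples)
    S = np.stack(Ss, axis=1)
    labels = np.asarray(labels)
    ok = np.all(S > 0, axis=1)
    if dispersions is None:
        dispersions = estimate_dispersions(C[ok], groups=labels)
    alpha = np.full(n_area, np.nan)
    alpha[ok] = dispersions.alpha
    g1, g2 = labels == conds[0], labels == conds[1]
    b1, se1 = nb_fit_intercept(C[ok][:, g1], np.log(S[ok][:, g1]), alpha[ok])
    b2, se2 = nb_fit_intercept(C[ok][:, g2], np.log(S[ok][:, g2]), alpha[ok])
    gamma = (b2 - b1) / np.log(2.0)
    se = np.sqrt(se1**2 + se2**2) / np.log(2.0)
    z = gamma / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    adj = multipletests(p, method="fdr_bh")[1]
    cls = np.where(
        (adj < fdr) & (2.0**gamma > fc),
        "induced",
        np.where(
            (adj < fdr) & (2.0**-gamma > fc),
            "reduced",
            np.where(2.0 ** np.abs(gamma) < common_fc, "common", "indeterminate"),
        ),
    )
    out = pd.DataFrame(
        {
            "area_id": np.flatnonzero(ok),
            "gamma": gamma,
            "se": se,
            "wald_p": p,
            "adj_p": adj,
            "class": cls,
        }
    )
    out["loop_members"] = [members[a] for a in out["area_id"]]
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def loops_to_bedpe(records: list[LoopRecord], path) -> None:
    """Write loop records as BEDPE (chrom1 start1 end1 chrom2 start2 end2 name score)."""
    rows = []
    for k, r in enumerate(records):
        rows.append(
            (
                r.chromosome,
                max(0, r.anchor5[0]),
                r.anchor5[1],
                r.chromosome,
                max(0, r.anchor3[0]),
                r.anchor3[1],
                f"loop_{k}",
                r.best_p,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
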