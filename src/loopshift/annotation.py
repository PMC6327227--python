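"""Peak/motif handling, regulatory-element classes, and loop-anchor annotation.

Interval conventions: all features are 0-based half-open; overlap means
any-bp intersection; strand is ignored for overlap tests.

Element classes follow standard chromatin-mark logic: promoters are +/-100 bp
windows around TSS, active when marked by H3K4me3; putative enhancers are
H3K4me1 peaks that overlap neither an H3K4me3 peak nor a promoter window,
active when overlapping H3K27ac and otherwise poised.  Induced enhancers are
active in condition 2 but overlap no condition-1 active enhancer (repressed:
symmetric).

Differential occupancy of point factors (CTCF, Rad21) between conditions uses
median-of-ratios size factors and the same negative-binomial Wald machinery as
loop testing, with the per-sample log size factor as offset.  A peak is
"gained" when adjusted p < 0.1 and the normalized condition-2/condition-1
ratio exceeds 1.

Tile profiles rescale loop domains to a common axis: each domain is divided
into 250 core tiles (tile size TS = domain length / 250) with 10 TS-sized
flanking tiles appended on each side (270 total); the profile reports, per
tile, the fraction of domains with at least one overlapping feature of a
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contact import NormalizedMatrix
from .loops import LoopRecord, estimate_dispersions, nb_fit_intercept

__all__ = [
    "GenomicFeature",
    "classify_regulatory_elements",
    "induced_enhancers",
    "assign_motifs",
    "differential_occupancy",
    "loop_domain_tile_profile",
    "pei_contact_dynamics",
    "anchor_feature_overlap",
    "fisher_2x2",
]


@dataclass
class GenomicFeature:
    chrom: str
    start: int
    end: int
    kind: str = "peak"  # peak | motif | TSS | enhancer | promoter
    orientation: str = "none"  # forward | reverse | none
    score: float = np.nan

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("feature end must exceed start")


def _trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    out: dict[str, IntervalTree] = {}
    for chrom, grp in df.groupby("chrom"):
        out[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    return out


def _overlaps_any(df: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per row of ``df``: any-bp intersection with ``subject``."""
    trees = _trees(subject)
    out = np.zeros(len(df), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        t = trees.get(chrom)
        out[k] = bool(t.overlap(int(s), int(e))) if t is not None else False
    return out


# ---------------------------------------------------------------------------
# Regulatory-element classification
# ---------------------------------------------------------------------------


def classify_regulatory_elements(
    k4me1: pd.DataFrame,
    k4me3: pd.DataFrame,
    k27ac: pd.DataFrame,
    tss: pd.DataFrame,
    promoter_half: int = 100,
) -> dict[str, pd.DataFrame]:
    """Promoter and enhancer classes from histone-mark peaks and TSS.

    Returns dict with ``promoters`` (columns chrom/start/end/active) and
    ``enhancers`` (chrom/start/end/status with status in {active, poised}).
    """
    promoters = pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": tss["pos"] - promoter_half,
            "end": tss["pos"] + promoter_half,
        }
    )
    promoters["active"] = (
        _overlaps_any(promoters, k4me3) if len(promoters) else np.array([], bool)
    )
    enh = k4me1[["chrom", "start", "end"]].copy().reset_index(drop=True)
    if len(enh):
        excl = _overlaps_any(enh, k4me3)
        if len(promoters):
            excl |= _overlaps_any(enh, promoters)
        enh = enh[~excl].reset_index(drop=True)
    enh["status"] = ""
    if len(enh):
        active = _overlaps_any(enh, k27ac)
        enh["status"] = np.where(active, "active", "poised")
    return {"promoters": promoters, "enhancers": enh}


def induced_enhancers(
    active_cond2: pd.DataFrame, active_cond1: pd.DataFrame
) -> pd.DataFrame:
    """Active-in-condition-2 enhancers overlapping no condition-1 active enhancer."""
    if not len(active_cond2):
        return active_cond2
    hit = (
        _overlaps_any(active_cond2, active_cond1)
        if len(active_cond1)
        else np.zeros(len(active_cond2), bool)
    )
    return active_cond2[~hit].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Motif orientation
# ---------------------------------------------------------------------------


def assign_motifs(
    peaks: pd.DataFrame, motif_hits: pd.DataFrame, p_max: float = 1e-4
) -> pd.DataFrame:
    """Orient peaks by their best motif hit (lowest p strictly below ``p_max``).

    Ties on p are broken by leftmost hit; peaks with no surviving hit get
    orientation "none".  Returns a copy of ``peaks`` with an ``orientation``
    column (forward / reverse / none).
    """
    out = peaks.copy().reset_index(drop=True)
    out["orientation"] = "none"
    hits = motif_hits[motif_hits["p"] < p_max]
    if not len(hits):
        return out
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in hits.groupby("chrom"):
        trees[chrom] = IntervalTree()
        for idx, row in grp.iterrows():
            trees[chrom].addi(int(row["start"]), int(row["end"]), idx)
    for k, (chrom, s, e) in enumerate(zip(out["chrom"], out["start"], out["end"])):
        t = trees.get(chrom)
        if t is None:
            continue
        found = t.overlap(int(s), int(e))
        if not found:
            continue
        cand = hits.loc[[iv.data for iv in found]]
        best = cand.sort_values(["p", "start"], kind="stable").iloc[0]
        out.loc[k, "orientation"] = "forward" if best["strand"] == "+" else "reverse"
    return out


# ---------------------------------------------------------------------------
# Differential occupancy
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style size factors: median of per-row ratios to the geometric mean."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    ref = logc.mean(axis=1)
    finite = np.isfinite(ref)
    if not np.any(finite):
        raise ValueError("no feature with nonzero counts in every sample")
    return np.exp(np.median(logc[finite] - ref[finite, None], axis=0))


def differential_occupancy(
    counts: pd.DataFrame | np.ndarray,
    conditions: np.ndarray,
    padj_max: float = 0.1,
    fc_min: float = 1.0,
) -> pd.DataFrame:
    """Per-peak NB Wald test of occupancy change between two conditions.

    ``counts`` is peaks x samples; ``conditions`` labels each sample column
    (exactly two levels, >= 2 replicates each).  Size factors are estimated
    by median-of-ratios and enter as offsets; dispersions by binned
    conditional ML on size-factor-scaled counts.  Status: gained when
    adj_p < ``padj_max`` and fold change (condition2/condition1,
    normalized) > ``fc_min``; lost symmetric; otherwise unchanged.  Peaks
    with zero total count are untested (status unchanged, NaN p).
    """
    C = np.asarray(counts, dtype=float)
    conditions = np.asarray(conditions)
    levels = pd.unique(conditions)
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    for lv in levels:
        if np.sum(conditions == lv) < 2:
            raise ValueError("at least two replicates per condition required")
    sf = median_of_ratios_size_factors(C)
    tested = C.sum(axis=1) > 0
    Ct = C[tested]
    disp = estimate_dispersions(Ct / sf, groups=conditions)
    g1, g2 = conditions == levels[0], conditions == levels[1]
    off1 = np.broadcast_to(np.log(sf[g1]), Ct[:, g1].shape)
    off2 = np.broadcast_to(np.log(sf[g2]), Ct[:, g2].shape)
    b1, se1 = nb_fit_intercept(Ct[:, g1], off1, disp.alpha)
    b2, se2 = nb_fit_intercept(Ct[:, g2], off2, disp.alpha)
    lfc = (b2 - b1) / np.log(2.0)
    se = np.sqrt(se1**2 + se2**2) / np.log(2.0)
    p = 2.0 * stats.norm.sf(np.abs(lfc / se))
    adj = multipletests(p, method="fdr_bh")[1]
    n = C.shape[0]
    out = pd.DataFrame(
        {
            "log2_fold_change": np.full(n, np.nan),
            "wald_p": np.full(n, np.nan),
            "adj_p": np.full(n, np.nan),
            "status": np.full(n, "unchanged", dtype=object),
        }
    )
    out.loc[tested, "log2_fold_change"] = lfc
    out.loc[tested, "wald_p"] = p
    out.loc[tested, "adj_p"] = adj
    gained = (adj < padj_max) & (2.0**lfc > fc_min)
    lost = (adj < padj_max) & (2.0**-lfc > fc_min)
    status = np.where(gained, "gained", np.where(lost, "lost", "unchanged"))
    out.loc[tested, "status"] = status
    return out


# ---------------------------------------------------------------------------
# Tile profiles
# ---------------------------------------------------------------------------


def loop_domain_tile_profile(
    domains,
    features: pd.DataFrame,
    n_core: int = 250,
    n_flank: int = 10,
) -> np.ndarray:
    """Fraction of domains with a feature per rescaled tile (270 values).

    ``domains`` is an iterable of (chrom, start, end).  Each domain is cut
    into ``n_core`` equal tiles of size TS = length / n_core, with
    ``n_flank`` TS-sized tiles appended before the start and after the end.
    """
    domains = list(domains)
    if not domains:
        raise ValueError("no domains supplied")
    total = n_core + 2 * n_flank
    trees = _trees(features)
    hit = np.zeros(total)
    n_used = 0
    for chrom, start, end in domains:
        length = end - start
        if length <= 0:
            raise ValueError("zero-length domain")
        if length < n_core:
            continue
        ts = length / n_core
        t = trees.get(chrom)
        n_used += 1
        if t is None:
            continue
        for k in range(total):
            lo = start + (k - n_flank) * ts
            hi = lo + ts
            if t.overlap(lo, hi):
                hit[k] += 1
    if n_used == 0:
        raise ValueError("no domain long enough to tile")
    return hit / n_used


# ---------------------------------------------------------------------------
# Intra-domain promoter-enhancer contact dynamics
# ---------------------------------------------------------------------------


def pei_contact_dynamics(
    loop_domains,
    promoters: pd.DataFrame,
    enhancers: pd.DataFrame,
    matrix_cond1: NormalizedMatrix,
    matrix_cond2: NormalizedMatrix,
    trim: int = 20_000,
    min_span: int = 20_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-domain mean ratio of promoter-enhancer contacts, condition2/condition1.

    Domain coordinates are trimmed ``trim`` inward (removing the anchors from
    consideration); bin pairs at the matrices' resolution spanning an active
    promoter and an active enhancer, separated by >= ``min_span``, qualify.
    Pairs with zero contact in condition 1 have an undefined ratio and are
    dropped; domains with no qualifying pair are omitted.

    Returns (pair-level records, per-domain mean ratios).
    """
    bs = matrix_cond1.bin_size
    if matrix_cond2.bin_size != bs:
        raise ValueError("matrices must share a bin size")
    n = matrix_cond1.n_bins
    d1 = dict(zip(zip(matrix_cond1.rows, matrix_cond1.cols), matrix_cond1.vals))
    d2 = dict(zip(zip(matrix_cond2.rows, matrix_cond2.cols), matrix_cond2.vals))

    def bins_hitting(df, lo, hi):
        out = set()
        for s, e in zip(df["start"], df["end"]):
            if e <= lo or s >= hi:
                continue
            for b in range(max(int(s), lo) // bs, (min(int(e), hi) - 1) // bs + 1):
                out.add(b)
        return out

    pair_rows = []
    dom_rows = []
    for did, dom in enumerate(loop_domains):
        chrom, start, end = dom
        lo, hi = start + trim, end - trim
        if hi <= lo:
            continue
        pbins = bins_hitting(promoters[promoters["chrom"] == chrom], lo, hi)
        ebins = bins_hitting(enhancers[enhancers["chrom"] == chrom], lo, hi)
        ratios = []
        for pb in sorted(pbins):
            for eb in sorted(ebins):
                if pb == eb or abs(pb - eb) * bs < min_span:
                    continue
                i, j = min(pb, eb), max(pb, eb)
                if not (0 <= i and j < n):
                    continue
                v1 = float(d1.get((i, j), 0.0))
                v2 = float(d2.get((i, j), 0.0))
                if v1 <= 0:
                    continue
                r = v2 / v1
                ratios.append(r)
                pair_rows.append((did, i, j, v1, v2, r))
        if ratios:
            dom_rows.append((did, float(np.mean(ratios)), len(ratios)))
    pairs = pd.DataFrame(
        pair_rows,
        columns=["domain_id", "promoter_bin", "enhancer_bin", "n1", "n2", "ratio"],
    )
    per_domain = pd.DataFrame(dom_rows, columns=["domain_id", "mean_ratio", "n_pairs"])
    return pairs, per_domain


# ---------------------------------------------------------------------------
# Anchor / peak overlap summaries
# ---------------------------------------------------------------------------


def anchor_feature_overlap(
    loops: list[LoopRecord],
    peaks: pd.DataFrame,
    mode: str = "anchor",
    extension: int | None = None,
) -> dict:
    """Fractions of loops with peaks at both, one, or neither anchor.

    ``mode="anchor"`` extends each whole anchor interval by ``extension``
    (default 10 kb) on both sides; ``mode="midpoint"`` uses the anchor
    midpoint +/- ``extension`` (default 5 kb).  Also reports the subset of
    loops with exactly one peak per anchor.
    """
    if mode not in ("anchor", "midpoint"):
        raise ValueError("mode must be 'anchor' or 'midpoint'")
    if extension is None:
        extension = 10_000 if mode == "anchor" else 5_000
    trees = _trees(peaks)
    rows = []
    for k, lp in enumerate(loops):
        t = trees.get(lp.chromosome, IntervalTree())
        counts = []
        for anchor in (lp.anchor5, lp.anchor3):
            if mode == "anchor":
                lo, hi = anchor[0] - extension, anchor[1] + extension
            else:
                mid = (anchor[0] + anchor[1]) // 2
                lo, hi = mid - extension, mid + extension
            counts.append(len(t.overlap(lo, hi)))
        rows.append((k, counts[0], counts[1]))
    per_loop = pd.DataFrame(rows, columns=["loop", "n_peaks_5p", "n_peaks_3p"])
    has5 = per_loop["n_peaks_5p"] > 0
    has3 = per_loop["n_peaks_3p"] > 0
    n = max(len(loops), 1)
    single = (per_loop["n_peaks_5p"] == 1) & (per_loop["n_peaks_3p"] == 1)
    return {
        "per_loop": per_loop,
        "n_loops": len(loops),
        "fraction_both": float((has5 & has3).sum()) / n,
        "fraction_one": float((has5 ^ has3).sum()) / n,
        "fraction_none": float((~has5 & ~has3).sum()) / n,
        "fraction_single_peak_per_anchor": float(single.sum()) / n,
    }


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided"):
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]] -> (odds_ratio, p)."""
    return stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
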