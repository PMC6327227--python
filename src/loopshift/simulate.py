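"""Seeded generators with planted ground truth for every pipeline stage.

The contact-map generator emulates the statistical structure of binned
chromosome-conformation count data: a power-law distance decay, multiplicative
per-bin visibility biases, block-enriched contact domains, a checkerboard
compartment pattern, focal loops enriched over a 3x3 pixel footprint, and
negative-binomial replicate noise (Var = mu + alpha * mu^2, the single
parameterization used throughout this package).  Condition effects are
multiplicative factors applied to selected loop footprints in the second
condition, mimicking loop induction upon differentiation.

The annotation generator places CTCF peaks at planted loop anchors with
convergent (inward-facing) motifs — forward motifs at 5' anchors, reverse at
3' anchors — plus uniform background peaks, and emits histone-mark tracks with
configurable co-occurrence to drive enhancer/promoter classification.

The localization generator emulates single-molecule localization data of
replication foci: cluster centers uniform in the field, events Gaussian around
centers, photon counts log-normal.

Every generator is a pure function of its arguments and the seed.  What these
simulations do NOT emulate: polymer physics, translocations, copy-number
variation, sequencing-read-level artifacts, or localization drift.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactMatrix

__all__ = [
    "SimulationTruth",
    "simulate_contact_maps",
    "simulate_annotations",
    "simulate_localizations",
    "nb_sample",
]


@dataclass
class SimulationTruth:
    """Planted ground truth; fully determines the generated data given the seed."""

    seed: int
    bias: np.ndarray | None = None
    decay_scale: float | None = None
    decay_exponent: float | None = None
    domains: list = field(default_factory=list)  # (start_bin, end_bin, factor)
    compartment_labels: np.ndarray | None = None  # +1 (A-like) / -1 per bin
    compartment_factor: float | None = None
    loops: list = field(default_factory=list)  # (i, j, enrichment)
    loop_condition_factors: list = field(default_factory=list)
    nb_dispersion: float | None = None
    gained_peaks: list = field(default_factory=list)  # indices into peak table
    cluster_centers: np.ndarray | None = None  # (m, 2) nm

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        d = {k: conv(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Draw negative-binomial counts with Var = mu + alpha * mu^2 (gamma-Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


def _place_loops(rng, n_bins, n_loops, enrichment, min_dist, max_dist, margin=3):
    """Random focal-loop centers, pairwise separated so 3x3 footprints are disjoint."""
    loops = []
    attempts = 0
    while len(loops) < n_loops:
        attempts += 1
        if attempts > 200 * n_loops:
            raise ValueError("could not place requested loops; matrix too small")
        d = int(rng.integers(min_dist, max_dist + 1))
        i = int(rng.integers(margin, n_bins - d - margin))
        j = i + d
        if all(max(abs(i - a), abs(j - b)) >= 6 for a, b, _ in loops):
            loops.append((i, j, float(enrichment)))
    return sorted(loops)


def simulate_contact_maps(
    n_bins: int = 2000,
    bin_size: int = 10_000,
    decay: tuple[float, float] = (400.0, 1.0),
    biases="lognormal",
    bias_sigma: float = 0.5,
    domains=None,
    compartments=None,
    loops=None,
    dispersion: float = 0.1,
    replicates: int = 2,
    conditions: int = 1,
    condition_loop_factor=None,
    max_dist: int | None = None,
    seed: int = 0,
    chromosome: str = "chrS",
):
    """Generate seeded contact matrices with planted structure.

    The mean count for a bin pair at distance r = j - i is

        mu_ij = b_i * b_j * c * (1 + r)^(-a) * domain * compartment * loop

    where (c, a) = ``decay`` (the ``1 + r`` form avoids the r = 0
    singularity), the domain factor applies when both bins fall in the same
    planted domain, the compartment factor applies when both bins carry the
    same checkerboard label, and each loop multiplies its 3x3 footprint by
    its enrichment factor.  Counts are drawn NB(mu, ``dispersion``)
    independently per replicate and condition; in condition 2 the footprints
    of selected loops are additionally multiplied by
    ``condition_loop_factor``.

    Parameters
    ----------
    biases
        ``"lognormal"`` (log-normal with sigma ``bias_sigma``, normalized to
        geometric mean 1), ``None`` (flat), or an explicit positive array.
    domains
        List of ``(start_bin, end_bin, factor)`` or ``{"n": k, "factor": f}``
        for k contiguous random-width domains.
    compartments
        ``{"period_bins": p, "factor": f}`` for alternating p-bin stripes.
    loops
        List of ``(i, j, enrichment)`` pixel centers, or
        ``{"n": k, "enrichment": f, "min_dist": bins, "max_dist": bins}``.
    condition_loop_factor
        Scalar applied to every planted loop, or a per-loop sequence
        (factor 1 = stable loop), in condition 2 only.

    Returns
    -------
    maps : dict mapping (condition_index, replicate_index) -> ContactMatrix
    truth : SimulationTruth
    """
    rng = np.random.default_rng(seed)
    if max_dist is None:
        max_dist = n_bins - 1
    D = max_dist + 1
    c, a = decay

    if biases is None:
        b = np.ones(n_bins)
    elif isinstance(biases, str) and biases == "lognormal":
        b = np.exp(rng.normal(0.0, bias_sigma, n_bins))
        b /= np.exp(np.mean(np.log(b)))
    else:
        b = np.asarray(biases, dtype=float)
        if b.size != n_bins or np.any(b <= 0):
            raise ValueError("explicit biases must be positive, length n_bins")

    if isinstance(domains, dict):
        k = domains["n"]
        f = domains.get("factor", 2.0)
        edges = np.sort(rng.choice(np.arange(5, n_bins - 5), size=k - 1, replace=False))
        edges = np.concatenate([[0], edges, [n_bins]])
        domains = [(int(s), int(e), float(f)) for s, e in zip(edges[:-1], edges[1:])]
    domains = list(domains or [])

    comp_labels = None
    comp_factor = None
    if compartments is not None:
        p = compartments["period_bins"]
        comp_factor = float(compartments.get("factor", 2.0))
        comp_labels = np.where((np.arange(n_bins) // p) % 2 == 0, 1, -1)

    if isinstance(loops, dict):
        loops = _place_loops(
            rng,
            n_bins,
            loops["n"],
            loops.get("enrichment", 3.0),
            loops.get("min_dist", 15),
            loops.get("max_dist", min(max_dist - 3, n_bins // 4)),
        )
    loops = [(int(i), int(j), float(e)) for i, j, e in (loops or [])]
    for i, j, _ in loops:
        if not (0 <= i - 1 and j + 1 < n_bins and j - i >= 3 and j - i + 1 < D):
            raise ValueError(f"loop ({i}, {j}) outside the simulated band")

    if condition_loop_factor is None:
        cond_factors = [1.0] * len(loops)
    elif np.isscalar(condition_loop_factor):
        cond_factors = [float(condition_loop_factor)] * len(loops)
    else:
        cond_factors = [float(x) for x in condition_loop_factor]
        if len(cond_factors) != len(loops):
            raise ValueError("condition_loop_factor length mismatch")

    # base mean band
    i_idx = np.arange(n_bins)[:, None]
    d_idx = np.arange(D)[None, :]
    j_idx = i_idx + d_idx
    valid = j_idx < n_bins
    j_clip = np.minimum(j_idx, n_bins - 1)
    mu = c * (1.0 + d_idx.astype(float)) ** (-a) * b[:, None] * b[j_clip]
    for s, e, f in domains:
        inside = (i_idx >= s) & (j_clip < e)
        mu = np.where(inside, mu * f, mu)
    if comp_labels is not None:
        same = comp_labels[:, None] == comp_labels[j_clip]
        mu = np.where(same, mu * comp_factor, mu)
    # band coords of matrix pixel (i+di, j+dj) are (i+di, d0 + dj - di)
    for i, j, e in loops:
        d0 = j - i
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                mu[i + di, d0 + dj - di] *= e
    mu = np.where(valid, mu, 0.0)

    maps = {}
    for cond in range(conditions):
        mu_c = mu.copy()
        if cond == 1:
            for (i, j, _), f in zip(loops, cond_factors):
                if f != 1.0:
                    d0 = j - i
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            mu_c[i + di, d0 + dj - di] *= f
        for rep in range(replicates):
            counts = nb_sample(rng, mu_c, dispersion)
            counts = np.where(valid, counts, 0)
            r, d = np.nonzero(counts)
            maps[(cond, rep)] = ContactMatrix(
                chromosome=chromosome,
                bin_size=bin_size,
                n_bins=n_bins,
                rows=r,
                cols=r + d,
                vals=counts[r, d],
                replicate_label=f"rep{rep + 1}",
                condition_label=f"cond{cond + 1}",
            )

    truth = SimulationTruth(
        seed=seed,
        bias=b,
        decay_scale=c,
        decay_exponent=a,
        domains=domains,
        compartment_labels=comp_labels,
        compartment_factor=comp_factor,
        loops=loops,
        loop_condition_factors=cond_factors,
        nb_dispersion=dispersion,
    )
    return maps, truth


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------


def simulate_annotations(
    truth: SimulationTruth,
    bin_size: int = 10_000,
    genome_length: int | None = None,
    chromosome: str = "chrS",
    peak_width: int = 400,
    background_peak_density: float = 1.0 / 50_000,
    inward_motifs: bool = True,
    gain_factor: float = 2.0,
    base_occupancy: float = 100.0,
    occupancy_dispersion: float = 0.05,
    replicates: int = 2,
    n_enhancers: int = 0,
    k27ac_cooccurrence: float = 0.5,
    n_tss: int = 0,
    k4me3_at_tss: float = 0.5,
    seed: int = 0,
):
    """Generate peak/motif/mark/TSS tracks tied to planted loop anchors.

    CTCF peaks are placed at the anchors of every planted loop (forward motif
    at the 5' anchor, reverse at the 3', when ``inward_motifs``) plus uniform
    background peaks with random orientation.  A per-peak count table over
    two conditions x ``replicates`` is drawn NB; peaks at anchors of loops
    whose planted condition factor exceeds 1 have condition-2 means inflated
    by ``gain_factor`` (these are the true "gained" peaks).

    Enhancer machinery: ``n_enhancers`` H3K4me1 peaks are placed uniformly;
    each overlaps an H3K27ac peak with probability ``k27ac_cooccurrence``
    (active enhancer) independently per condition.  ``n_tss`` TSS positions
    are placed uniformly; each overlaps an H3K4me3 peak with probability
    ``k4me3_at_tss``.

    Returns a dict of DataFrames (``ctcf_peaks``, ``motif_hits``,
    ``occupancy_counts``, ``k4me1``, ``k4me3``, ``k27ac_cond1``,
    ``k27ac_cond2``, ``tss``) and an updated copy of ``truth`` with the
    planted gained-peak indices.
    """
    if background_peak_density < 0:
        raise ValueError("background peak density must be non-negative")
    rng = np.random.default_rng(seed)
    if genome_length is None:
        if truth.bias is None:
            raise ValueError("genome_length required when truth has no matrix")
        genome_length = truth.bias.size * bin_size

    half = peak_width // 2
    starts, ends, strands, at_anchor, loop_idx, side = [], [], [], [], [], []
    for k, (i, j, _e) in enumerate(truth.loops):
        for anchor_bin, s in ((i, "+"), (j, "-")):
            mid = anchor_bin * bin_size + bin_size // 2
            starts.append(mid - half)
            ends.append(mid + half)
            strands.append(s if inward_motifs else rng.choice(["+", "-"]))
            at_anchor.append(True)
            loop_idx.append(k)
            side.append("5p" if s == "+" else "3p")
    n_bg = rng.poisson(background_peak_density * genome_length)
    for _ in range(n_bg):
        mid = int(rng.integers(half, genome_length - half))
        starts.append(mid - half)
        ends.append(mid + half)
        strands.append(str(rng.choice(["+", "-"])))
        at_anchor.append(False)
        loop_idx.append(-1)
        side.append("")
    peaks = pd.DataFrame(
        {
            "chrom": chromosome,
            "start": starts,
            "end": ends,
            "strand": strands,
            "at_anchor": at_anchor,
            "loop_index": loop_idx,
            "anchor_side": side,
        }
    )

    motif_hits = pd.DataFrame(
        {
            "chrom": chromosome,
            "start": peaks["start"] + half // 2,
            "end": peaks["start"] + half // 2 + 19,
            "strand": peaks["strand"],
            "p": 10.0 ** rng.uniform(-8, -5, len(peaks)),
        }
    )

    induced = {
        k for k, f in enumerate(truth.loop_condition_factors or []) if f > 1.0
    }
    gained_true = peaks["loop_index"].isin(induced) & peaks["at_anchor"]
    mu = np.full((len(peaks), 2 * replicates), base_occupancy)
    mu[gained_true.to_numpy(), replicates:] *= gain_factor
    counts = nb_sample(rng, mu, occupancy_dispersion)
    occupancy = pd.DataFrame(
        counts,
        columns=[f"cond1_rep{r + 1}" for r in range(replicates)]
        + [f"cond2_rep{r + 1}" for r in range(replicates)],
    )

    def _uniform_intervals(n, width):
        s = rng.integers(0, genome_length - width, n)
        return np.sort(s)

    enh_w = 1000
    k4me1_s = _uniform_intervals(n_enhancers, enh_w) if n_enhancers else np.array([], int)
    k4me1 = pd.DataFrame(
        {"chrom": chromosome, "start": k4me1_s, "end": k4me1_s + enh_w}
    )
    k27 = {}
    for cond in (1, 2):
        act = rng.random(n_enhancers) < k27ac_cooccurrence
        k27[cond] = pd.DataFrame(
            {
                "chrom": chromosome,
                "start": k4me1_s[act] + enh_w // 4,
                "end": k4me1_s[act] + 3 * enh_w // 4,
            }
        )
    tss_pos = (
        np.sort(rng.integers(1000, genome_length - 1000, n_tss))
        if n_tss
        else np.array([], int)
    )
    tss = pd.DataFrame(
        {
            "chrom": chromosome,
            "pos": tss_pos,
            "strand": rng.choice(["+", "-"], n_tss) if n_tss else [],
        }
    )
    has_k4me3 = rng.random(n_tss) < k4me3_at_tss if n_tss else np.array([], bool)
    k4me3 = pd.DataFrame(
        {
            "chrom": chromosome,
            "start": tss_pos[has_k4me3] - 300,
            "end": tss_pos[has_k4me3] + 300,
        }
    )

    out_truth = dataclasses.replace(
        truth, gained_peaks=list(np.flatnonzero(gained_true.to_numpy()))
    )
    tracks = {
        "ctcf_peaks": peaks,
        "motif_hits": motif_hits,
        "occupancy_counts": occupancy,
        "k4me1": k4me1,
        "k4me3": k4me3,
        "k27ac_cond1": k27[1],
        "k27ac_cond2": k27[2],
        "tss": tss,
    }
    return tracks, out_truth


# ---------------------------------------------------------------------------
# Localization events
# ---------------------------------------------------------------------------


def simulate_localizations(
    n_clusters: int = 100,
    cluster_sigma_nm: float = 20.0,
    events_per_cluster: int = 200,
    photon_median: float = 800.0,
    photon_sigma: float = 0.5,
    field_nm: float = 6400.0,
    margin_nm: float = 200.0,
    seed: int = 0,
):
    """Clustered 2-D localization events with log-normal photon counts.

    Cluster centers are uniform in the field (inside ``margin_nm``); events
    are isotropic Gaussian around their center with sd ``cluster_sigma_nm``;
    photon counts are log-normal with the given median and log-sd.

    Returns an event DataFrame (frame, x_nm, y_nm, photons) and a
    :class:`SimulationTruth` carrying the planted centers.
    """
    if field_nm <= 2 * margin_nm:
        raise ValueError("field too small for the requested margin")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(margin_nm, field_nm - margin_nm, size=(n_clusters, 2))
    n = n_clusters * events_per_cluster
    which = np.repeat(np.arange(n_clusters), events_per_cluster)
    xy = centers[which] + rng.normal(0.0, cluster_sigma_nm, size=(n, 2))
    xy = np.clip(xy, 0.0, np.nextafter(field_nm, 0.0))
    photons = np.exp(rng.normal(np.log(photon_median), photon_sigma, n))
    events = pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "photons": photons,
        }
    )
    truth = SimulationTruth(seed=seed, cluster_centers=centers)
    return events, truth
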