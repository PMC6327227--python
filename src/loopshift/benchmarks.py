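"""Seeded validation experiments: planted-truth recovery at study-like scale.

Each function simulates data under fixed study conditions with the
:mod:`loopshift.simulate` generators, runs the corresponding pipeline stage,
and returns the recovery metrics.  These experiments back both the
acceptance-level tests and the reproduction script; problem sizes are chosen
so the full battery runs in minutes on one CPU (one ~100 Mb chromosome
equivalent at 10-kb bins for loop calling, a 20 Mb chromosome elsewhere).
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .contact import ipf_normalize
from .loops import LoopRecord, call_loops, test_differential_loops
from .topology import call_compartments, insulation_score
from .annotation import assign_motifs, differential_occupancy, loop_domain_tile_profile
from .sri import ForkSet, detect_forks, nnd_stats, reconstruct
from .contact import fit_expected

__all__ = [
    "ipf_bias_recovery",
    "loop_call_recovery",
    "differential_loop_benchmark",
    "insulation_boundary_discrimination",
    "compartment_recovery",
    "sri_recovery",
    "orientation_tile_benchmark",
]


def ipf_bias_recovery(seed: int = 1, n_bins: int = 2000) -> dict:
    """Pearson correlation of IPF-recovered biases with planted log-normal truth."""
    maps, truth = simulate.simulate_contact_maps(
        n_bins=n_bins, bias_sigma=0.5, seed=seed
    )
    bias, _ = ipf_normalize(maps[(0, 0)])
    ok = ~bias.mask
    r = float(np.corrcoef(bias.values[ok], truth.bias[ok])[0, 1])
    return {"correlation": r, "n": int(n_bins)}


def _loop_hit(record: LoopRecord, planted) -> bool:
    return any(
        any(abs(i - a) <= 1 and abs(j - b) <= 1 for (i, j) in record.pixel_cluster)
        for a, b, _ in planted
    )


def loop_call_recovery(
    seed: int = 2,
    n_bins: int = 10_000,
    n_loops: int = 50,
    enrichment: float = 3.0,
    dispersion: float = 0.05,
) -> dict:
    """Recall and empirical FDR of the loop caller on planted 3x focal loops.

    ~2e6 pixels within 2 Mb of the diagonal are tested (about one large
    chromosome at 10-kb resolution).
    """
    maps, truth = simulate.simulate_contact_maps(
        n_bins=n_bins,
        loops={"n": n_loops, "enrichment": enrichment, "min_dist": 15, "max_dist": 195},
        dispersion=dispersion,
        replicates=2,
        max_dist=210,
        seed=seed,
    )
    records, calls = call_loops([maps[(0, 0)], maps[(0, 1)]])
    recovered = sum(
        1
        for a, b, _ in truth.loops
        if any(
            any(abs(i - a) <= 1 and abs(j - b) <= 1 for (i, j) in lp.pixel_cluster)
            for lp in records
        )
    )
    false = sum(1 for lp in records if not _loop_hit(lp, truth.loops))
    return {
        "recall": recovered / n_loops,
        "fdr": false / max(len(records), 1),
        "n_tested_pixels": int(len(calls)),
        "n_detected": len(records),
    }


def differential_loop_benchmark(
    seed: int = 3,
    n_null: int = 2000,
    n_effect: int = 30,
    effect: float = 3.0,
    dispersion: float = 0.1,
    fdr: float = 0.1,
) -> dict:
    """Null control and effect recovery of differential loop-strength testing."""
    n_total = n_null + n_effect
    maps, truth = simulate.simulate_contact_maps(
        n_bins=6000,
        loops={"n": n_total, "enrichment": 2.0, "min_dist": 15, "max_dist": 190},
        dispersion=dispersion,
        replicates=2,
        conditions=2,
        condition_loop_factor=[effect] * n_effect + [1.0] * n_null,
        max_dist=200,
        seed=seed,
    )
    bs = 10_000
    records = [
        LoopRecord(
            chromosome="chrS",
            anchor5=((i - 1) * bs, (i + 2) * bs),
            anchor3=((j - 1) * bs, (j + 2) * bs),
            pixel_cluster=frozenset({(i, j)}),
        )
        for i, j, _ in truth.loops
    ]
    raws = {1: [maps[(0, 0)], maps[(0, 1)]], 2: [maps[(1, 0)], maps[(1, 1)]]}
    models = {
        c: [fit_expected(ipf_normalize(m)[1]) for m in raws[c]] for c in raws
    }
    res = test_differential_loops(records, raws, models, fdr=fdr)
    planted = {k for k, f in enumerate(truth.loop_condition_factors) if f > 1}
    null_rows = res[[not (set(m) & planted) for m in res["loop_members"]]]
    flagged = np.isin(null_rows["class"], ["induced", "reduced"])
    induced_members: set = set()
    for _, row in res[res["class"] == "induced"].iterrows():
        induced_members.update(row["loop_members"])
    return {
        "null_flag_fraction": float(np.mean(flagged)),
        "induced_recovered": len(induced_members & planted),
        "n_null": int(len(null_rows)),
        "n_effect": n_effect,
    }


def insulation_boundary_discrimination(
    seed: int = 5, n_bins: int = 1000, domain_width: int = 50, contrast: float = 4.0
) -> dict:
    """Median insulation-score gap between planted boundaries and interiors."""
    domains = [
        (s, min(s + domain_width, n_bins), contrast)
        for s in range(0, n_bins, domain_width)
    ]
    maps, _ = simulate.simulate_contact_maps(
        n_bins=n_bins, domains=domains, dispersion=0.05, replicates=1, seed=seed
    )
    _, norm = ipf_normalize(maps[(0, 0)])
    prof = insulation_score(norm)
    boundaries = [s for s in range(domain_width, n_bins, domain_width)]
    interior = [
        b
        for b in range(n_bins)
        if np.isfinite(prof.score[b])
        and min(abs(b - s) for s in boundaries) > 10
    ]
    gap = float(
        np.nanmedian(prof.score[boundaries]) - np.nanmedian(prof.score[interior])
    )
    return {"median_is_gap": gap, "n": int(n_bins)}


def compartment_recovery(seed: int = 6, n_bins: int = 200) -> dict:
    """Sign agreement of the compartment eigenvector with a planted checkerboard."""
    maps, truth = simulate.simulate_contact_maps(
        n_bins=n_bins,
        bin_size=50_000,
        biases=None,
        compartments={"period_bins": 5, "factor": 2.0},
        dispersion=0.05,
        replicates=1,
        seed=seed,
    )
    expression = np.where(truth.compartment_labels > 0, 2.0, 1.0)
    track = call_compartments(maps[(0, 0)], expression)
    signs = np.where(track.values > 0, 1, -1)
    agreement = float(np.mean(signs == truth.compartment_labels))
    return {"agreement": agreement, "n": int(n_bins)}


def sri_recovery(seed: int = 4, n_clusters: int = 100) -> dict:
    """Fork-count and NND recovery on a planted cluster field, plus the grid oracle."""
    events, truth = simulate.simulate_localizations(n_clusters=n_clusters, seed=seed)
    forks = detect_forks(reconstruct(events))
    nnd = nnd_stats(forks)
    from scipy.spatial import cKDTree

    tree = cKDTree(truth.cluster_centers)
    d, _ = tree.query(truth.cluster_centers, k=2)
    grid = ForkSet(
        pixels=np.array([(i * 7, j * 7) for i in range(5) for j in range(5)]),
        pixel_size=10.0,
        disc_radius=4.0,
        min_neighbors=3,
    )
    grid_nnd = nnd_stats(grid)
    return {
        "n_planted": n_clusters,
        "n_detected": len(forks),
        "mean_nnd_nm": float(nnd.mean),
        "planted_mean_spacing_nm": float(d[:, 1].mean()),
        "grid_nnd_nm": float(np.unique(np.round(grid_nnd.distances, 9))[0]),
    }


def orientation_tile_benchmark(seed: int = 7, n_loops: int = 40) -> dict:
    """Tile-profile position of gained CTCF peaks, stratified by motif orientation.

    Simulates induced loops with convergent anchor motifs and gained anchor
    occupancy, runs differential occupancy and motif assignment, and locates
    the maximum of the 270-tile profiles of increased-forward and
    increased-reverse peaks over the induced loop domains.  Positions are
    reported as fractions along the 250 core tiles.
    """
    maps, truth = simulate.simulate_contact_maps(
        n_bins=2000,
        loops={"n": n_loops, "enrichment": 3.0, "min_dist": 30, "max_dist": 190},
        dispersion=0.05,
        replicates=2,
        conditions=2,
        condition_loop_factor=2.0,
        max_dist=200,
        seed=seed,
    )
    tracks, truth2 = simulate.simulate_annotations(truth, seed=seed + 1)
    peaks = tracks["ctcf_peaks"]
    oriented = assign_motifs(peaks, tracks["motif_hits"])
    occ = differential_occupancy(
        tracks["occupancy_counts"], np.array(["c1", "c1", "c2", "c2"])
    )
    bs = 10_000
    domains = [
        ("chrS", i * bs + bs // 2, j * bs + bs // 2) for i, j, _ in truth.loops
    ]
    out = {}
    for name, orient in (("forward", "forward"), ("reverse", "reverse")):
        sel = (occ["status"] == "gained").to_numpy() & (
            oriented["orientation"] == orient
        ).to_numpy()
        prof = loop_domain_tile_profile(domains, oriented[sel])
        core = prof[10:260]
        out[f"{name}_core_argmax_fraction"] = float(np.argmax(core) / 250.0)
        out[f"n_gained_{name}"] = int(sel.sum())
    return out
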