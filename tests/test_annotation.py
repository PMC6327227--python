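"""Regulatory elements, motif orientation, occupancy dynamics, tile profiles."""

import numpy as np
import pandas as pd
import pytest

import loopshift as ls
from loopshift.annotation import (
    anchor_feature_overlap,
    assign_motifs,
    classify_regulatory_elements,
    differential_occupancy,
    induced_enhancers,
    loop_domain_tile_profile,
    median_of_ratios_size_factors,
    pei_contact_dynamics,
)
from loopshift.contact import BiasVector, NormalizedMatrix
from loopshift.loops import LoopRecord


def iv(rows, chrom="chrT"):
    return pd.DataFrame(
        [(chrom, s, e) for s, e in rows], columns=["chrom", "start", "end"]
    )


class TestRegulatoryClassification:
    def test_k4me1_overlapping_k4me3_is_not_enhancer(self):
        out = classify_regulatory_elements(
            k4me1=iv([(1000, 2000)]),
            k4me3=iv([(1500, 1800)]),
            k27ac=iv([]),
            tss=pd.DataFrame(columns=["chrom", "pos", "strand"]),
        )
        assert len(out["enhancers"]) == 0

    def test_unmarked_k4me1_is_poised(self):
        out = classify_regulatory_elements(
            k4me1=iv([(1000, 2000)]),
            k4me3=iv([]),
            k27ac=iv([]),
            tss=pd.DataFrame(columns=["chrom", "pos", "strand"]),
        )
        assert list(out["enhancers"]["status"]) == ["poised"]

    def test_promoter_window_and_activity(self):
        tss = pd.DataFrame({"chrom": ["chrT"], "pos": [5000], "strand": ["+"]})
        out = classify_regulatory_elements(
            k4me1=iv([]), k4me3=iv([(4950, 5050)]), k27ac=iv([]), tss=tss
        )
        p = out["promoters"].iloc[0]
        assert (p["start"], p["end"]) == (4900, 5100)
        assert bool(p["active"])

    def test_induced_set_is_condition2_minus_condition1(self):
        ns_active = iv([(0, 1000), (5000, 6000)])
        es_active = iv([(0, 1000)])
        induced = induced_enhancers(ns_active, es_active)
        assert [(r["start"], r["end"]) for _, r in induced.iterrows()] == [(5000, 6000)]
        assert len(induced_enhancers(es_active, ns_active)) == 0

    def test_every_k4me1_peak_in_exactly_one_class(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(np.arange(0, 10_000_000, 2500), 400, replace=False))
        k4me1 = iv([(s, s + 1000) for s in starts])
        k4me3 = iv([(s, s + 400) for s in starts[::7]])
        k27ac = iv([(s + 100, s + 600) for s in starts[::3]])
        out = classify_regulatory_elements(
            k4me1, k4me3, k27ac,
            tss=pd.DataFrame(columns=["chrom", "pos", "strand"]),
        )
        enh = out["enhancers"]
        assert set(enh["status"]) <= {"active", "poised"}
        n_excluded = len(k4me1) - len(enh)
        assert n_excluded + len(enh) == len(k4me1)


class TestMotifAssignment:
    def peaks(self):
        return iv([(1000, 2000)])

    def hits(self, rows):
        return pd.DataFrame(
            [("chrT", s, e, strand, p) for s, e, strand, p in rows],
            columns=["chrom", "start", "end", "strand", "p"],
        )

    def test_lowest_p_hit_wins(self):
        out = assign_motifs(
            self.peaks(),
            self.hits([(1100, 1120, "+", 1e-5), (1200, 1220, "-", 1e-6)]),
        )
        assert out["orientation"].iloc[0] == "reverse"

    def test_weak_hit_leaves_peak_unoriented(self):
        out = assign_motifs(self.peaks(), self.hits([(1100, 1120, "+", 5e-4)]))
        assert out["orientation"].iloc[0] == "none"

    def test_threshold_is_strict(self):
        out = assign_motifs(self.peaks(), self.hits([(1100, 1120, "+", 1e-4)]))
        assert out["orientation"].iloc[0] == "none"

    def test_tie_broken_by_leftmost(self):
        out = assign_motifs(
            self.peaks(),
            self.hits([(1500, 1520, "-", 1e-6), (1100, 1120, "+", 1e-6)]),
        )
        assert out["orientation"].iloc[0] == "forward"


class TestDifferentialOccupancy:
    conditions = np.array(["c1", "c1", "c2", "c2"])

    def test_identical_tables_produce_no_calls(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, 500)
        counts = np.stack([col] * 4, axis=1)
        res = differential_occupancy(counts, self.conditions)
        assert set(res["status"]) == {"unchanged"}

    def test_global_scaling_absorbed_by_size_factors(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, (500, 4)).astype(float)
        res1 = differential_occupancy(counts, self.conditions)
        doubled = counts.copy()
        doubled[:, 3] *= 2
        # oracle: median-of-ratios absorbs an exact doubling exactly, so the
        # normalized matrix changes only by one global constant
        sf1 = median_of_ratios_size_factors(counts)
        sf2 = median_of_ratios_size_factors(doubled)
        norm1, norm2 = counts / sf1, doubled / sf2
        scale = norm2[0, 0] / norm1[0, 0]
        assert np.allclose(norm2, norm1 * scale, rtol=1e-12)
        assert sf2[3] / sf2[2] == pytest.approx(2.0 * sf1[3] / sf1[2], rel=1e-12)
        # statuses: unchanged except at most borderline re-weighting flips
        res2 = differential_occupancy(doubled, self.conditions)
        agree = np.mean(res1["status"].to_numpy() == res2["status"].to_numpy())
        assert agree >= 0.99

    def test_planted_gains_recovered_with_fdr_control(self):
        rng = np.random.default_rng(3)
        n, frac = 5000, 0.1
        n_gain = int(n * frac)
        reps = 4  # two-fold gains at NB alpha 0.05 need ~4 replicates for >80% power
        conditions = np.array(["c1"] * reps + ["c2"] * reps)
        mu = np.full((n, 2 * reps), 100.0)
        mu[:n_gain, reps:] *= 2.0
        lam = rng.gamma(1 / 0.05, 0.05 * mu)
        counts = rng.poisson(lam)
        res = differential_occupancy(counts, conditions)
        gained = (res["status"] == "gained").to_numpy()
        recovery = gained[:n_gain].mean()
        fdr = gained[n_gain:].sum() / max(gained.sum(), 1)
        assert recovery >= 0.8
        assert fdr <= 0.15

    def test_condition_swap_negates_lfc_and_swaps_status(self):
        rng = np.random.default_rng(4)
        mu = np.full((400, 4), 80.0)
        mu[:40, 2:] *= 3.0
        counts = rng.poisson(mu)
        res = differential_occupancy(counts, self.conditions)
        swapped = differential_occupancy(
            counts[:, [2, 3, 0, 1]], self.conditions
        )
        assert np.allclose(
            res["log2_fold_change"], -swapped["log2_fold_change"],
            atol=1e-8, equal_nan=True,
        )
        assert list(res["status"].replace({"gained": "lost", "lost": "gained"})) == list(
            swapped["status"]
        )


class TestTileProfiles:
    def test_single_domain_geometry(self):
        prof = loop_domain_tile_profile(
            [("chrT", 0, 500_000)], iv([(0, 100)])
        )
        assert prof.shape == (270,)
        # feature at domain start overlaps flank tile 9 and core tile 10
        assert prof[10] == 1.0
        assert prof[11] == 0.0

    def test_feature_in_flank_counted_in_flank_tile(self):
        prof = loop_domain_tile_profile(
            [("chrT", 100_000, 600_000)], iv([(80_000, 80_500)])
        )
        ts = 500_000 / 250
        k = 10 + int(np.floor((80_000 - 100_000) / ts))
        assert prof[k] == 1.0 and prof.sum() == pytest.approx(1.0)

    def test_uniform_features_give_flat_profile(self):
        rng = np.random.default_rng(5)
        domains = [("chrT", s, s + 500_000) for s in range(0, 100_000_000, 1_000_000)]
        starts = rng.integers(0, 100_000_000, 30_000)
        feats = iv([(s, s + 200) for s in np.sort(starts)])
        prof = loop_domain_tile_profile(domains, feats)
        p_hat = prof.mean()
        se = np.sqrt(p_hat * (1 - p_hat) / len(domains))
        assert np.all(np.abs(prof - p_hat) < 2.58 * se * 3)  # 99% envelope, loose

    def test_invariance_under_coordinate_rescaling(self):
        domains = [("chrT", 1_000, 6_000), ("chrT", 10_000, 20_000)]
        feats = iv([(1_200, 1_300), (12_000, 15_000)])
        p1 = loop_domain_tile_profile(domains, feats)
        scale = 7
        domains2 = [(c, s * scale, e * scale) for c, s, e in domains]
        feats2 = iv([(1_200 * scale, 1_300 * scale), (12_000 * scale, 15_000 * scale)])
        p2 = loop_domain_tile_profile(domains2, feats2)
        assert np.array_equal(p1, p2)

    def test_zero_length_domain_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            loop_domain_tile_profile([("chrT", 5, 5)], iv([]))


def norm_from_dense(dense, bin_size=5_000):
    n = dense.shape[0]
    rows, cols = np.triu_indices(n)
    return NormalizedMatrix(
        "chrT", bin_size, n, rows, cols, dense[rows, cols].astype(float),
        BiasVector(np.ones(n)),
    )


class TestPEIDynamics:
    def setup_matrices(self, n=60, ratio=2.0):
        base = np.full((n, n), 4.0)
        return norm_from_dense(base), norm_from_dense(base * ratio)

    def test_constant_doubling_gives_mean_ratio_two(self):
        m1, m2 = self.setup_matrices()
        doms = [("chrT", 0, 300_000)]
        prom = iv([(60_000, 61_000)])
        enh = iv([(200_000, 201_000)])
        pairs, per_dom = pei_contact_dynamics(doms, prom, enh, m1, m2)
        assert per_dom["mean_ratio"].iloc[0] == pytest.approx(2.0)

    def test_short_span_pairs_excluded(self):
        m1, m2 = self.setup_matrices()
        doms = [("chrT", 0, 300_000)]
        prom = iv([(100_000, 101_000)])
        enh = iv([(112_000, 113_000)])  # 12 kb apart, below 20 kb span
        pairs, per_dom = pei_contact_dynamics(doms, prom, enh, m1, m2)
        assert len(pairs) == 0 and len(per_dom) == 0

    def test_trim_margin_excludes_anchor_proximal_bins(self):
        m1, m2 = self.setup_matrices()
        doms = [("chrT", 0, 300_000)]
        prom = iv([(5_000, 6_000)])  # inside the 20-kb trim
        enh = iv([(200_000, 201_000)])
        pairs, per_dom = pei_contact_dynamics(doms, prom, enh, m1, m2)
        assert len(pairs) == 0


class TestAnchorOverlap:
    def loops(self):
        def mk(m5, m3):
            return LoopRecord(
                chromosome="chrT",
                anchor5=(m5 - 10_000, m5 + 10_000),
                anchor3=(m3 - 10_000, m3 + 10_000),
                pixel_cluster=frozenset({(m5 // 10_000, m3 // 10_000)}),
            )

        return [
            mk(200_000, 800_000),   # peaks at both anchors
            mk(1_200_000, 1_900_000),  # peak at one anchor
            mk(2_500_000, 3_200_000),  # no peaks
            mk(4_000_000, 4_700_000),  # single peak per anchor
        ]

    def peaks(self):
        return iv(
            [
                (199_000, 199_400), (201_000, 201_400), (795_000, 795_400),
                (1_195_000, 1_195_400),
                (3_995_000, 3_995_400), (4_702_000, 4_702_400),
                (786_000, 786_400),  # near the 800 kb anchor but > 5 kb off-midpoint
            ]
        )

    def test_hand_counted_fractions(self):
        out = anchor_feature_overlap(self.loops(), self.peaks())
        assert out["fraction_both"] == pytest.approx(2 / 4)
        assert out["fraction_one"] == pytest.approx(1 / 4)
        assert out["fraction_none"] == pytest.approx(1 / 4)
        assert out["fraction_single_peak_per_anchor"] == pytest.approx(1 / 4)

    def test_midpoint_mode_narrows_window(self):
        wide = anchor_feature_overlap(self.loops(), self.peaks(), mode="anchor")
        narrow = anchor_feature_overlap(self.loops(), self.peaks(), mode="midpoint")
        # peak at 786 kb is inside the extended whole anchor [780, 820) kb
        assert wide["per_loop"]["n_peaks_3p"].iloc[0] == 2
        # but outside the midpoint window [795, 805) kb
        assert narrow["per_loop"]["n_peaks_3p"].iloc[0] == 1
        # the 4.7 Mb anchor peak at 4,702,000 survives both modes
        assert narrow["per_loop"]["n_peaks_3p"].iloc[3] == 1
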