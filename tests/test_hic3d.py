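"""Compartment calling, TAD boundaries and TE-composition analytics."""

import numpy as np
import pytest

from retroscape import hic3d
from retroscape import synthetic_data as sd
from retroscape.io_formats import ContactMatrix, IntervalSet


def plaid_matrix(n=200, rho=0.2, seed=7, boundaries=(), boost=1.0):
    a = np.where(np.arange(n) < n // 2, 1, -1)
    cfg = sd.PlaidConfig(
        n_bins=n, compartments=a, plaid_strength=rho, decay_exponent=1.0,
        tad_boundaries=list(boundaries), tad_boost=boost, seed=seed,
    )
    return sd.simulate_contact_matrix(cfg), a


def gc_for(a, seed=3):
    rng = np.random.default_rng(seed)
    return 0.40 + 0.04 * (np.asarray(a) > 0) + rng.normal(0, 0.01, len(a))


class TestOE:
    def test_constant_per_diagonal_becomes_ones(self):
        n = 20
        v = np.fromfunction(lambda i, j: 1.0 / (1 + abs(i - j)), (n, n))
        oe, mask = hic3d.oe_normalize(ContactMatrix("c", 100_000, v))
        assert not mask.any()
        np.testing.assert_allclose(oe, 1.0)

    def test_mean_one_per_diagonal(self):
        m, _ = plaid_matrix(n=60)
        oe, mask = hic3d.oe_normalize(m)
        keep = ~mask
        for d in range(1, 10):
            idx = np.arange(60 - d)
            vals = oe[idx, idx + d][keep[idx] & keep[idx + d]]
            assert vals.mean() == pytest.approx(1.0, abs=1e-9)

    def test_plaid_sign_structure_retained(self):
        m, a = plaid_matrix(n=100, rho=0.3)
        oe, mask = hic3d.oe_normalize(m)
        same = np.outer(a, a) > 0
        off = ~np.eye(100, dtype=bool)
        assert oe[same & off].mean() > oe[~same & off].mean()


class TestCompartments:
    def test_planted_labels_recovered(self):
        m, a = plaid_matrix()
        track = hic3d.compartments(m, gc_for(a))
        sign = np.where(track.pc1 > 0, 1, -1)
        agree = max((sign == a).mean(), (sign == -a).mean())
        assert agree >= 0.95

    def test_matches_eigh_oracle(self):
        m, a = plaid_matrix(seed=11)
        track = hic3d.compartments(m, gc_for(a))
        oe, mask = hic3d.oe_normalize(m)
        corr = hic3d.correlation_matrix(oe, mask)
        w, v = np.linalg.eigh(corr)
        lead = v[:, np.argmax(w)]
        pc = track.pc1[~mask]
        cos = abs(lead @ pc) / (np.linalg.norm(lead) * np.linalg.norm(pc))
        assert cos >= 0.999

    def test_gc_anchor_orients_a_to_gc_rich(self):
        m, a = plaid_matrix(seed=2)
        track = hic3d.compartments(m, gc_for(a, seed=9))
        labels = track.labels
        gc = gc_for(a, seed=9)
        assert gc[labels == "A"].mean() > gc[labels == "B"].mean()

    def test_no_plaid_flags_weak_compartmentalization(self):
        m, a = plaid_matrix(rho=0.0, seed=5)
        track = hic3d.compartments(m, gc_for(a))
        assert track.weak

    def test_masked_bins_propagate(self):
        m, a = plaid_matrix(n=40, seed=4)
        v = m.values.copy()
        v[5, :] = 0.0
        v[:, 5] = 0.0
        track = hic3d.compartments(ContactMatrix("c", 100_000, v), gc_for(a)[:40])
        assert track.labels[5] == "masked"
        assert np.isnan(track.pc1[5])

    def test_too_few_unmasked_bins_rejected(self):
        with pytest.raises(ValueError):
            hic3d.compartments(
                ContactMatrix("c", 100_000, np.zeros((12, 12))), np.full(12, 0.4)
            )


class TestCompartmentAssociation:
    def test_planted_sine_enrichment_in_a(self):
        m, a = plaid_matrix(seed=8)
        track = hic3d.compartments(m, gc_for(a))
        rng = np.random.default_rng(0)
        sine = np.where(track.labels == "A", 0.3, 0.1) + rng.normal(0, 0.02, 200)
        line = np.where(track.labels == "B", 0.4, 0.2) + rng.normal(0, 0.02, 200)
        df = hic3d.compartment_te_association(track, {"SINE": sine, "LINE": line})
        sine_row = df[df["te_class"] == "SINE"].iloc[0]
        line_row = df[df["te_class"] == "LINE"].iloc[0]
        assert sine_row["mean_A"] > sine_row["mean_B"] and sine_row["p"] < 0.01
        assert line_row["mean_B"] > line_row["mean_A"] and line_row["p"] < 0.01

    def test_single_compartment_rejected(self):
        track = hic3d.CompartmentTrack(
            pc1=np.ones(20), labels=np.array(["A"] * 20, dtype=object), sign_anchor_r=1.0
        )
        with pytest.raises(ValueError, match="single compartment"):
            hic3d.compartment_te_association(track, {"SINE": np.ones(20)})


class TestTads:
    def test_two_tad_block_matrix_unique_boundary(self):
        v = np.ones((40, 40))
        v[:20, :20] = 5.0
        v[20:, 20:] = 5.0
        res = hic3d.tad_separation(ContactMatrix("c", 100_000, v))
        assert len(res.boundaries) == 1
        assert abs(res.boundaries[0] - 20) <= 1

    def test_uniform_matrix_no_boundaries(self):
        res = hic3d.tad_separation(ContactMatrix("c", 100_000, np.ones((60, 60))))
        assert res.boundaries == []

    def test_three_planted_tads_recovered(self):
        m, _ = plaid_matrix(n=90, rho=0.0, seed=5, boundaries=(30, 60), boost=3.0)
        res = hic3d.tad_separation(m)
        assert len(res.boundaries) == 2
        assert min(abs(b - 30) for b in res.boundaries) <= 1
        assert min(abs(b - 60) for b in res.boundaries) <= 1

    def test_scale_invariance(self):
        m, _ = plaid_matrix(n=90, rho=0.0, seed=6, boundaries=(30, 60), boost=3.0)
        res1 = hic3d.tad_separation(m)
        scaled = ContactMatrix("c", 100_000, m.values * 7.5)
        res2 = hic3d.tad_separation(scaled)
        assert res1.boundaries == res2.boundaries


class TestBinClasses:
    def test_dominant_class_wins_and_ties_neutral(self):
        lf = np.array([0.9, 0.1, 0.5, 0.5])
        sf = np.array([0.1, 0.9, 0.5, 0.2])
        track = hic3d.classify_bins(lf, sf, quantile=0.5)
        assert track.labels[0] == "LINE-rich"
        assert track.labels[1] == "SINE-rich"
        assert track.labels[2] == "neutral"  # exact tie

    def test_planted_alternating_pattern_reproduced(self, rng):
        n = 100
        rich = (np.arange(n) // 10) % 2 == 0
        lf = np.where(rich, 0.6, 0.1) + rng.normal(0, 0.01, n)
        sf = np.where(~rich, 0.6, 0.1) + rng.normal(0, 0.01, n)
        track = hic3d.classify_bins(lf, sf, quantile=0.5)
        expect = np.where(rich, "LINE-rich", "SINE-rich")
        assert (track.labels == expect).mean() >= 0.95


class TestHomotypic:
    def test_plaid_sign_pattern(self):
        m, a = plaid_matrix(seed=12, rho=0.3)
        oe, mask = hic3d.oe_normalize(m)
        corr = hic3d.correlation_matrix(oe, mask)
        # LINE-rich = B half, SINE-rich = A half
        labels = np.where(a > 0, "SINE-rich", "LINE-rich").astype(object)
        track = hic3d.BinClassTrack(labels, np.zeros(200), np.zeros(200))
        stats_by = hic3d.homotypic_stats(corr, track)
        assert stats_by["LINE-LINE"].fraction_positive > stats_by["LINE-SINE"].fraction_positive
        assert stats_by["SINE-SINE"].fraction_positive > stats_by["LINE-SINE"].fraction_positive

    def test_all_positive_matrix(self):
        corr = np.full((6, 6), 0.5)
        labels = np.array(["LINE-rich"] * 3 + ["SINE-rich"] * 3, dtype=object)
        track = hic3d.BinClassTrack(labels, np.zeros(6), np.zeros(6))
        st = hic3d.homotypic_stats(corr, track)
        assert all(s.fraction_positive == 1.0 for s in st.values())

    def test_missing_class_reports_zero_pairs(self):
        corr = np.eye(4)
        labels = np.array(["LINE-rich"] * 4, dtype=object)
        st = hic3d.homotypic_stats(corr, hic3d.BinClassTrack(labels, np.zeros(4), np.zeros(4)))
        assert st["SINE-SINE"].n_pairs == 0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        corr = rng.normal(size=(20, 20))
        corr = (corr + corr.T) / 2
        labels = np.array(
            ["LINE-rich"] * 8 + ["SINE-rich"] * 8 + ["neutral"] * 4, dtype=object
        )
        st1 = hic3d.homotypic_stats(corr, hic3d.BinClassTrack(labels, np.zeros(20), np.zeros(20)))
        swapped = np.where(
            labels == "LINE-rich", "SINE-rich",
            np.where(labels == "SINE-rich", "LINE-rich", labels),
        ).astype(object)
        st2 = hic3d.homotypic_stats(corr, hic3d.BinClassTrack(swapped, np.zeros(20), np.zeros(20)))
        assert st1["LINE-LINE"].fraction_positive == st2["SINE-SINE"].fraction_positive
        assert st1["LINE-SINE"].n_pairs == st2["LINE-SINE"].n_pairs


class TestFeatureOverlap:
    TRACK = hic3d.BinClassTrack(
        np.array(["LINE-rich"] * 5 + ["SINE-rich"] * 5, dtype=object),
        np.zeros(10), np.zeros(10),
    )

    def test_loop_anchors_same_class(self):
        loops = IntervalSet(
            intervals=[],
            anchor_pairs=[(("c", 550_000, 650_000), ("c", 750_000, 850_000))],
        )
        df = hic3d.feature_overlap(loops, self.TRACK, resolution=100_000)
        assert df.set_index("label").loc["SINE-rich", "proportion"] == 1.0

    def test_span_majority_and_tie(self):
        feats = IntervalSet(intervals=[("c", 0, 300_000), ("c", 400_000, 600_000)])
        df = hic3d.feature_overlap(feats, self.TRACK, resolution=100_000)
        idx = df.set_index("label")
        assert idx.loc["LINE-rich", "n_features"] == 1  # fully in LINE half
        assert idx.loc["mixed", "n_features"] == 1  # exact 100kb/100kb tie

    def test_empty_features_all_zero(self):
        df = hic3d.feature_overlap(IntervalSet(intervals=[]), self.TRACK, 100_000)
        assert (df["n_features"] == 0).all()
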