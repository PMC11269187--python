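"""Variant orientation, motif-score deltas, the saturation null, weighted MWU."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from tssgrammar import genvar as gv
from tssgrammar import seqmodel as sm
from tssgrammar import synth
from tssgrammar.enrichment import _offset_scores


def _variants_frame(rows):
    return pd.DataFrame(rows, columns=["variant_id", "window_id", "rel_pos",
                                       "ref", "alt"])


class TestOrientation:
    @pytest.fixture()
    def variants(self):
        return _variants_frame([
            ("v1", "w0", -10, "A", "C"),
            ("v2", "w0", -20, "G", "T"),
            ("v3", "w0", -30, "C", "A"),
        ])

    def test_positive_slope_keeps_alt_active(self, variants):
        activity = pd.DataFrame({"variant_id": ["v1"], "slope": [0.3],
                                 "p": [0.01]})
        oriented, counts = gv.assign_orientation(variants, activity)
        assert counts["retained"] == 1
        assert oriented.iloc[0]["active"] == "alt"

    def test_small_slope_dropped(self, variants):
        activity = pd.DataFrame({"variant_id": ["v1"], "slope": [0.05],
                                 "p": [0.01]})
        _, counts = gv.assign_orientation(variants, activity)
        assert counts["retained"] == 0

    def test_weak_p_dropped(self, variants):
        activity = pd.DataFrame({"variant_id": ["v1"], "slope": [0.5],
                                 "p": [0.4]})
        _, counts = gv.assign_orientation(variants, activity)
        assert counts["retained"] == 0

    def test_negative_slope_keeps_ref_active(self, variants):
        activity = pd.DataFrame({"variant_id": ["v2"], "slope": [-0.4],
                                 "p": [0.001]})
        oriented, _ = gv.assign_orientation(variants, activity)
        assert oriented.iloc[0]["active"] == "ref"


class TestObservedDeltas:
    def _single_window_setup(self, nrf1, center=-55):
        from tests.conftest import consensus_window
        w = consensus_window(nrf1, center=center)
        return [w]

    def test_destroying_consensus_base_gives_positive_delta_when_ref_active(
            self, nrf1):
        windows = self._single_window_setup(nrf1)
        # mutate the motif's central base; ref (consensus) allele is active
        rel = -55
        ref_base = windows[0].base_at(rel)
        alt_base = "A" if ref_base != "A" else "C"
        oriented = _variants_frame([("v0", "w0", rel, ref_base, alt_base)])
        oriented["active"] = "ref"
        deltas = gv.observed_motif_deltas(oriented, windows, nrf1,
                                          interval=(-80, -30))
        assert len(deltas) == 1
        assert deltas[0] > 0

    def test_variant_outside_any_hit_contributes_nothing(self, nrf1):
        windows = self._single_window_setup(nrf1)
        oriented = _variants_frame([("v0", "w0", 50, "A", "C")])
        oriented["active"] = "alt"
        deltas = gv.observed_motif_deltas(oriented, windows, nrf1,
                                          interval=(-150, 100))
        assert len(deltas) == 0

    def test_deltas_match_two_allele_rescan_oracle(self, nrf1):
        """Brute force: rescan both allele sequences over every overlapping
        offset and compare the best-placement delta."""
        rng = np.random.default_rng(21)
        cfg = synth.SimConfig(seed=21, n=40, up=60, down=40,
                              plants=[synth.PlantSpec(nrf1, (-40, -10), 0.8)])
        mat, _, _ = synth.simulate_tss_windows(cfg)
        windows = synth.as_windows(mat, 60, 40)
        interval = (-50, 0)
        recs = gv.saturation_delta_records(mat, nrf1, up=60)
        # pick random SNVs and verify against brute force
        checked = 0
        for _ in range(300):
            si = int(rng.integers(0, 40))
            rel = int(rng.integers(-50, 10))
            col = rel + 60
            ref = int(mat[si, col])
            alt = int((ref + rng.integers(1, 4)) % 4)
            oriented = _variants_frame(
                [("v", windows[si].window_id, rel, "ACGT"[ref], "ACGT"[alt])])
            oriented["active"] = "alt"
            got = gv.observed_motif_deltas(oriented, windows, nrf1, interval,
                                           records=recs, up=60)
            expect = self._brute_force_delta(mat[si], nrf1, col, ref, alt,
                                             interval, up=60)
            if expect is None:
                assert len(got) == 0
            else:
                checked += 1
                assert got[0] == pytest.approx(expect, abs=1e-12)
        assert checked > 10

    @staticmethod
    def _brute_force_delta(row, pwm, col, ref, alt, interval, up):
        best = None
        for p in (pwm, pwm.reverse_complement()):
            lo = np.where(np.isfinite(p.log_odds), p.log_odds, -1e4)
            Lm = len(p)
            for off in range(len(row) - Lm + 1):
                if not (off <= col < off + Lm):
                    continue
                center = off + p.center_index - up
                if not (interval[0] <= center <= interval[1]):
                    continue
                ref_row = row.copy(); ref_row[col] = ref
                alt_row = row.copy(); alt_row[col] = alt
                s_ref = sum(lo[j, ref_row[off + j]] for j in range(Lm))
                s_alt = sum(lo[j, alt_row[off + j]] for j in range(Lm))
                if max(s_ref, s_alt) < pwm.detection_threshold:
                    continue
                key = max(s_ref, s_alt)
                if best is None or key > best[0]:
                    best = (key, s_alt - s_ref)
        return None if best is None else best[1]


class TestExpectedDistribution:
    def test_single_type_single_window_is_point_mass(self, nrf1):
        from tests.conftest import consensus_window
        w = consensus_window(nrf1, center=-55)
        ref = w.base_at(-55)
        alt = "A" if ref != "A" else "C"
        b2i = {b: i for i, b in enumerate("ACGT")}
        counts = pd.DataFrame({"rel_pos": [-55], "from_base": [b2i[ref]],
                               "to_base": [b2i[alt]], "count": [1]})
        vals, wts = gv.expected_delta_distribution([w], nrf1, counts,
                                                   (-80, -30))
        assert len(vals) == 1
        assert wts[0] == pytest.approx(1.0)

    def test_doubling_counts_leaves_normalized_distribution_unchanged(
            self, nrf1):
        cfg = synth.SimConfig(seed=31, n=30, up=60, down=40,
                              plants=[synth.PlantSpec(nrf1, (-40, -20), 0.9)])
        mat, _, _ = synth.simulate_tss_windows(cfg)
        b2i = list(range(4))
        counts = pd.DataFrame({
            "rel_pos": [-30, -30, -25], "from_base": [0, 1, 2],
            "to_base": [1, 0, 3], "count": [3, 2, 5]})
        v1, w1 = gv.expected_delta_distribution(mat, nrf1, counts, (-50, -10),
                                                up=60)
        counts2 = counts.assign(count=counts["count"] * 2)
        v2, w2 = gv.expected_delta_distribution(mat, nrf1, counts2, (-50, -10),
                                                up=60)
        assert np.allclose(v1, v2)
        assert np.allclose(w2 / w2.sum(), w1 / w1.sum())

    def test_expected_mean_matches_enumeration_oracle(self, nrf1):
        """Weighted mean equals a brute-force enumeration over
        (window x position x substitution) triples."""
        cfg = synth.SimConfig(seed=32, n=12, up=40, down=20,
                              plants=[synth.PlantSpec(nrf1, (-25, -15), 0.9)])
        mat, _, _ = synth.simulate_tss_windows(cfg)
        counts = pd.DataFrame({
            "rel_pos": [-20, -18], "from_base": [1, 2], "to_base": [3, 0],
            "count": [4, 7]})
        interval = (-30, -5)
        vals, wts = gv.expected_delta_distribution(mat, nrf1, counts,
                                                   interval, up=40)
        got_mean = np.average(vals, weights=wts)
        num = den = 0.0
        for _, row in counts.iterrows():
            deltas = []
            for si in range(len(mat)):
                col = int(row["rel_pos"]) + 40
                if mat[si, col] != row["from_base"]:
                    continue
                d = TestObservedDeltas._brute_force_delta(
                    mat[si], nrf1, col, int(row["from_base"]),
                    int(row["to_base"]), interval, up=40)
                if d is not None:
                    deltas.append(d)
            if deltas:
                num += row["count"] * np.mean(deltas)
                den += row["count"]
        assert got_mean == pytest.approx(num / den, abs=1e-9)

    def test_empty_counts_give_empty_expected(self, nrf1):
        mat = np.zeros((5, 60), dtype=np.uint8)
        counts = pd.DataFrame(columns=["rel_pos", "from_base", "to_base",
                                       "count"])
        vals, wts = gv.expected_delta_distribution(mat, nrf1, counts,
                                                   (-10, 10), up=30)
        assert len(vals) == 0 and len(wts) == 0


class TestWeightedMWU:
    def test_reduces_to_scipy_with_unit_weights(self):
        rng = np.random.default_rng(1)
        for i in range(100):
            x = rng.normal(size=rng.integers(5, 40))
            y = rng.normal(size=rng.integers(5, 40))
            U, p, _ = gv.weighted_mannwhitney(x, y, np.ones(len(y)))
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_matches_scipy_under_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = np.round(rng.normal(size=rng.integers(10, 40)))
            y = np.round(rng.normal(size=rng.integers(10, 40)))
            U, p, _ = gv.weighted_mannwhitney(x, y, np.ones(len(y)))
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_all_tied_gives_p_one(self):
        U, p, sign = gv.weighted_mannwhitney(np.ones(10), np.ones(5),
                                             np.full(5, 2.0))
        assert p == 1.0

    def test_duplicating_support_with_split_weights_preserves_u_and_sign(
            self):
        """Splitting every support weight across duplicated values leaves U
        and the sign unchanged exactly; the P-value is nearly unchanged
        (exact invariance would contradict the null calibration, because a
        finer-grained support genuinely carries more information)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        vals = rng.normal(size=300)
        w = rng.uniform(0.05, 0.2, size=300)
        U1, p1, s1 = gv.weighted_mannwhitney(x, vals, w)
        vals2 = np.concatenate([vals, vals])
        w2 = np.concatenate([w * 0.4, w * 0.6])
        U2, p2, s2 = gv.weighted_mannwhitney(x, vals2, w2)
        assert U1 == pytest.approx(U2)
        assert s1 == s2
        assert p1 == pytest.approx(p2, rel=0.05)

    def test_sign_positive_when_x_stochastically_larger(self):
        U, p, sign = gv.weighted_mannwhitney(
            np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0]), np.ones(2))
        assert sign == 1 and p < 0.2


class TestAssociationMap:
    def test_flipping_orientations_flips_every_sign(self, nrf1):
        fx = synth.fixture_dual_tf_variants(17, n_windows=800, mode="activator")
        oriented, _ = gv.assign_orientation(fx["variants"], fx["activity"])
        t1 = gv.positional_association_test(oriented, fx["mat"], nrf1,
                                            up=fx["up"], min_obs=5)
        flipped = oriented.copy()
        flipped["active"] = np.where(flipped["active"] == "alt", "ref", "alt")
        t2 = gv.positional_association_test(flipped, fx["mat"], nrf1,
                                            up=fx["up"], min_obs=5)
        tested = t1["p"].notna() & t2["p"].notna()
        assert tested.any()
        assert (t1.loc[tested, "sign"] == -t2.loc[tested, "sign"]).all()

    def test_windows_below_min_obs_not_tested(self, nrf1):
        fx = synth.fixture_dual_tf_variants(18, n_windows=200, mode="activator")
        oriented, _ = gv.assign_orientation(fx["variants"], fx["activity"])
        table = gv.positional_association_test(oriented, fx["mat"], nrf1,
                                               up=fx["up"], min_obs=10 ** 6)
        assert table["p"].isna().all()


class TestVcfPlumbing:
    def test_vcf_round_trip_and_mapping(self, tmp_path, nrf1):
        cfg = synth.SimConfig(seed=41, n=5, up=20, down=10)
        mat, _, _ = synth.simulate_tss_windows(cfg)
        windows = synth.as_windows(mat, 20, 10)
        # one valid SNV in window coordinates of the shared synthetic contig
        variants = _variants_frame([("v0", "w0", -5, windows[0].base_at(-5),
                                     "A" if windows[0].base_at(-5) != "A"
                                     else "C")])
        path = tmp_path / "x.vcf"
        synth.variants_to_vcf(variants, path, anchor=20)
        back = gv.read_vcf_minimal(path)
        assert len(back) == 1
        mapped = gv.map_variants_to_windows(back, windows[:1], cis_range=30)
        assert len(mapped) == 1
        assert mapped.iloc[0]["rel_pos"] == -5
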