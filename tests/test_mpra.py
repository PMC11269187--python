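"""MPRA scaling formula, sweep profiles, insertion effects, TSS shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tssgrammar import mpra, synth


def _insert(counts, plasmid=1000, insert_id="i0", planted=None, barcode="bc0"):
    return mpra.InsertMatrix(
        insert_id=insert_id, promoter="P", motif="M", planted_pos=planted,
        barcode=barcode, replicate="r1", plasmid_dna_count=plasmid,
        start_counts=np.asarray(counts, dtype=float))


class TestScaleInsert:
    @pytest.mark.parametrize("plasmid,factor", [
        (1000, 10.0),   # 10000/1000
        (50, 100.0),    # capped branch: 10000/50 = 200 -> 100
        (10000, 1.0),
        (200, 50.0),
    ])
    def test_scaling_factor_branches(self, plasmid, factor):
        assert mpra.scaling_factor(plasmid) == factor

    def test_zero_count_maps_to_zero_after_pseudocount_log(self):
        out = mpra.scale_insert_log2(_insert([0, 4], plasmid=1000))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(np.log2(41))

    def test_low_plasmid_insert_excluded_and_reported(self):
        bad = _insert([1, 2], plasmid=49)
        assert not bad.usable
        with pytest.raises(ValueError, match="unusable"):
            mpra.scale_insert(bad)
        merged, excluded = mpra.merged_log2_by_insert(
            [bad, _insert([1, 2], plasmid=60, insert_id="ok")])
        assert excluded == ["i0"] and list(merged) == ["ok"]

    @given(st.integers(50, 20000), st.integers(0, 1000), st.integers(0, 1000))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_counts(self, plasmid, c1, c2):
        a = mpra.scale_insert_log2(_insert([c1], plasmid))
        b = mpra.scale_insert_log2(_insert([c2], plasmid))
        assert (a <= b).all() == (c1 <= c2)


class TestInsertionEffect:
    def test_self_effect_is_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=100)
        ins = [_insert(counts, barcode=f"b{i}") for i in range(3)]
        assert mpra.insertion_effect(ins, ins, tss_pos=50) == 0.0

    def test_fourfold_recovered_from_simulated_counts(self):
        cfg = synth.MpraSimConfig(seed=9)
        design = pd.DataFrame(
            [("ins", "P", "M", 60), ("ctl", "P", "none", np.nan)],
            columns=["insert_id", "promoter", "motif", "planted_pos"])

        def eff(pos, planted):
            return np.full(len(pos), 4.0 if planted is not None else 1.0)

        inserts, _ = synth.simulate_mpra(design, eff, cfg)
        a = [m for m in inserts if m.insert_id == "ins"]
        c = [m for m in inserts if m.insert_id == "ctl"]
        got = mpra.insertion_effect(a, c, cfg.tss_pos)
        assert got == pytest.approx(2.0, abs=0.1)

    def test_twofold_repression_recovered(self):
        cfg = synth.MpraSimConfig(seed=10)
        design = pd.DataFrame(
            [("ins", "P", "M", 60), ("ctl", "P", "none", np.nan)],
            columns=["insert_id", "promoter", "motif", "planted_pos"])

        def eff(pos, planted):
            return np.full(len(pos), 0.5 if planted is not None else 1.0)

        inserts, _ = synth.simulate_mpra(design, eff, cfg)
        a = [m for m in inserts if m.insert_id == "ins"]
        c = [m for m in inserts if m.insert_id == "ctl"]
        assert mpra.insertion_effect(a, c, cfg.tss_pos) == \
            pytest.approx(-1.0, abs=0.1)

    def test_zero_control_window_flagged_undefined(self):
        ins = np.ones(40)
        ctl = np.zeros(40)
        assert np.isnan(mpra.insertion_effect(ins, ctl, tss_pos=20))

    def test_window_inclusive_both_ends(self):
        ins = np.zeros(40)
        ins[13] = ins[27] = 8.0  # exactly +/-7 from 20
        ctl = np.zeros(40)
        ctl[20] = 16.0
        assert mpra.insertion_effect(ins, ctl, tss_pos=20) == pytest.approx(0.0)


class TestTssShift:
    def test_identical_distributions_zero(self):
        v = np.array([0, 1, 5, 1, 0], dtype=float)
        assert mpra.tss_shift(v, v) == 0.0

    def test_point_masses(self):
        c = np.zeros(100); c[60] = 5
        m = np.zeros(100); m[75] = 3
        assert mpra.tss_shift(m, c) == pytest.approx(15.0)

    @pytest.mark.parametrize("k", [1, 6, 23])
    def test_translation_recovered_exactly(self, k):
        rng = np.random.default_rng(4)
        c = np.zeros(120)
        c[40:55] = rng.integers(1, 30, 15)
        m = np.roll(c, k)
        assert mpra.tss_shift(m, c) == pytest.approx(float(k), abs=1e-9)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = rng.random(50)
        b = rng.random(50)
        assert mpra.tss_shift(a, b) == pytest.approx(-mpra.tss_shift(b, a))

    def test_zero_signal_undefined(self):
        assert np.isnan(mpra.tss_shift(np.zeros(10), np.ones(10)))


class TestSweep:
    def test_identical_inserts_give_zero_profile(self):
        counts = np.arange(50, dtype=float)
        ins = [_insert(counts, insert_id=f"i{k}", planted=10 + 2 * k)
               for k in range(6)]
        table, prof = mpra.sweep_delta(ins)
        assert np.allclose(table.to_numpy(), 0.0)
        assert np.allclose(prof.mean_delta, 0.0)

    def test_planted_boost_recovered_at_distance(self):
        design = synth.sweep_design(start=10, stop=90, step=2)

        def eff(pos, planted):
            f = np.ones(len(pos))
            if planted is not None:
                f[(pos - planted >= 53) & (pos - planted <= 57)] = 4.0
            return f

        inserts, _ = synth.simulate_mpra(design, eff,
                                         synth.MpraSimConfig(seed=11))
        _, prof = mpra.sweep_delta(inserts)
        peak = prof.distances[np.argmax(prof.mean_delta)]
        assert abs(peak - 55) <= 2

    def test_profile_invariant_to_insert_order(self):
        design = synth.sweep_design(start=10, stop=50, step=4)
        inserts, _ = synth.simulate_mpra(
            design, lambda p, q: np.ones(len(p)),
            synth.MpraSimConfig(seed=12))
        _, p1 = mpra.sweep_delta(inserts)
        _, p2 = mpra.sweep_delta(inserts[::-1])
        assert np.allclose(p1.mean_delta, p2.mean_delta)

    def test_mismatched_lengths_error(self):
        ins = [_insert(np.ones(10), insert_id="a", planted=2),
               _insert(np.ones(12), insert_id="b", planted=4),
               _insert(np.ones(10), insert_id="c", planted=6),
               _insert(np.ones(10), insert_id="d", planted=8),
               _insert(np.ones(10), insert_id="e", planted=9)]
        with pytest.raises(ValueError):
            mpra.sweep_delta(ins)


class TestLoess:
    def test_smooths_toward_local_polynomial(self):
        x = np.linspace(0, 10, 200)
        y = np.sin(x)
        sm = mpra.loess_smooth(x, y, span=0.2)
        assert np.abs(sm - y).max() < 0.05

    def test_statistics_never_smoothed(self):
        design = synth.sweep_design(start=10, stop=50, step=4)
        inserts, _ = synth.simulate_mpra(
            design, lambda p, q: np.ones(len(p)),
            synth.MpraSimConfig(seed=13))
        _, prof = mpra.sweep_delta(inserts)
        assert not np.allclose(prof.mean_delta, prof.smoothed)


class TestClassifyMutationPositions:
    def _emap(self):
        from tssgrammar.enrichment import EnrichmentMap
        table = pd.DataFrame({
            "motif": ["M", "M"], "strand": "both",
            "window_start": [-60, 10], "window_end": [-31, 39],
            "target_count": [50, 5], "background_count": [5, 50],
            "p": [1e-6, 1e-6], "p_adj": [1e-5, 1e-5],
            "signed_logP": [5.0, -5.0]})
        return EnrichmentMap(table, [(-60, -31), (10, 39)], 100, 100)

    def test_position_labels(self):
        sites = pd.DataFrame({
            "motif": ["M", "M", "M"],
            "promoter": ["p1", "p2", "p3"],
            "rel_pos": [-55, 25, 80]})
        out = mpra.classify_mutation_positions(sites, self._emap())
        assert list(out["label"]) == ["enriched-position",
                                      "depleted-position", "neutral"]

    def test_motifs_with_few_promoters_excluded(self):
        sites = pd.DataFrame({
            "motif": "M", "promoter": [f"p{i}" for i in range(12)],
            "rel_pos": -55})
        out = mpra.classify_mutation_positions(sites, self._emap(),
                                               min_promoters=20)
        assert not out["included"].any()


class TestBarcodeConcordance:
    def test_activity_correlates_across_barcodes(self):
        """Inserts with genuinely different activities (position-dependent
        planted effects) must give near-identical activity rankings across
        barcode replicates."""
        design = synth.sweep_design(start=10, stop=130, step=2)

        def eff(pos, planted):
            # smooth position-dependent activity: 0.25x to 4x by position
            return np.full(len(pos),
                           2.0 ** (2.0 * np.sin((planted or 0) / 20.0)))

        inserts, _ = synth.simulate_mpra(design, eff,
                                         synth.MpraSimConfig(seed=14))
        groups: dict[str, list] = {}
        for m in inserts:
            groups.setdefault(m.insert_id, []).append(m)
        acts = np.array([
            [np.log2(mpra.scale_insert(m).sum() + 1) for m in v]
            for v in groups.values()])
        for i in range(acts.shape[1]):
            for j in range(i + 1, acts.shape[1]):
                assert np.corrcoef(acts[:, i], acts[:, j])[0, 1] >= 0.95 or \
                    acts[:, i].std() * acts[:, j].std() == 0


class TestIO:
    def test_insert_tables_round_trip(self, tmp_path):
        design = synth.sweep_design(start=10, stop=20, step=2)
        inserts, _ = synth.simulate_mpra(
            design, lambda p, q: np.ones(len(p)),
            synth.MpraSimConfig(seed=15))
        rows_d, rows_c, rows_p = [], [], []
        for m in inserts:
            oid = f"{m.insert_id}:{m.barcode}"
            rows_d.append((oid, m.insert_id, m.promoter, m.motif,
                           m.planted_pos, m.barcode, m.replicate))
            rows_c.append([oid] + list(m.start_counts))
            rows_p.append((oid, m.plasmid_dna_count))
        (tmp_path / "d.tsv").write_text(
            pd.DataFrame(rows_d, columns=["oligo_id", "insert_id", "promoter",
                                          "motif", "planted_pos", "barcode",
                                          "replicate"]).to_csv(sep="\t",
                                                               index=False))
        cols = ["oligo_id"] + list(range(len(inserts[0].start_counts)))
        (tmp_path / "c.tsv").write_text(
            pd.DataFrame(rows_c, columns=cols).to_csv(sep="\t", index=False))
        (tmp_path / "p.tsv").write_text(
            pd.DataFrame(rows_p, columns=["oligo_id", "plasmid_dna_count"]
                         ).to_csv(sep="\t", index=False))
        back = mpra.read_insert_tables(tmp_path / "d.tsv", tmp_path / "c.tsv",
                                       tmp_path / "p.tsv")
        assert len(back) == len(inserts)
        assert np.allclose(back[0].start_counts, inserts[0].start_counts)
        assert back[0].plasmid_dna_count == inserts[0].plasmid_dna_count
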