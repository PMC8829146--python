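import numpy as np
import pytest

from etmnet.etm_finder import EtmParams, scan_lncrna
from etmnet.expression_specificity import aggregate_tissues, compute_tau, filter_de
from etmnet.synthetic_data import (
    CisSpec,
    PlantedEtm,
    PlantedTau,
    SynthConfig,
    TransSpec,
    build_etm_site,
    default_config,
    gen_annotation,
    gen_de_table,
    gen_expression,
    gen_sequences,
    simulate_all,
)


class TestDeterminism:
    def test_simulate_all_byte_identical_across_runs(self, tmp_path):
        p1 = simulate_all(default_config(42), tmp_path / "a")
        p2 = simulate_all(default_config(42), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_changes_sequences(self, tmp_path):
        a, _, _ = gen_sequences(default_config(1))
        b, _, _ = gen_sequences(default_config(2))
        assert [r.residues for r in a] != [r.residues for r in b]


class TestPlantedSites:
    def test_positive_passes_oracle_and_mismatch_outside_seed(self, rng):
        cfg = default_config(0)
        site, meta = build_etm_site(
            "UGACAGAAGAAAGAGAGCAC", PlantedEtm(0, 0, 0, n_mismatches=1), rng
        )
        assert meta["n_mismatches"] == 1
        assert all(not (2 <= p <= 8) for p in meta["mismatch_positions"])

    def test_rule1_negative_has_seed_mismatch(self, rng):
        _, meta = build_etm_site(
            "UGACAGAAGAAAGAGAGCAC", PlantedEtm(0, 0, 0, violate_rule=1), rng
        )
        (p,) = meta["mismatch_positions"]
        assert 2 <= p <= 8

    def test_rule2_negative_has_oversized_bulge(self, rng):
        params = EtmParams()
        _, meta = build_etm_site(
            "UGACAGAAGAAAGAGAGCAC", PlantedEtm(0, 0, 0, violate_rule=2), rng, params
        )
        assert meta["bulge_length"] == params.max_bulge + 1
        assert 9 <= meta["bulge_anchor"] <= 12

    def test_manifest_complete_one_entry_per_item(self):
        cfg = default_config(3)
        _, _, manifest = gen_sequences(cfg)
        assert len(manifest.etm_sites) == len(cfg.planted_etm_spec)

    def test_infeasible_site_rejected(self):
        cfg = SynthConfig(
            seed=0,
            n_mirnas=1,
            n_lncrnas=1,
            lncrna_length_range=(300, 300),
            planted_etm_spec=[PlantedEtm(0, 0, 290)],  # runs past the 3' end
        )
        with pytest.raises(ValueError, match="fit"):
            gen_sequences(cfg)

    def test_overbudget_spec_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            SynthConfig(
                n_mirnas=1, n_lncrnas=1,
                planted_etm_spec=[PlantedEtm(0, 0, 0, n_mismatches=2, n_wobbles=1)],
            )

    def test_positives_recovered_negatives_rejected(self):
        cfg = default_config(9)
        mirnas, lncrnas, manifest = gen_sequences(cfg)
        mir = {m.id: m for m in mirnas}
        lnc = {l.id: l for l in lncrnas}
        for entry in manifest.etm_sites:
            hits = scan_lncrna(mir[entry["mirna_id"]], lnc[entry["lncrna_id"]])
            overlapping = [
                h for h in hits
                if h[0].site_start < entry["site_end"]
                and entry["site_start"] < h[0].site_end
            ]
            if entry["is_positive"]:
                assert len(overlapping) == 1
                assert overlapping[0][0].site_start == entry["site_start"]
            else:
                assert overlapping == []


class TestExpression:
    def test_seeded_runs_identical(self):
        cfg = SynthConfig(seed=8, n_lncrnas=5, n_genes=5, n_mirnas=3)
        a, _, _ = gen_expression(cfg)
        b, _, _ = gen_expression(cfg)
        assert a.values.equals(b.values)

    def test_planted_fold_gives_high_tau_across_seeds(self):
        """A 1000-fold tissue-enriched feature scores tau >= 0.95 under
        10% replicate noise, checked by simulation across 100 seeds."""
        for seed in range(100):
            cfg = SynthConfig(
                seed=seed, n_lncrnas=2, n_genes=0, n_mirnas=0,
                planted_tau_spec=[PlantedTau("lnc000", "stamen", 1000.0)],
            )
            matrix, _, _ = gen_expression(cfg)
            (planted, background) = [
                compute_tau(p) for p in aggregate_tissues(matrix)
            ]
            assert planted.tau >= 0.95
            assert planted.peak_tissue == "stamen"

    def test_background_tau_stays_low(self):
        taus = []
        for seed in range(30):
            cfg = SynthConfig(seed=seed, n_lncrnas=4, n_genes=0, n_mirnas=0)
            matrix, _, _ = gen_expression(cfg)
            taus += [compute_tau(p).tau for p in aggregate_tissues(matrix)]
        assert np.quantile(taus, 0.95) < 0.5  # no planting -> far from 0.95

    def test_trans_pairs_hit_target_r(self):
        cfg = SynthConfig(
            seed=4, n_lncrnas=3, n_genes=3, n_mirnas=0,
            trans_r_spec=[TransSpec("lnc000", "gene000", 0.99),
                          TransSpec("lnc001", "gene001", -0.8)],
        )
        matrix, _, manifest = gen_expression(cfg)
        for entry in manifest.trans_pairs:
            x = matrix.values.loc[entry["lncrna_id"]].to_numpy()
            y = matrix.values.loc[entry["gene_id"]].to_numpy()
            r = float(np.corrcoef(x, y)[0, 1])
            assert abs(abs(r) - abs(entry["target_r"])) <= 0.02
            assert (r >= 0) == (entry["target_r"] >= 0)

    def test_invalid_target_r_rejected(self):
        with pytest.raises(ValueError, match="target_r"):
            SynthConfig(trans_r_spec=[TransSpec("a", "b", 1.0)])

    def test_noise_free_replicates_exact(self):
        cfg = SynthConfig(seed=0, n_lncrnas=2, n_genes=0, n_mirnas=0, noise_cv=0.0)
        matrix, _, _ = gen_expression(cfg)
        arr = matrix.values.to_numpy().reshape(2, 4, 3)
        assert (arr == arr[:, :, :1]).all()  # replicates identical


class TestAnnotation:
    def test_requested_distances_realized(self):
        feats, manifest = gen_annotation(default_config(0))
        by_id = {f.id: f for f in feats}
        for entry in manifest.cis_pairs:
            lnc, gene = by_id[entry["lncrna_id"]], by_id[entry["gene_id"]]
            assert lnc.chrom == gene.chrom
            gap = max(0, max(lnc.start, gene.start) - min(lnc.end, gene.end))
            assert gap == abs(entry["signed_distance_bp"])

    def test_distractors_far_or_elsewhere(self):
        cfg = default_config(0)
        feats, _ = gen_annotation(cfg, window_bp=100_000)
        lncs = [f for f in feats if f.feature_class.value == "lncRNA"]
        for g in (f for f in feats if f.id.startswith("distractor")):
            for lnc in lncs:
                if g.chrom == lnc.chrom:
                    gap = max(lnc.start, g.start) - min(lnc.end, g.end)
                    assert gap > 100_000

    def test_empty_spec_only_distractors(self):
        cfg = SynthConfig(n_genes=5)
        feats, manifest = gen_annotation(cfg)
        assert manifest.cis_pairs == []
        assert all(f.id.startswith("distractor") for f in feats)

    def test_duplicate_pair_rejected(self):
        cfg = SynthConfig(
            cis_distance_spec=[CisSpec("l", "g", 10), CisSpec("l", "g", 20)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            gen_annotation(cfg)


class TestDeTable:
    def test_filter_recovers_exactly_the_planted_set(self):
        cfg = SynthConfig(seed=6, n_de_planted=100, n_de_background=900)
        records, manifest = gen_de_table(cfg)
        assert len(records) == 1000
        kept = set(filter_de(records))
        assert kept == {e["feature_id"] for e in manifest.de_features}
        assert len(kept) == 100

    def test_boundary_rows_present_and_dropped(self):
        records, _ = gen_de_table(SynthConfig(seed=1))
        boundary = [r for r in records if r.padj == 0.05 or abs(r.log2fc) == 1.0]
        assert len(boundary) >= 3
        kept = set(filter_de(records))
        assert not kept & {r.feature_id for r in boundary}
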