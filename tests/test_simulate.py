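import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cnvkin.calls import read_call_table, read_rawcnv
from cnvkin.consensus import intersect_callers, merge_fragments
from cnvkin.simulate import (
    CNVSpec,
    CommonRegionSpec,
    ConfigError,
    SimConfig,
    generate_caller_views,
    generate_cohort,
    generate_reference_tracks,
    simulate_to_dir,
)


def truth_config(**overrides):
    base = dict(
        seed=1,
        n_families=10,
        n_unrelated=5,
        n_controls=5,
        cnv_truth=(
            CNVSpec("chr1", 10_050_001, 10_550_000, "deletion", ("FAM000_C1",)),
            CNVSpec("chr2", 8_000_001, 8_400_000, "duplication", ("UNR000", "FAM001_MO")),
        ),
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfigValidation:
    def test_negative_count(self):
        with pytest.raises(ConfigError, match="n_families"):
            SimConfig(n_families=-1)

    def test_rate_outside_unit(self):
        with pytest.raises(ConfigError, match="fp_rate"):
            SimConfig(fp_rate=1.5)

    def test_unknown_carrier(self):
        cfg = truth_config(cnv_truth=(CNVSpec("chr1", 1, 30_000, "deletion", ("NOBODY",)),))
        with pytest.raises(ConfigError, match="NOBODY"):
            generate_cohort(cfg)

    def test_bad_common_freq(self):
        with pytest.raises(ConfigError, match="frequency"):
            SimConfig(common_region_specs=(CommonRegionSpec("chr1", 1, 100, 1.5),))


class TestDeterminism:
    def test_identical_bundles_same_seed(self):
        cfg = truth_config()
        b1, t1 = generate_cohort(cfg)
        b2, t2 = generate_cohort(cfg)
        for attr in ("pedigree", "pcs", "dosages", "weights", "phenotypes", "ibd"):
            pd.testing.assert_frame_equal(getattr(b1, attr), getattr(b2, attr))
        assert t1.true_relationships == t2.true_relationships
        assert [c.key for c in t1.true_cnvs] == [c.key for c in t2.true_cnvs]

    def test_byte_identical_files(self, tmp_path):
        cfg = truth_config(fragmentation_rate=0.5, boundary_jitter_bp=500, fp_rate=0.5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(cfg, d1)
        simulate_to_dir(cfg, d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_different_seed_differs(self):
        b1, _ = generate_cohort(truth_config(seed=1))
        b2, _ = generate_cohort(truth_config(seed=2))
        assert not b1.phenotypes["pgs"].equals(b2.phenotypes["pgs"])


class TestCohort:
    def test_empty_cohort(self):
        cfg = SimConfig(n_families=0, n_unrelated=0, n_controls=0)
        bundle, truth = generate_cohort(cfg)
        assert bundle.pedigree.empty
        assert truth.true_cnvs == [] and truth.samples == []

    def test_trio_structure(self):
        bundle, _ = generate_cohort(truth_config())
        ped = bundle.pedigree
        children = ped[ped["father_id"] != ""]
        for row in children.itertuples(index=False):
            assert row.father_id in set(ped["sample_id"])
            assert row.mother_id in set(ped["sample_id"])

    def test_children_mendelian_consistent(self):
        bundle, _ = generate_cohort(truth_config())
        ped = bundle.pedigree
        d = bundle.dosages
        for row in ped[ped["father_id"] != ""].itertuples(index=False):
            c = d.loc[row.sample_id].to_numpy()
            f = d.loc[row.father_id].to_numpy()
            m = d.loc[row.mother_id].to_numpy()
            half = {0: {0}, 1: {0, 1}, 2: {1}}
            for ci, fi, mi in zip(c, f, m):
                assert ci in {a + b for a in half[fi] for b in half[mi]}

    def test_injected_mendel_errors_counted(self):
        cfg = truth_config(mendelian_error_rate=0.05, n_variants=400)
        bundle, truth = generate_cohort(cfg)
        assert sum(truth.mendel_errors.values()) > 0
        # recompute one child's error rate from the emitted panel
        from cnvkin.kinship import mendelian_error_rate

        ped = bundle.pedigree
        child = ped[ped["father_id"] != ""].iloc[0]
        rate = mendelian_error_rate(
            bundle.dosages.loc[child["sample_id"]],
            bundle.dosages.loc[child["father_id"]],
            bundle.dosages.loc[child["mother_id"]],
        )
        assert rate == pytest.approx(truth.mendel_errors[child["sample_id"]] / cfg.n_variants)

    def test_group_shift_realized(self):
        cfg = SimConfig(seed=7, n_families=400, n_unrelated=0, n_controls=400,
                        group_pgs_shifts={"ASD": 0.3})
        bundle, _ = generate_cohort(cfg)
        ph = bundle.phenotypes
        asd = ph.loc[ph["group"] == "ASD", "pgs"]
        ctl = ph.loc[ph["group"] == "CTL", "pgs"]
        diff = asd.mean() - ctl.mean()
        se = np.sqrt(asd.var(ddof=1) / len(asd) + ctl.var(ddof=1) / len(ctl))
        assert abs(diff - 0.3) < 3 * se

    def test_planted_r2_in_phenotype(self):
        cfg = SimConfig(seed=3, n_families=0, n_unrelated=2000, n_controls=0, pgs_r2=0.25)
        bundle, truth = generate_cohort(cfg)
        r = np.corrcoef(bundle.phenotypes["pgs"], bundle.phenotypes["phenotype"])[0, 1]
        assert truth.true_r2 == 0.25
        assert r**2 == pytest.approx(0.25, abs=0.05)

    def test_ibd_invariants_and_relationships(self):
        from cnvkin.kinship import classify_pairs

        bundle, truth = generate_cohort(truth_config(quad_fraction=0.5, seed=11))
        got = classify_pairs(bundle.ibd)
        for row in got.itertuples(index=False):
            want = truth.true_relationships[(row.id1, row.id2)]
            assert row.relationship == want

    def test_pc_coords_near_centroids(self):
        cfg = SimConfig(seed=5, n_families=0, n_unrelated=200, n_controls=0,
                        population_fractions={"EUR": 0.5, "SAS": 0.5})
        bundle, _ = generate_cohort(cfg)
        from cnvkin.kinship import assign_ancestry
        from cnvkin.simulate import POPULATIONS

        pops = {k: v for k, v in POPULATIONS.items()}
        labels = []
        for row in bundle.pcs.itertuples(index=False):
            labels.append(assign_ancestry(row.sample_id, (row.pc1, row.pc2), pops).label)
        assert set(labels) == {"EUR", "SAS"}
        assert labels.count("EUR") > 50 and labels.count("SAS") > 50


class TestCallerViews:
    def test_noise_free_views_equal_truth(self):
        cfg = truth_config()
        _, truth = generate_cohort(cfg)
        va, vb, _ = generate_caller_views(truth, cfg)
        want = sorted(c.key for c in truth.true_cnvs)
        assert sorted(c.key for c in va) == want
        assert sorted(c.key for c in vb) == want

    def test_full_fragmentation_remerges_to_true_span(self):
        cfg = truth_config(fragmentation_rate=1.0, max_fragment_gap_bp=50_000)
        _, truth = generate_cohort(cfg)
        va, vb, _ = generate_caller_views(truth, cfg)
        for views in (va, vb):
            for cnv in truth.true_cnvs:
                frags = [v for v in views
                         if v.sample_id == cnv.sample_id and v.chrom == cnv.chrom
                         and v.type == cnv.type]
                assert len(frags) >= 2
                merged = merge_fragments(frags, trigger_count=0,
                                         max_gap_bp=cfg.max_fragment_gap_bp)
                assert len(merged) == 1
                assert (merged[0].start, merged[0].end) == (cnv.start, cnv.end)

    def test_common_region_carrier_count(self):
        spec = CommonRegionSpec("chr3", 1_000_000, 1_050_000, 0.5)
        cfg = SimConfig(seed=9, n_families=0, n_unrelated=60, n_controls=0,
                        common_region_specs=(spec,))
        _, truth = generate_cohort(cfg)
        n = len(truth.common_carriers[spec])
        # binomial(60, 0.5): mean 30, SD ~3.9
        assert 30 - 4 * 3.9 <= n <= 30 + 4 * 3.9
        va, vb, _ = generate_caller_views(truth, cfg)
        assert sum(v.chrom == "chr3" for v in va) == n
        assert sum(v.chrom == "chr3" for v in vb) == n

    def test_false_positives_caller_private(self):
        cfg = truth_config(fp_rate=1.0)
        _, truth = generate_cohort(cfg)
        va, vb, _ = generate_caller_views(truth, cfg)
        true_keys = {c.key for c in truth.true_cnvs}
        fp_a = [v for v in va if v.key not in true_keys]
        fp_b = [v for v in vb if v.key not in true_keys]
        assert fp_a and fp_b
        # consensus wipes all false positives
        cons = intersect_callers(va, vb)
        assert sorted(c.key for c in cons) == sorted(true_keys)

    def test_qc_outliers_planted(self):
        from cnvkin.filters import SampleIntensityQC, sample_qc

        cfg = truth_config(n_qc_outliers=2)
        _, truth = generate_cohort(cfg)
        _, _, qc = generate_caller_views(truth, cfg)
        stats = [SampleIntensityQC(r.sample_id, r.LRRSD, r.BAFSD, r.GCWF)
                 for r in qc.itertuples(index=False)]
        out = sample_qc(stats)
        failed = set(out.loc[~out["passed"], "sample_id"])
        assert set(qc["sample_id"].iloc[:2]) <= failed


class TestReferenceTracks:
    def test_cytobands_tile_chromosomes(self):
        cfg = SimConfig()
        cyto = generate_reference_tracks(cfg)["cytobands"]
        for chrom, length in cfg.chrom_lengths.items():
            sub = cyto[cyto["chrom"] == chrom].sort_values("start")
            assert sub.iloc[0]["start"] == 1
            assert sub.iloc[-1]["end"] == length
            gaps = sub["start"].iloc[1:].to_numpy() - sub["end"].iloc[:-1].to_numpy()
            assert (gaps == 1).all()

    def test_exons_lie_within_genes(self):
        tracks = generate_reference_tracks(SimConfig())
        for gene in tracks["genes"][:200]:
            for s, e in gene.exons:
                assert gene.gene_start <= s <= e <= gene.gene_end


class TestRoundTrip:
    def test_emitted_files_reload_exactly(self, tmp_path):
        cfg = truth_config(fragmentation_rate=0.3, fp_rate=0.3, boundary_jitter_bp=100)
        bundle, truth = generate_cohort(cfg)
        va, vb, qc = generate_caller_views(truth, cfg)
        simulate_to_dir(cfg, tmp_path)

        back_a = read_rawcnv(tmp_path / "caller_a.rawcnv")
        assert sorted(c.key for c in back_a) == sorted(c.key for c in va)
        assert sorted((c.n_snps, c.confidence) for c in back_a) == sorted(
            (c.n_snps, round(c.confidence, 3)) for c in va
        )
        back_b = read_call_table(tmp_path / "caller_b.tsv")
        assert sorted(c.key for c in back_b) == sorted(c.key for c in vb)

        for name, frame in (
            ("pedigree.tsv", bundle.pedigree),
            ("pcs.tsv", bundle.pcs),
            ("phenotypes.tsv", bundle.phenotypes),
            ("ibd.tsv", bundle.ibd),
            ("weights.tsv", bundle.weights),
        ):
            reread = pd.read_csv(tmp_path / name, sep="\t", keep_default_na=False,
                                 dtype=str)
            original = frame.astype(str).replace("nan", "")
            pd.testing.assert_frame_equal(
                reread.reset_index(drop=True), original.reset_index(drop=True),
                check_dtype=False,
            )
        dos = pd.read_csv(tmp_path / "dosages.tsv", sep="\t", index_col=0)
        pd.testing.assert_frame_equal(dos, bundle.dosages, check_dtype=False,
                                      check_index_type=False)
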