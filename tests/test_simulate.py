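import pytest

from methsilence.simulate import (
    ConfigError,
    SimulationConfig,
    plant_ground_truth,
    read_ground_truth,
    simulate_annotation,
    simulate_expression,
    simulate_methylome,
    simulate_sirna,
    write_ground_truth,
)

from conftest import small_config


def meth_cfg(seed=5):
    # TE-rich single chromosome for generator self-checks
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chromosome_length=50_000,
        n_genes=0,
        n_tes=40,
        te_length=800,
        n_dmrs_suvh29=8,
        n_dmrs_shared=2,
        n_dmrs_morc6_specific=0,
        n_up_tes={"suvh29": 0, "morc6": 0},
        n_up_tes_shared=0,
        n_up_genes={"suvh29": 0, "morc6": 0},
        n_up_genes_shared=0,
        n_meth_promoter_genes=0,
    )


class TestAnnotation:
    def test_features_are_disjoint_and_counted(self):
        cfg = small_config()
        feats = simulate_annotation(cfg)
        assert sum(f.kind == "gene" for f in feats) == cfg.n_genes
        assert sum(f.kind == "TE" for f in feats) == cfg.n_tes
        by_chrom = {}
        for f in feats:
            by_chrom.setdefault(f.chrom, []).append(f)
        for group in by_chrom.values():
            group.sort(key=lambda f: f.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start
            assert group[-1].end <= cfg.chromosome_length

    def test_same_seed_reproduces_coordinates(self):
        assert simulate_annotation(small_config()) == simulate_annotation(small_config())

    def test_zero_features_give_empty_annotation(self):
        cfg = meth_cfg()
        cfg.n_tes = 0
        cfg.n_dmrs_suvh29 = cfg.n_dmrs_shared = 0
        assert simulate_annotation(cfg) == []

    def test_overfull_chromosome_is_a_config_error(self):
        cfg = small_config()
        cfg.chromosome_length = 10_000
        with pytest.raises(ConfigError, match="exceed"):
            simulate_annotation(cfg)


class TestGroundTruth:
    def test_planted_dmrs_lie_inside_tes(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        tes = [f for f in ann if f.kind == "TE"]
        for d in truth.dmrs:
            assert any(
                t.chrom == d.chrom and t.start <= d.start and d.end <= t.end for t in tes
            )
        assert len(truth.dmrs_for("suvh29")) == cfg.n_dmrs_suvh29
        assert (
            len(truth.dmrs_for("morc6"))
            == cfg.n_dmrs_shared + cfg.n_dmrs_morc6_specific
        )

    def test_planted_up_features_exist_and_counts_match(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        ids = {f.feature_id for f in ann}
        kind = {f.feature_id: f.kind for f in ann}
        for g in ("suvh29", "morc6"):
            assert set(truth.up_features[g]) <= ids
            n_te = sum(kind[f] == "TE" for f in truth.up_features[g])
            n_gene = sum(kind[f] == "gene" for f in truth.up_features[g])
            assert n_te == cfg.n_up_tes[g]
            assert n_gene == cfg.n_up_genes[g]
        common_te = {
            f for f in truth.up_features["suvh29"]
            if kind[f] == "TE" and f in truth.up_features["morc6"]
        }
        assert len(common_te) == cfg.n_up_tes_shared

    def test_up_features_disjoint_from_dmr_tes(self):
        """Expression and methylation effects are planted on different TEs."""
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        dmr_spans = [(d.chrom, d.start, d.end) for d in truth.dmrs]
        by_id = {f.feature_id: f for f in ann}
        for g, planted in truth.up_features.items():
            for fid in planted:
                f = by_id[fid]
                for chrom, s, e in dmr_spans:
                    assert not (f.chrom == chrom and f.start < e and s < f.end)

    def test_roundtrip_through_tsv(self, tmp_path):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        p = tmp_path / "truth.tsv"
        write_ground_truth(truth, p)
        back = read_ground_truth(p)
        assert back.dmrs == truth.dmrs
        assert back.up_features == truth.up_features
        assert back.sirna_labels == truth.sirna_labels
        assert back.methylated_promoters == truth.methylated_promoters


class TestMethylome:
    def test_deterministic_under_seed(self):
        cfg = meth_cfg()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        a = simulate_methylome(cfg, ann, truth, "WT")
        b = simulate_methylome(cfg, ann, truth, "WT")
        assert a == b

    def test_empirical_level_matches_configured_baseline(self):
        cfg = meth_cfg()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        sites = simulate_methylome(cfg, ann, truth, "WT")
        te_spans = [(f.start, f.end) for f in ann]
        m = u = n = 0
        for s in sites:
            if s.context != "CG":
                continue
            if any(a <= s.start < b for a, b in te_spans):
                m += s.count_meth
                u += s.count_unmeth
                n += 1
        assert n > 1000
        assert m / (m + u) == pytest.approx(cfg.baseline[("TE", "CG")], abs=0.02)

    def test_planted_delta_shifts_affected_genotype_only(self):
        cfg = meth_cfg()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        d = truth.dmrs_for("suvh29")[0]

        def chh_level(genotype):
            m = u = 0
            for s in simulate_methylome(cfg, ann, truth, genotype):
                if s.context == "CHH" and d.start <= s.start < d.end:
                    m += s.count_meth
                    u += s.count_unmeth
            return m / (m + u)

        wt = chh_level("WT")
        mut = chh_level("suvh29")
        assert wt == pytest.approx(cfg.baseline[("TE", "CHH")], abs=0.06)
        # baseline 0.30 + planted delta -0.30 -> generating level 0
        assert mut == pytest.approx(0.0, abs=0.02)

    def test_zero_coverage_mean_yields_empty_report(self):
        cfg = meth_cfg()
        cfg.coverage_mean = 0.0
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        assert simulate_methylome(cfg, ann, truth, "WT") == []

    def test_unknown_genotype_rejected(self):
        cfg = meth_cfg()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        with pytest.raises(ConfigError):
            simulate_methylome(cfg, ann, truth, "nrpd1")


class TestExpression:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        assert simulate_expression(cfg, ann, truth, "WT") == simulate_expression(
            cfg, ann, truth, "WT"
        )

    def test_planted_fold_change_recovered_in_expectation(self):
        """Mean mutant/WT count ratio over replicate seeds approaches the
        planted fold (generator self-check)."""
        totals_wt = totals_mut = 0.0
        for seed in range(60):
            cfg = small_config(seed=seed)
            ann = simulate_annotation(cfg)
            truth = plant_ground_truth(cfg, ann)
            planted = set(truth.up_features["suvh29"])
            wt, _ = simulate_expression(cfg, ann, truth, "WT")
            mut, _ = simulate_expression(cfg, ann, truth, "suvh29")
            totals_wt += sum(wt[f] for f in planted)
            totals_mut += sum(mut[f] for f in planted)
        assert totals_mut / totals_wt == pytest.approx(small_config().up_fold, rel=0.15)

    def test_null_features_have_equal_means_across_genotypes(self):
        totals = {"WT": 0.0, "morc6": 0.0}
        for seed in range(40):
            cfg = small_config(seed=seed)
            ann = simulate_annotation(cfg)
            truth = plant_ground_truth(cfg, ann)
            planted = set(truth.up_features["morc6"])
            for g in totals:
                counts, _ = simulate_expression(cfg, ann, truth, g)
                totals[g] += sum(v for f, v in counts.items() if f not in planted)
        assert totals["morc6"] / totals["WT"] == pytest.approx(1.0, rel=0.05)


class TestSiRNA:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        a, _ = simulate_sirna(cfg, ann, truth, "nrpd1")
        b, _ = simulate_sirna(cfg, ann, truth, "nrpd1")
        assert a.equals(b)

    def test_pol_iv_dependent_features_collapse_in_nrpd1(self):
        wt_total = mut_total = 0.0
        for seed in range(20):
            cfg = small_config(seed=seed)
            ann = simulate_annotation(cfg)
            truth = plant_ground_truth(cfg, ann)
            wt, _ = simulate_sirna(cfg, ann, truth, "WT")
            mut, _ = simulate_sirna(cfg, ann, truth, "nrpd1")
            wt_total += wt["24"].sum()
            mut_total += mut["24"].sum()
        # all planted siRNA classes are Pol IV-dependent
        assert mut_total / wt_total == pytest.approx(0.02, rel=0.15)

    def test_pol_v_independent_features_retained_in_nrpe1(self):
        cfg = small_config()
        ann = simulate_annotation(cfg)
        truth = plant_ground_truth(cfg, ann)
        wt, _ = simulate_sirna(cfg, ann, truth, "WT")
        mut, _ = simulate_sirna(cfg, ann, truth, "nrpe1")
        indep = [f for f, (_, v) in truth.sirna_labels.items() if not v]
        wt_sum = wt.set_index("feature_id").loc[indep, "24"].sum()
        mut_sum = mut.set_index("feature_id").loc[indep, "24"].sum()
        assert mut_sum / wt_sum == pytest.approx(1.0, abs=0.1)
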