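import numpy as np
import pandas as pd
import pytest

from refstab import (
    ExpressionMatrix,
    GeneAnnotation,
    InputError,
    ScreenConfig,
    aggregate_and_confirm,
    compute_fold_changes,
    filter_probes,
    run_screen,
    simulate_screen_bundle,
)


def matrix(values: dict[str, list[float]], genes: dict[str, str],
           time_points: list[float]) -> ExpressionMatrix:
    cols, meta_rows = [], []
    counters: dict[float, int] = {}
    for tp in time_points:
        counters[tp] = counters.get(tp, 0) + 1
        cid = f"c{len(cols)}"
        cols.append(cid)
        meta_rows.append((cid, tp, counters[tp]))
    meta = pd.DataFrame(meta_rows, columns=["condition_id", "time_point",
                                            "replicate"]).set_index("condition_id")
    return ExpressionMatrix(
        pd.DataFrame(values, index=cols).T,
        pd.Series(genes),
        meta,
    )


DISCOVERY_TPS = [0, 0, 1, 1, 5, 5]


class TestComputeFoldChanges:
    def test_replicates_averaged_before_ratio(self):
        m = matrix({"p1": [100, 102, 202, 202, 101, 101]}, {"p1": "G"}, DISCOVERY_TPS)
        fct = compute_fold_changes(m, [(1, 0)])
        assert fct.group_means.loc["p1", 0] == pytest.approx(101)
        assert fct.fc.loc["p1", "fc_1/0"] == pytest.approx(2.0)

    def test_constant_probe_has_unit_fc_everywhere(self):
        m = matrix({"p1": [150] * 6}, {"p1": "G"}, DISCOVERY_TPS)
        fct = compute_fold_changes(m, [(1, 0), (5, 0), (5, 1)])
        assert np.allclose(fct.fc.loc["p1"], 1.0)

    def test_zero_denominator_flags_undefined_fc(self):
        m = matrix({"p1": [0, 0, 50, 50, 60, 60]}, {"p1": "G"}, DISCOVERY_TPS)
        fct = compute_fold_changes(m, [(1, 0)])
        assert np.isnan(fct.fc.loc["p1", "fc_1/0"])
        assert fct.undefined.loc["p1", "fc_1/0"]

    def test_absent_time_point_rejected(self):
        m = matrix({"p1": [1, 1, 1, 1, 1, 1]}, {"p1": "G"}, DISCOVERY_TPS)
        with pytest.raises(InputError, match="absent time point"):
            compute_fold_changes(m, [(7, 0)])

    def test_chained_contrast_consistency(self):
        """fc_5/1 equals fc_5/0 / fc_1/0 when built from the same means."""
        rng = np.random.default_rng(4)
        vals = {f"p{i}": rng.uniform(100, 1000, 6).tolist() for i in range(5)}
        m = matrix(vals, {f"p{i}": f"G{i}" for i in range(5)}, DISCOVERY_TPS)
        fct = compute_fold_changes(m, [(1, 0), (5, 0), (5, 1)])
        assert np.allclose(fct.fc["fc_5/1"], fct.fc["fc_5/0"] / fct.fc["fc_1/0"])


def discovery_fixture():
    """Probes engineered to fall at each cascade stage."""
    vals = {
        # G1: two clean probes, survives everything
        "g1a": [500, 500, 500, 500, 500, 500],
        "g1b": [800, 800, 800, 800, 800, 800],
        # boundary probe: fc exactly 1.01 at day 1, then back to 1.0 at day 5
        "g2a": [100000, 100000, 101000, 101000, 100000, 100000],
        "g2b": [500, 500, 500, 500, 500, 500],
        # stage-1 casualty: fc_1/0 = 1.5
        "g3a": [200, 200, 300, 300, 200, 200],
        # stage-4 casualty: flat but one group mean = 99
        "g4a": [99, 99, 99, 99, 99, 99],
        # stage-5 casualty: clean but its gene has only this probe
        "g5a": [500, 500, 500, 500, 500, 500],
    }
    genes = {"g1a": "G1", "g1b": "G1", "g2a": "G2", "g2b": "G2",
             "g3a": "G3", "g4a": "G4", "g5a": "G5"}
    return matrix(vals, genes, DISCOVERY_TPS)


class TestFilterProbes:
    def setup_method(self):
        self.fct = compute_fold_changes(discovery_fixture(), [(1, 0), (5, 0), (5, 1)])

    def test_stage_casualties_and_boundaries(self):
        report = filter_probes(self.fct)
        names = [s.name for s in report.stages]
        assert len(names) == 6
        survivors = [set(s.probe_ids) for s in report.stages]
        assert "g3a" not in survivors[1]          # fc_1/0 window
        assert "g2a" in survivors[1]              # 1.01 inclusive boundary
        # g2a has fc_5/1 = 1/1.01 ~ 0.990099 -> still inside the window
        assert "g2a" in survivors[3]
        assert "g4a" not in survivors[4]          # min-signal
        assert "g5a" not in survivors[5]          # single-probe gene
        assert report.surviving_genes() == ["G1", "G2"]

    def test_counts_monotone_non_increasing(self):
        report = filter_probes(self.fct)
        counts = [s.n_probes for s in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_survivors_nested(self):
        report = filter_probes(self.fct)
        stages = [set(s.probe_ids) for s in report.stages]
        assert all(b <= a for a, b in zip(stages, stages[1:]))

    def test_scale_equivariance_except_min_signal(self):
        """Scaling all fluorescence by a constant leaves every fc stage
        unchanged; only the min-signal stage can differ."""
        scaled = discovery_fixture()
        scaled = ExpressionMatrix(scaled.fluorescence * 7.0, scaled.probe2gene,
                                  scaled.condition_meta)
        fct2 = compute_fold_changes(scaled, [(1, 0), (5, 0), (5, 1)])
        r1, r2 = filter_probes(self.fct), filter_probes(fct2)
        for s1, s2 in zip(r1.stages[:4], r2.stages[:4]):
            assert s1.probe_ids == s2.probe_ids

    def test_empty_input_rejected(self):
        empty = compute_fold_changes(discovery_fixture(), [(1, 0), (5, 0), (5, 1)])
        empty.fc = empty.fc.iloc[0:0]
        with pytest.raises(InputError, match="empty"):
            filter_probes(empty)


def confirmation_fixture(fc7: dict[str, float]):
    """One probe per (gene, suffix); fc_7/0 set per probe via day-7 level."""
    vals, genes = {}, {}
    for probe, fc in fc7.items():
        vals[probe] = [1000, 1000, 1000 * fc, 1000 * fc]
        genes[probe] = probe.split("_")[0]
    return matrix(vals, genes, [0, 0, 7, 7])


class TestAggregateAndConfirm:
    def run(self, fc7, annotation=None, config=None):
        fct = compute_fold_changes(discovery_fixture(), [(1, 0), (5, 0), (5, 1)])
        report = filter_probes(fct, config)
        conf = compute_fold_changes(confirmation_fixture(fc7), [(7, 0)])
        return aggregate_and_confirm(report, fct, conf, annotation, config)

    def test_clean_genes_retained(self):
        final = self.run({"G1_a": 1.0, "G1_b": 1.0, "G2_a": 1.0, "G2_b": 1.0})
        assert final.candidate_genes() == ["G1", "G2"]

    def test_mean_outside_gene_window_excluded(self):
        final = self.run({"G1_a": 1.03, "G1_b": 1.03, "G2_a": 1.0, "G2_b": 1.0})
        assert final.candidate_genes() == ["G2"]
        assert final.candidates.loc["G1", "mean_fc_7/0"] == pytest.approx(1.03)

    def test_probe_spread_above_sd_gate_excluded(self):
        # mean 1.0 (in window) but sample SD ~ 0.099 > 0.05
        final = self.run({"G1_a": 1.07, "G1_b": 0.93, "G2_a": 1.0, "G2_b": 1.0})
        assert final.candidate_genes() == ["G2"]

    def test_single_probe_confirmation_sd_is_zero(self):
        final = self.run({"G1_a": 1.0, "G2_a": 1.0, "G2_b": 1.0})
        assert final.candidates.loc["G1", "sd_fc_7/0"] == 0.0
        assert "G1" in final.candidate_genes()

    def test_pseudogene_flag_excludes_otherwise_clean_gene(self):
        ann = GeneAnnotation(pd.DataFrame(
            {"accession": ["x", "y"], "has_pseudogene": [True, False],
             "intron_spanning": [True, True]},
            index=pd.Index(["G1", "G2"], name="symbol")))
        final = self.run({"G1_a": 1.0, "G1_b": 1.0, "G2_a": 1.0, "G2_b": 1.0},
                         annotation=ann)
        assert final.candidate_genes() == ["G2"]

    def test_gene_missing_from_confirmation_reported_not_passed(self):
        final = self.run({"G1_a": 1.0, "G1_b": 1.0})
        assert final.missing_from_confirmation == ["G2"]
        assert final.candidate_genes() == ["G1"]

    def test_unannotated_gene_excluded_only_in_strict_mode(self):
        ann = GeneAnnotation(pd.DataFrame(
            {"accession": ["y"], "has_pseudogene": [False],
             "intron_spanning": [True]}, index=pd.Index(["G2"], name="symbol")))
        fc7 = {"G1_a": 1.0, "G1_b": 1.0, "G2_a": 1.0, "G2_b": 1.0}
        lax = self.run(fc7, annotation=ann)
        assert lax.candidate_genes() == ["G1", "G2"]
        assert lax.unannotated_genes == ["G1"]
        strict = self.run(fc7, annotation=ann,
                          config=ScreenConfig(strict_annotation=True))
        assert strict.candidate_genes() == ["G2"]

    def test_discovery_sd_uses_all_probes_of_gene(self):
        """A probe that failed the per-probe stages still enters the
        gene-level mean/SD over the discovery contrasts."""
        fct = compute_fold_changes(discovery_fixture(), [(1, 0), (5, 0), (5, 1)])
        report = filter_probes(fct)
        conf = compute_fold_changes(
            confirmation_fixture({"G1_a": 1.0, "G1_b": 1.0, "G2_a": 1.0, "G2_b": 1.0}),
            [(7, 0)])
        final = aggregate_and_confirm(report, fct, conf)
        # G2's failed-stage probe g2a (fc_1/0 = 1.01) contributes to the SD
        expected_sd = np.std([1.01, 1.0], ddof=1)
        assert final.candidates.loc["G2", "sd_fc_1/0"] == pytest.approx(expected_sd)


class TestPlantedBundle:
    def test_planted_clean_set_recovered_exactly(self):
        bundle = simulate_screen_bundle(seed=17)
        report = run_screen(bundle.discovery, bundle.confirmation,
                            bundle.annotation, extra=bundle.extra)
        assert report.candidate_genes() == bundle.expected_candidates
        counts = [s.n_probes for s in report.stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_each_plant_dies_at_its_stage(self):
        bundle = simulate_screen_bundle(seed=17)
        report = run_screen(bundle.discovery, bundle.confirmation,
                            bundle.annotation, extra=bundle.extra)
        genes_per_stage = [set(bundle.discovery.probe2gene[p]
                               for p in s.probe_ids) for s in report.stages]
        reg = set(bundle.truth.index[bundle.truth == "regulated"])
        assert reg & genes_per_stage[1] == set()
        assert "STAB1" in genes_per_stage[3] and "STAB1" not in genes_per_stage[4]
        assert "STAB2" in genes_per_stage[4] and "STAB2" not in genes_per_stage[5]
        for gene in ("STAB3", "STAB4", "STAB5"):   # confirmation-stage plants
            assert gene in genes_per_stage[5] and gene not in genes_per_stage[6]

    def test_extra_study_is_descriptive_by_default(self):
        bundle = simulate_screen_bundle(seed=17)
        report = run_screen(bundle.discovery, bundle.confirmation,
                            bundle.annotation, extra=bundle.extra)
        assert "mean_fc_3/0" in report.candidates.columns
        assert "mean_fc_14/0" in report.candidates.columns
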