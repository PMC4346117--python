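"""Clonal-evolution simulator: planted truth, noise model, determinism."""

import numpy as np
import pandas as pd
import pytest

import heteroclone as hc


class TestSimulateTruth:
    def test_common_loci_present_everywhere(self, small_params):
        truth = hc.simulate_truth(small_params)
        common = [l for l, (k, _) in truth.locus_category.items() if k == "common"]
        assert len(common) == small_params.n_common
        assert (truth.presence[common].sum(axis=0) == len(truth.samples)).all()

    def test_sample_specific_column_sums(self):
        params = hc.SimParams(samples_per_cluster=(3, 2, 2),
                              n_sample_specific_per_sample=2, seed=3)
        truth = hc.simulate_truth(params)
        private = [l for l, (k, _) in truth.locus_category.items()
                   if k == "sample_specific"]
        assert len(private) == 2 * 7
        assert (truth.presence[private].sum(axis=0) == 1).all()

    def test_category_conservation(self, small_params):
        truth = hc.simulate_truth(small_params)
        p = small_params
        expected = (p.n_common + sum(p.n_shared.values())
                    + sum(p.n_cluster_specific.values())
                    + p.n_sample_specific_per_sample * len(truth.samples))
        assert len(truth.presence.columns) == expected

    def test_vaf_zero_where_absent_and_purity_scaled(self, small_params):
        truth = hc.simulate_truth(small_params)
        vaf = truth.true_vaf.to_numpy()
        pres = truth.presence.to_numpy()
        assert (vaf[pres == 0] == 0).all()
        assert np.allclose(vaf[pres == 1], small_params.purity / 2)

    def test_clusters_are_clades_in_true_tree(self, small_params):
        truth = hc.simulate_truth(small_params)
        newick = truth.true_tree.to_newick()
        from conftest import rf_distance
        # every cluster must be a clade: compare against a tree with the same
        # cluster clades by checking monophyly via leaf sets of internal nodes
        clades = []

        def walk(node):
            if not node.is_leaf:
                clades.append(frozenset(node.leaf_names()))
                for c in node.children:
                    walk(c)

        walk(truth.true_tree.root)
        for members in truth.scheme().clusters.values():
            if len(members) > 1:
                assert frozenset(members) in clades

    def test_seed_determinism(self, small_params):
        t1 = hc.simulate_truth(small_params)
        t2 = hc.simulate_truth(small_params)
        assert t1.presence.equals(t2.presence)
        assert t1.locus_category == t2.locus_category
        assert t1.true_segments == t2.true_segments

    def test_rejects_degenerate_designs(self):
        with pytest.raises(ValueError):
            hc.SimParams(cluster_labels=("only",), samples_per_cluster=(3,))
        with pytest.raises(ValueError):
            hc.SimParams(samples_per_cluster=(3, 0, 2))
        with pytest.raises(ValueError):
            hc.SimParams(fn_rate=1.5)

    def test_params_yaml_round_trip(self, small_params, tmp_path):
        p = tmp_path / "params.yaml"
        small_params.to_yaml(p)
        back = hc.SimParams.from_yaml(p)
        assert back == small_params


class TestObservedCalls:
    def test_noiseless_identity(self, small_params):
        import dataclasses
        params = dataclasses.replace(small_params, fn_rate=0.0, fp_rate=0.0)
        truth = hc.simulate_truth(params)
        calls, _ = hc.simulate_observed_calls(truth, params)
        mat = hc.build_binary_matrix(calls, truth.samples)
        assert mat.df[truth.presence.columns].equals(truth.presence)
        assert set(mat.loci) == set(truth.presence.columns)

    def test_dropout_count_within_binomial_band(self):
        """>= 10,000 present entries: dropped count within 3 sigma of n*fn."""
        params = hc.SimParams(
            samples_per_cluster=(6, 3, 2), n_common=1000,
            n_shared={("P1", "M"): 0}, n_cluster_specific={},
            n_sample_specific_per_sample=0, fp_rate=0.0, fp_locus_pool=0,
            seed=7)
        truth = hc.simulate_truth(params)
        n_present = int(truth.presence.to_numpy().sum())
        assert n_present == 11_000
        calls, _ = hc.simulate_observed_calls(truth, params)
        mat = hc.build_binary_matrix(calls, truth.samples)
        observed = mat.df.reindex(columns=truth.presence.columns, fill_value=0)
        dropped = int((truth.presence.to_numpy() - observed.to_numpy() == 1).sum())
        mean, sd = n_present * 0.06, np.sqrt(n_present * 0.06 * 0.94)
        assert abs(dropped - mean) <= 3 * sd

    def test_planted_amp_segment_in_every_carrier(self, small_params):
        truth = hc.simulate_truth(small_params)
        _, segments = hc.simulate_observed_calls(truth, small_params)
        for branch, segs in truth.true_segments.items():
            carriers = truth.branch_samples[branch]
            for chrom, start, end, direction in segs:
                for s in carriers:
                    row = segments[(segments["sample"] == s)
                                   & (segments["chrom"] == chrom)
                                   & (segments["start"] == start)
                                   & (segments["end"] == end)]
                    assert len(row) == 1
                    log2 = row["log2_ratio"].iloc[0]
                    if direction == "amp":
                        assert log2 >= 0.2
                    else:
                        assert log2 <= -0.2

    def test_calls_satisfy_table_invariants(self, small_params):
        truth = hc.simulate_truth(small_params)
        calls, _ = hc.simulate_observed_calls(truth, small_params)
        assert (calls["alt_count"] <= calls["depth"]).all()
        assert (calls["alt_count"] >= 1).all()
        assert not calls.duplicated(["sample", "chrom", "pos", "ref", "alt"]).any()

    def test_noise_calibration_over_seeds(self):
        """Realized FN/FP rates over 50 seeds inside 99% binomial intervals."""
        import dataclasses
        from scipy import stats
        base = hc.SimParams(samples_per_cluster=(3, 2, 2), n_common=30,
                            n_shared={("P1", "M"): 30},
                            n_cluster_specific={"P1": 20, "M": 10, "P2": 20},
                            n_sample_specific_per_sample=5, fp_locus_pool=100)
        n_drop = n_present = n_fp = n_absent = 0
        for seed in range(50):
            params = dataclasses.replace(base, seed=seed)
            truth = hc.simulate_truth(params)
            calls, _ = hc.simulate_observed_calls(truth, params)
            mat = hc.build_binary_matrix(
                calls, truth.samples)
            obs = mat.df.reindex(columns=truth.presence.columns, fill_value=0)
            pres = truth.presence.to_numpy()
            n_present += int(pres.sum())
            n_drop += int(((pres == 1) & (obs.to_numpy() == 0)).sum())
            # false positives: calls at truth-absent pairs (incl. decoys)
            n_calls_total = len(mat.df.columns)
            true_hits = int(((pres == 1) & (obs.to_numpy() == 1)).sum())
            all_calls = int(mat.df.to_numpy().sum())
            n_fp += all_calls - true_hits
            n_absent += (pres == 0).sum() + len(truth.decoy_info) * len(truth.samples)
        lo, hi = stats.binom.interval(0.99, n_present, 0.06)
        assert lo <= n_drop <= hi
        lo, hi = stats.binom.interval(0.99, n_absent, 0.01)
        assert lo <= n_fp <= hi


class TestValidationTable:
    def test_absent_locus_has_no_signal(self, small_params):
        truth = hc.simulate_truth(small_params)
        calls, _ = hc.simulate_observed_calls(truth, small_params)
        table = hc.simulate_validation_table(truth, calls, small_params)
        decoy = table[table["locus"].isin(truth.decoy_info.index)]
        assert len(decoy) > 0
        assert (decoy["alt_fraction"] < 0.05).all()

    def test_median_depth_near_mean(self, small_params):
        truth = hc.simulate_truth(small_params)
        calls, _ = hc.simulate_observed_calls(truth, small_params)
        table = hc.simulate_validation_table(truth, calls, small_params)
        assert len(table) >= 100
        med = table["tumor_depth"].median()
        assert abs(med - 9647) / 9647 < 0.10

    def test_determinism(self, small_params):
        truth = hc.simulate_truth(small_params)
        calls, _ = hc.simulate_observed_calls(truth, small_params)
        t1 = hc.simulate_validation_table(truth, calls, small_params)
        t2 = hc.simulate_validation_table(truth, calls, small_params)
        assert t1.equals(t2)

    def test_unknown_panel_locus_rejected(self, small_params):
        truth = hc.simulate_truth(small_params)
        calls, _ = hc.simulate_observed_calls(truth, small_params)
        with pytest.raises(ValueError, match="absent"):
            hc.simulate_validation_table(truth, calls, small_params,
                                         loci=["chrZ:1:A>G"])


def test_write_simulation_outputs_parse_back(tmp_path, small_params):
    truth = hc.simulate_truth(small_params)
    calls, segments = hc.simulate_observed_calls(truth, small_params)
    table = hc.simulate_validation_table(truth, calls, small_params)
    paths = hc.write_simulation(truth, calls, segments, table, tmp_path / "sim")
    from heteroclone.io import read_mutation_table, read_seg, read_cluster_yaml
    back_calls = read_mutation_table(paths["mutations"])
    assert len(back_calls) == len(calls)
    back_seg = read_seg(paths["segments"])
    assert len(back_seg) == len(segments)
    scheme = read_cluster_yaml(paths["clusters"])
    assert scheme.partition() == truth.scheme().partition()
    params_back = hc.SimParams.from_yaml(paths["params"])
    assert params_back == small_params
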