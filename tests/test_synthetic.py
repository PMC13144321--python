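"""Generators: reproducibility, planted structure, statistical nulls."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from signet import synthetic as syn
from signet.preprocess import smooth_viability


def test_generate_network_tree_when_m_is_one():
    g = syn.generate_network(10, 1, seed=1)
    assert g.number_of_edges() == 9
    assert nx.is_connected(g)


def test_generate_network_heavy_tail_and_determinism():
    g = syn.generate_network(200, 3, seed=7)
    degrees = sorted(d for _, d in g.degree())
    assert max(degrees) > np.median(degrees) * 3
    g2 = syn.generate_network(200, 3, seed=7)
    assert set(g.edges()) == set(g2.edges())
    assert all(g[u][v]["confidence"] == g2[u][v]["confidence"]
               for u, v in g.edges())


def test_generate_network_rejects_bad_sizes():
    with pytest.raises(ValueError):
        syn.generate_network(5, 1, seed=0)
    with pytest.raises(ValueError):
        syn.generate_network(20, 0, seed=0)


def test_plant_truth_paths_exist_and_converge(small_world):
    graph, truth, _ = small_world
    for path in truth.planted_paths:
        for u, v in zip(path[:-1], path[1:]):
            assert graph.has_edge(u, v)
            assert graph[u][v]["confidence"] >= 0.9
    assert truth.convergence_hubs
    hub = next(iter(truth.convergence_hubs))
    on = sum(hub in p for p in truth.planted_paths)
    assert on >= 2


def test_plant_truth_support_features_exist(small_world):
    _, truth, _ = small_world
    for k, per_view in truth.factor_support.items():
        for view, feats in per_view.items():
            if view == "phospho":
                assert all(f in truth.site_map for f in feats)
            else:
                assert all(f in truth.nodes for f in feats)


def test_annotations_planted_overlap_vs_background(small_world):
    graph, truth, ann = small_world
    path = truth.planted_paths[0]
    hubs = truth.convergence_hubs
    for u, v in zip(path[:-1], path[1:]):
        jac = len(ann[u] & ann[v]) / len(ann[u] | ann[v])
        if u in hubs or v in hubs:
            # hubs carry both paths' cores, diluting pairwise overlap
            assert jac >= 0.3
        else:
            assert jac >= 0.5
    # background pairs: expected Jaccard is tiny under uniform sampling
    rng = np.random.default_rng(0)
    bg = [n for n in graph.nodes() if n not in truth.path_nodes()]
    jacs = []
    for _ in range(200):
        u, v = rng.choice(bg, size=2, replace=False)
        jacs.append(len(ann[u] & ann[v]) / len(ann[u] | ann[v]))
    assert np.mean(jacs) < 0.05


def test_omics_shapes_and_grid(omics):
    mrna, protein, phospho = omics
    assert mrna.matrix.shape[0] == 24  # 2 genotypes x 4 treatments x 3 reps
    assert (mrna.matrix.to_numpy() >= 0).all()
    assert mrna.matrix.to_numpy().dtype.kind == "i"
    assert not mrna.matrix.isna().any().any()
    assert set(phospho.feature_meta["protein"]) <= set(protein.matrix.columns)


def test_omics_missingness_rate_and_intensity_dependence():
    truth = _retruth()
    _, complete, _ = syn.simulate_omics(truth, missing_rate=0.0, seed=11)
    _, censored, _ = syn.simulate_omics(truth, missing_rate=0.1, seed=11)
    frac = censored.matrix.isna().mean().mean()
    assert 0.05 < frac < 0.15  # requested mean rate 0.1
    # censoring is intensity-dependent: dropped entries sit low
    mask = censored.matrix.isna().to_numpy()
    vals = complete.matrix.to_numpy()
    assert vals[mask].mean() < vals[~mask].mean() - 1.0


def _retruth():
    graph = syn.generate_network(120, 3, seed=11)
    return syn.plant_truth(graph, 2, 2, 4, seed=11)


def test_missing_rate_zero_means_complete():
    truth = _retruth()
    _, protein, phospho = syn.simulate_omics(truth, missing_rate=0.0, seed=3)
    assert not protein.matrix.isna().any().any()
    assert not phospho.matrix.isna().any().any()


def test_phospho_tracks_parent_protein_without_site_signal():
    truth = _retruth()
    _, protein, phospho = syn.simulate_omics(truth, missing_rate=0.0,
                                             noise_sd=0.1, seed=3)
    signal_sites = set()
    for per_view in truth.factor_support.values():
        signal_sites |= set(per_view.get("phospho", {}))
    quiet = [s for s in phospho.matrix.columns if s not in signal_sites][:20]
    rs = []
    for site in quiet:
        parent = phospho.feature_meta.loc[site, "protein"]
        rs.append(np.corrcoef(phospho.matrix[site],
                              protein.matrix[parent])[0, 1])
    # population correlation bio^2/(bio^2+noise^2) = 0.92 at these settings;
    # average across sites to damp the n=24 sampling noise of single r's
    assert np.mean(rs) > 0.9


def test_null_effect_size_gives_uniform_pvalues():
    graph = syn.generate_network(2000, 2, seed=5)
    truth = syn.plant_truth(graph, 2, 2, 4, seed=5)
    _, protein, _ = syn.simulate_omics(truth, effect_size=0.0, noise_sd=1.0,
                                       missing_rate=0.0, seed=5)
    meta = protein.sample_meta
    a = meta.index[meta["genotype"] == "WT"]
    b = meta.index[meta["genotype"] == "KO"]
    _, pvals = stats.ttest_ind(protein.matrix.loc[a], protein.matrix.loc[b],
                               equal_var=False)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_regulons_shift_targets_in_knockouts():
    truth = _retruth()
    regulons = syn.simulate_regulons(truth, targets_per_tf=8, seed=2)
    mrna, _, _ = syn.simulate_omics(truth, effect_size=2.0, missing_rate=0.0,
                                    seed=9)
    assert all(len(t) == 8 for t in regulons.values())
    meta = mrna.sample_meta
    ko = meta.index[meta["genotype"] == "KO"]
    wt = meta.index[meta["genotype"] == "WT"]
    logm = np.log2(mrna.matrix + 0.5)
    lfc = logm.loc[ko].mean() - logm.loc[wt].mean()
    for tf, activity in truth.planted_tf_activity.items():
        targets = regulons[tf]
        score = np.mean([np.sign(w) * lfc[g] for g, w in targets.items()])
        if activity > 0:
            assert score > 0.5
        elif activity == 0:
            assert abs(score) < 0.5


def test_kinomics_thresholds():
    truth = _retruth()
    tab = syn.simulate_kinomics(truth, seed=4)
    planted = tab[tab["kinase"].isin(truth.kinases)]
    assert (planted["median_activity_change"].abs() > 1).all()
    # Gaussian(0, 0.3) exceeds +-1 with probability < 0.001
    assert 2 * stats.norm.sf(1.0, scale=0.3) < 1e-3
    truth.kinases = set()
    with pytest.raises(ValueError):
        syn.simulate_kinomics(truth, seed=4)


def test_viability_trace_shape_and_spikes():
    quiet = syn.simulate_viability(seed=8, spike_rate=0.0)
    assert quiet.matrix.shape[1] == 25
    assert (quiet.matrix.to_numpy() >= 0).all()
    spiky = syn.simulate_viability(seed=8, spike_rate=0.08)
    sm_quiet = smooth_viability(quiet)
    sm_spiky = smooth_viability(spiky)
    # smoothing suppresses the bulk of the spikes (adjacent spike pairs
    # can defeat a window-3 median and are tolerated)
    diff = (sm_spiky.matrix - sm_quiet.matrix).abs().to_numpy()
    raw_diff = (spiky.matrix - quiet.matrix).abs().to_numpy()
    assert (diff > 1.0).sum() <= 0.3 * (raw_diff > 1.0).sum()
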