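"""Shared state builder for the numbered analysis drivers.

Synthetic inputs and intermediate stages are regenerated
deterministically from the config seed (every generator is
bit-reproducible), so each driver can rebuild exactly the prefix of the
pipeline it needs and then run and report its own stage.
"""

from pathlib import Path

import numpy as np

from signet import factors as fm
from signet import preprocess as pp
from signet import propagation as prop
from signet import synthetic as syn
from signet.config import RunConfig
from signet.pipeline import child_seeds

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
CONFIG_PATH = Path(__file__).resolve().parent / "config.yaml"


def load_config() -> RunConfig:
    if CONFIG_PATH.exists():
        return RunConfig.from_yaml(CONFIG_PATH)
    return RunConfig()


def simulate(config: RunConfig) -> dict:
    seeds = child_seeds(config.seed)
    graph = syn.generate_network(config.n_nodes, config.edges_per_node,
                                 seeds["simulate"])
    truth = syn.plant_truth(graph, config.n_receptors, config.n_paths,
                            config.path_length, seeds["simulate"],
                            support_mode=config.support_mode)
    ann = syn.generate_annotations(graph, truth, seed=seeds["simulate"])
    syn.simulate_regulons(truth, seed=seeds["simulate"])
    kinomics = syn.simulate_kinomics(truth, seed=seeds["simulate"])
    mrna, protein, phospho = syn.simulate_omics(
        truth, config.replicates, config.effect_size, config.noise_sd,
        config.missing_rate, seeds["simulate"])
    trace = syn.simulate_viability(seeds["simulate"])
    return {"config": config, "seeds": seeds, "graph": graph, "truth": truth,
            "ann": ann, "kinomics": kinomics, "mrna": mrna,
            "protein": protein, "phospho": phospho, "trace": trace}


def preprocess(state: dict) -> dict:
    config = state["config"]
    mrna_f = pp.cpm_filter(state["mrna"], config.cpm_threshold)
    tmm = pp.effective_library_sizes(mrna_f)
    mrna_log = mrna_f.copy_with(pp.log_cpm(mrna_f, tmm))
    qc = min(config.qc_min_quantified,
             max(1, state["protein"].matrix.shape[1] // 2))
    protein_i = pp.impute_within_condition(
        pp.qc_filter_samples(state["protein"], qc),
        config.impute_min_quantified)
    qc_ph = min(config.qc_min_quantified,
                max(1, state["phospho"].matrix.shape[1] // 2))
    phospho_i = pp.impute_within_condition(
        pp.qc_filter_samples(state["phospho"], qc_ph),
        config.impute_min_quantified)
    phospho_net = pp.aggregate_duplicate_sites(
        pp.net_phosphorylation(phospho_i, protein_i))
    state.update(mrna_f=mrna_f, tmm=tmm, mrna_log=mrna_log,
                 protein_i=protein_i,
                 protein_s=pp.median_center_scale(protein_i),
                 phospho_net=phospho_net,
                 phospho_s=pp.median_center_scale(phospho_net))
    return state


def factorize(state: dict) -> dict:
    config = state["config"]
    sels = {
        "mrna": pp.anova_select(state["mrna_log"], **config.anova_strict),
        "protein": pp.anova_select(state["protein_s"], **config.anova_strict),
        "phospho": pp.anova_select(state["phospho_s"],
                                   **config.anova_phospho),
    }
    shared = [s for s in state["mrna_log"].samples
              if s in state["protein_s"].samples
              and s in state["phospho_s"].samples]
    views = []
    for sel in sels.values():
        if sel.features:
            views.append(sel.view.copy_with(
                sel.view.matrix.loc[shared].fillna(0.0)))
    model = fm.fit_factors(views, K=config.n_factors)
    meta = state["mrna"].sample_meta.loc[shared]
    model = fm.orient_factors(model, fm.default_control_masks(meta))
    state.update(selections=sels, views=views, model=model,
                 variance_explained=fm.variance_explained(model, views))
    return state


def propagate(state: dict) -> dict:
    config = state["config"]
    rng = np.random.default_rng(state["seeds"]["propagate"])
    networks, seedsets = {}, {}
    for k in range(1, config.n_factors + 1):
        weights = fm.protein_weights(state["model"], k,
                                     site_map=state["truth"].site_map)
        seedsets[k] = fm.select_seeds(weights, config.seed_quantile, factor=k)
        pos, neg = prop.propagate_factor(
            state["graph"], seedsets[k], damping=config.damping,
            rwr_threshold=config.rwr_threshold, kde_cutoff=config.kde_cutoff,
            n_null=config.n_null, ann=state["ann"],
            seed=int(rng.integers(2**31)))
        networks[k] = prop.build_signed_network(pos, neg, state["graph"],
                                                factor=k)
    state.update(networks=networks, seedsets=seedsets)
    return state
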