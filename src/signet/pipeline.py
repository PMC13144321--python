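"""End-to-end orchestration over synthetic inputs, plus a compact
planted-recovery trial used by the validation suite.

``run_all`` executes simulate -> preprocess -> factorize -> seeds ->
propagate (per factor) -> PCSF -> cross-talk -> max flow -> TF activity
-> viability, writing every intermediate artifact and a JSON run record
(parameter echo, derived child seeds, per-stage counts).  All
stochastic stages consume child seeds spawned deterministically from
the master seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import factors as fm
from . import flow as fl
from . import io
from . import pcsf as ps
from . import preprocess as pp
from . import propagation as prop
from . import synthetic as syn
from . import tf as tfa
from .config import RunConfig

_STAGES = ("simulate", "preprocess", "factorize", "propagate", "pcsf",
           "crosstalk", "flow", "tf", "viability")


def child_seeds(master: int) -> dict:
    """Deterministic per-stage integer seeds below 2**31."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(_STAGES))
    return {name: int(c.generate_state(1, dtype=np.uint32)[0] % 2**31)
            for name, c in zip(_STAGES, children)}


def run_all(config: RunConfig, outdir) -> dict:
    """Run the full pipeline on simulated inputs; returns the run record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed)
    record: dict = {"config": config.__dict__ | {}, "seeds": seeds,
                    "counts": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def stage(name):
        def fail(exc):
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return fail

    # -- simulate ------------------------------------------------------
    try:
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
    except Exception as exc:  # pragma: no cover - structured abort
        stage("simulate")(exc)
    io.write_edge_list(graph, out / "network.tsv")
    io.write_truth(truth, out / "truth.json")
    io.write_gmt(ann, out / "annotations.gmt")
    io.write_gmt(truth.regulons, out / "regulons.gmt", weighted=True)
    io.write_matrix(mrna, out / "mrna.csv", out / "samples.csv")
    record["counts"]["nodes"] = graph.number_of_nodes()
    record["counts"]["edges"] = graph.number_of_edges()

    # -- preprocess ----------------------------------------------------
    try:
        mrna_f = pp.cpm_filter(mrna, config.cpm_threshold)
        tmm = pp.effective_library_sizes(mrna_f)
        logmat = pp.log_cpm(mrna_f, tmm)
        mrna_log = mrna_f.copy_with(logmat)

        def clean(view):
            v = pp.qc_filter_samples(view, min(config.qc_min_quantified,
                                               max(1, view.matrix.shape[1] // 2)))
            return pp.impute_within_condition(v, config.impute_min_quantified)

        protein_i = clean(protein)
        phospho_i = clean(phospho)
        phospho_net = pp.net_phosphorylation(phospho_i, protein_i)
        phospho_net = pp.aggregate_duplicate_sites(phospho_net)
        protein_s = pp.median_center_scale(protein_i)
        phospho_s = pp.median_center_scale(phospho_net)
    except Exception as exc:
        stage("preprocess")(exc)
    record["counts"]["genes_after_cpm"] = mrna_f.matrix.shape[1]

    # -- factorize -----------------------------------------------------
    try:
        sel_mrna = pp.anova_select(mrna_log, **config.anova_strict)
        sel_prot = pp.anova_select(protein_s, **config.anova_strict)
        sel_phos = pp.anova_select(phospho_s, **config.anova_phospho)
        shared = [s for s in mrna_log.samples
                  if s in protein_s.samples and s in phospho_s.samples]
        views = []
        for sel in (sel_mrna, sel_prot, sel_phos):
            if not sel.features:  # a view can select nothing at small scale
                continue
            mat = sel.view.matrix.loc[shared].fillna(0.0)
            views.append(sel.view.copy_with(mat))
        if not views:
            raise ValueError("no view retained any feature")
        model = fm.fit_factors(views, K=config.n_factors)
        meta = mrna.sample_meta.loc[shared]
        model = fm.orient_factors(model, fm.default_control_masks(meta))
        ve = fm.variance_explained(model, views)
    except Exception as exc:
        stage("factorize")(exc)
    for v, sel in zip(("mrna", "protein", "phospho"),
                      (sel_mrna, sel_prot, sel_phos)):
        record["counts"][f"selected_{v}"] = len(sel.features)
    model.scores.to_csv(out / "factor_scores.tsv", sep="\t")
    ve.to_csv(out / "variance_explained.tsv", sep="\t")
    for v, df in model.loadings.items():
        df.to_csv(out / f"loadings_{v}.tsv", sep="\t")

    # -- propagate per factor -----------------------------------------
    networks = {}
    rng = np.random.default_rng(seeds["propagate"])
    try:
        for k in range(1, config.n_factors + 1):
            weights = fm.protein_weights(model, k, site_map=truth.site_map)
            seedset = fm.select_seeds(weights, config.seed_quantile, factor=k)
            pos, neg = prop.propagate_factor(
                graph, seedset, damping=config.damping,
                rwr_threshold=config.rwr_threshold,
                kde_cutoff=config.kde_cutoff, n_null=config.n_null,
                ann=ann, seed=int(rng.integers(2**31)))
            networks[k] = prop.build_signed_network(pos, neg, graph, factor=k)
            io.write_graphml(networks[k], out / f"network_factor{k}.graphml")
            record["counts"][f"factor{k}_nodes"] = len(networks[k].nodes)
    except Exception as exc:
        stage("propagate")(exc)

    # -- PCSF per factor ----------------------------------------------
    forests = {}
    try:
        for k, net in networks.items():
            if net.graph.number_of_edges() == 0:
                continue
            pr = ps.pagerank_centrality(net)
            prizes = ps.select_terminals(pr, config.n_terminals)
            forests[k] = ps.pcsf_randomized(
                net, prizes, beta=config.pcsf_beta, n_iter=config.pcsf_iters,
                noise=config.pcsf_noise, freq_cutoff=config.pcsf_freq_cutoff,
                seed=seeds["pcsf"] + k)
            io.write_graphml(forests[k].forest, out / f"pcsf_factor{k}.graphml")
            record["counts"][f"pcsf_factor{k}_nodes"] = \
                forests[k].forest.number_of_nodes()
    except Exception as exc:
        stage("pcsf")(exc)

    # -- cross-talk on the factor-1 U factor-3 union ------------------
    try:
        union = prop.union_networks(networks[1], networks[config.n_factors])
        de_treat = pp.differential_abundance(
            mrna_log, ("combination", "untreated"))
        de_geno = pp.differential_abundance(mrna_log, ("KO", "WT"))
        receptors = sorted(truth.receptors)

        def receptor_vec(de):
            # prefer upregulated receptors, fall back to downregulated
            try:
                return fl.receptor_seed_vector(de, receptors,
                                               alpha=config.receptor_alpha)
            except ValueError:
                return fl.receptor_seed_vector(de, receptors,
                                               alpha=config.receptor_alpha,
                                               direction="down")

        vec_a = receptor_vec(de_treat)
        vec_b = receptor_vec(de_geno)
        in_union_a = {n: w for n, w in vec_a.items() if n in union.graph}
        in_union_b = {n: w for n, w in vec_b.items() if n in union.graph}
        if in_union_a and in_union_b:
            walk_net = union
            vec_a, vec_b = in_union_a, in_union_b
        else:
            # significant receptors fell outside the factor networks at
            # this scale; walk the full interactome instead
            walk_net = graph
            record["counts"]["crosstalk_on_full_graph"] = True
        crosstalk = fl.crosstalk_propagate(walk_net, vec_a, vec_b,
                                           damping=config.damping)
        emp_a = fl.permutation_significance(walk_net, vec_a, config.damping,
                                            config.crosstalk_n_perm,
                                            seed=seeds["crosstalk"])
        emp_b = fl.permutation_significance(walk_net, vec_b, config.damping,
                                            config.crosstalk_n_perm,
                                            seed=seeds["crosstalk"] + 1)
        crosstalk.table["emp_p_a"] = emp_a
        crosstalk.table["emp_p_b"] = emp_b
        crosstalk.table.rename_axis("node").to_csv(out / "crosstalk.tsv", sep="\t")
        kin_vec = fl.kinase_seed_vector(kinomics[kinomics["contrast"]
                                                 == "combination_vs_untreated"],
                                        sorted(truth.kinases),
                                        config.kinomics_threshold)
        record["counts"]["kinase_seeds"] = len(kin_vec)
    except Exception as exc:
        stage("crosstalk")(exc)

    # -- max flow ------------------------------------------------------
    try:
        caps = fl.edge_capacities_from_similarity(walk_net, ann)
        source = max(vec_a, key=vec_a.get)
        hubs = crosstalk.top_hubs(5)
        sink = hubs[0] if hubs else sorted(truth.tfs)[0]
        flow_res = fl.max_flow(walk_net, source, sink, caps)
        sub = fl.flow_subgraph(flow_res, config.flow_percentile)
        flow_res.edge_flows.to_csv(out / "flow_edges.tsv", sep="\t", index=False)
        io.write_graphml(sub, out / "flow_subgraph.graphml")
        record["counts"]["flow_value"] = flow_res.value
        record["counts"]["flow_subgraph_nodes"] = sub.graph.number_of_nodes()
    except Exception as exc:
        stage("flow")(exc)

    # -- TF activity ---------------------------------------------------
    try:
        tf_res = tfa.activity_contrast(mrna, ("KO", "WT"), truth.regulons,
                                       min_count=config.min_count,
                                       min_targets=config.min_targets)
        tf_res.rename_axis("tf").to_csv(out / "tf_activity.tsv", sep="\t")
    except Exception as exc:
        stage("tf")(exc)

    # -- viability -----------------------------------------------------
    try:
        smoothed = pp.smooth_viability(trace)
        t, p = pp.endpoint_welch(
            smoothed, {"genotype": "WT", "gRNA": "empty", "drug": "drug"},
            {"genotype": "KO", "gRNA": "empty", "drug": "drug"})
        record["counts"]["viability_endpoint_t"] = t
        record["counts"]["viability_endpoint_p"] = p
    except Exception as exc:
        stage("viability")(exc)

    record["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_record.json").write_text(json.dumps(record, indent=1,
                                                    default=str))
    return record


def fit_view_confined_recovery(seed: int, n_nodes: int = 900) -> tuple:
    """Fit the 3-factor model on planted view-confined supports.

    Simulates the 2 genotype x 4 treatment x 3 replicate design at
    effect 2 / noise 0.5 with each factor's support confined to one
    view, fits the factorization on the planted (selected, z-scored)
    features, and returns (max principal angle in degrees between the
    fitted and planted score subspaces, per-view flags that variance
    explained peaks on the planted factor).  Because the treatment and
    combination indicators are correlated, the fitted factor carrying a
    view's planted axis is identified as the one best correlated with
    that axis before comparing against the VE argmax.
    """
    from scipy.linalg import subspace_angles

    from .types import OmicsView

    graph = syn.generate_network(n_nodes, 3, seed=seed)
    truth = syn.plant_truth(graph, 2, 3, 4, seed=seed,
                            support_mode="view_confined")
    mrna, protein, phospho = syn.simulate_omics(
        truth, effect_size=2.0, noise_sd=0.5, missing_rate=0.0, seed=seed)
    logm = OmicsView("mrna", pp.log_cpm(mrna), mrna.sample_meta)
    views = []
    for k, (v, label) in enumerate(((logm, "mrna"), (protein, "protein"),
                                    (phospho, "phospho")), 1):
        support = sorted(truth.factor_support[k][label])
        sub = v.matrix.loc[:, [f for f in support if f in v.matrix.columns]]
        z = (sub - sub.mean()) / sub.std(ddof=1).replace(0, np.nan)
        views.append(OmicsView(label, z.fillna(0.0), mrna.sample_meta))
    model = fm.fit_factors(views, K=3)
    meta = mrna.sample_meta
    design = np.column_stack([
        (meta["treatment"] != "untreated").to_numpy(float),
        (meta["treatment"] == "combination").to_numpy(float),
        (meta["genotype"] == "KO").to_numpy(float)])
    design = design - design.mean(axis=0)
    angle = float(np.degrees(
        subspace_angles(model.scores.to_numpy(), design)).max())
    ve = fm.variance_explained(model, views)
    scores = model.scores.to_numpy()
    argmax_ok = []
    for vi, k in enumerate(range(3)):
        corr = [abs(np.corrcoef(scores[:, j], design[:, k])[0, 1])
                for j in range(3)]
        argmax_ok.append(int(np.argmax(corr))
                         == int(np.argmax(ve.iloc[vi].to_numpy())))
    return angle, argmax_ok


# ------------------------------------------------------------------
# compact planted-recovery trial (validation workhorse)


@dataclass
class RecoveryOutcome:
    hub_in_top5: bool
    flow_coverage: float
    path_retention: float
    intermediate_p: float


def planted_recovery_trial(seed: int, n_nodes: int = 150, n_null: int = 200,
                           n_perm: int = 500, pcsf_iters: int = 200,
                           path_length: int = 4) -> RecoveryOutcome:
    """One seeded replicate of the end-to-end planted-truth recovery.

    Plants two receptor->effector paths sharing a convergence hub,
    propagates each path's proteins as a factor seed set, merges the
    two signed networks, extracts a consensus forest, ranks cross-talk
    hubs from the two receptors, and traces the first path by
    similarity-capacitated max flow.  Reports whether the planted hub
    ranks in the top-5 cross-talk scores, the fraction of first-path
    nodes covered by the high-flow subgraph, the fraction retained by
    propagation, and the permutation p of a planted intermediate node.
    """
    rng = np.random.default_rng(seed)
    graph = syn.generate_network(n_nodes, 3, int(rng.integers(2**31)))
    truth = syn.plant_truth(graph, n_receptors=2, n_paths=2,
                            path_length=path_length,
                            seed=int(rng.integers(2**31)))
    ann = syn.generate_annotations(graph, truth, seed=int(rng.integers(2**31)))
    path1, path2 = truth.planted_paths[0], truth.planted_paths[1]
    hub = next(iter(truth.convergence_hubs))

    nets = []
    for k, path in enumerate((path1, path2), start=1):
        pos_w = {n: 1.0 for n in path}
        bg = [n for n in sorted(graph.nodes()) if n not in path]
        neg_w = {n: -1.0 for n in
                 list(np.random.default_rng(seed + k).choice(bg, size=len(path),
                                                             replace=False))}
        seedset = fm.SeedSet(positive=pos_w, negative=neg_w, factor=k,
                             quantile=0.05)
        pos, neg = prop.propagate_factor(graph, seedset, n_null=n_null,
                                         ann=ann, seed=int(rng.integers(2**31)))
        nets.append(prop.build_signed_network(pos, neg, graph, factor=k))
    retention = np.mean([n in nets[0].nodes for n in path1])

    union = prop.union_networks(nets[0], nets[1])
    pr = ps.pagerank_centrality(union)
    prizes = ps.select_terminals(pr, n=min(50, len(pr)))
    ps.pcsf_randomized(union, prizes, n_iter=pcsf_iters,
                       seed=int(rng.integers(2**31)))

    vec_a = {path1[0]: 1.0}
    vec_b = {path2[0]: 1.0}
    crosstalk = fl.crosstalk_propagate(union, vec_a, vec_b)
    hub_top5 = hub in crosstalk.top_hubs(5)
    # receptor-walk significance over the full interactome: rewiring
    # destroys the planted high-confidence route to the interior node
    emp = fl.permutation_significance(graph, vec_a, n_perm=n_perm,
                                      seed=int(rng.integers(2**31)))
    inter_p = float(emp.get(path1[1], 1.0))

    caps = fl.edge_capacities_from_similarity(union, ann)
    flow_res = fl.max_flow(union, path1[0], path1[-1], caps)
    sub = fl.flow_subgraph(flow_res, 95.0)
    coverage = np.mean([n in sub.graph for n in path1])
    return RecoveryOutcome(hub_in_top5=bool(hub_top5),
                           flow_coverage=float(coverage),
                           path_retention=float(retention),
                           intermediate_p=inter_p)
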