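"""Locate receptor cross-talk hubs by permutation-tested random walks on
the factor-1 U factor-3 union network and trace the dominant
receptor->hub route by similarity-capacitated maximum flow.
"""

from _stages import RESULTS, factorize, load_config, preprocess, propagate, simulate

from signet import flow as fl, io, preprocess as pp, propagation as prop

out = RESULTS / "pipeline"
out.mkdir(parents=True, exist_ok=True)

config = load_config()
state = propagate(factorize(preprocess(simulate(config))))
truth, graph, ann = state["truth"], state["graph"], state["ann"]

union = prop.union_networks(state["networks"][1],
                            state["networks"][config.n_factors])
de_treat = pp.differential_abundance(state["mrna_log"],
                                     ("combination", "untreated"))
de_geno = pp.differential_abundance(state["mrna_log"], ("KO", "WT"))
receptors = sorted(truth.receptors)


def receptor_vec(de):
    try:
        return fl.receptor_seed_vector(de, receptors,
                                       alpha=config.receptor_alpha)
    except ValueError:
        return fl.receptor_seed_vector(de, receptors,
                                       alpha=config.receptor_alpha,
                                       direction="down")


vec_a, vec_b = receptor_vec(de_treat), receptor_vec(de_geno)
walk_net = union if (set(vec_a) & union.nodes and set(vec_b) & union.nodes) \
    else graph
vec_a = {n: w for n, w in vec_a.items() if n in
         (walk_net.graph if hasattr(walk_net, "graph") else walk_net)} or vec_a
ct = fl.crosstalk_propagate(walk_net, vec_a, vec_b, damping=config.damping)
emp_a = fl.permutation_significance(walk_net, vec_a, config.damping,
                                    config.crosstalk_n_perm,
                                    seed=state["seeds"]["crosstalk"])
ct.table["emp_p_a"] = emp_a
ct.table.rename_axis("node").to_csv(out / "crosstalk.tsv", sep="\t")

hubs = ct.top_hubs(5)
path_nodes = truth.path_nodes()
print(f"treatment receptors: {vec_a}; genotype receptors: {vec_b}")
print(f"top-5 cross-talk hubs: {hubs} "
      f"({sum(h in path_nodes for h in hubs)} on planted paths)")

caps = fl.edge_capacities_from_similarity(walk_net, ann)
source = max(vec_a, key=vec_a.get)
sink = hubs[0]
res = fl.max_flow(walk_net, source, sink, caps)
sub = fl.flow_subgraph(res, config.flow_percentile)
res.edge_flows.to_csv(out / "flow_edges.tsv", sep="\t", index=False)
io.write_graphml(sub, out / "flow_subgraph.graphml")
print(f"max flow {source} -> {sink}: value {res.value:.3f}; "
      f"high-flow subgraph {sub.graph.number_of_nodes()} nodes")
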