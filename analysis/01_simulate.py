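"""Generate the synthetic study: interactome, planted signaling paths,
annotations, regulons, kinase activities, three omics views, viability.

Writes the raw inputs under results/pipeline/ and reports the planted
ground truth a downstream reader should expect to recover.
"""

from _stages import RESULTS, load_config, simulate

from signet import io

out = RESULTS / "pipeline"
out.mkdir(parents=True, exist_ok=True)

config = load_config()
state = simulate(config)
graph, truth = state["graph"], state["truth"]

io.write_edge_list(graph, out / "network.tsv")
io.write_truth(truth, out / "truth.json")
io.write_gmt(state["ann"], out / "annotations.gmt")
io.write_gmt(truth.regulons, out / "regulons.gmt", weighted=True)
io.write_matrix(state["mrna"], out / "mrna_counts.csv", out / "samples.csv")
io.write_matrix(state["protein"], out / "protein.csv", out / "samples.csv")
io.write_matrix(state["phospho"], out / "phospho.csv", out / "samples.csv")
state["kinomics"].to_csv(out / "kinomics.csv", index=False)
state["trace"].matrix.to_csv(out / "viability.csv")
config.to_yaml(out / "config_used.yaml")

print(f"interactome: {graph.number_of_nodes()} proteins, "
      f"{graph.number_of_edges()} interactions")
print(f"planted paths: {truth.planted_paths}")
print(f"convergence hub(s): {sorted(truth.convergence_hubs)}")
print(f"receptors: {sorted(truth.receptors)}; TFs: {sorted(truth.tfs)}")
print(f"omics: {state['mrna'].matrix.shape[1]} genes, "
      f"{state['protein'].matrix.shape[1]} proteins, "
      f"{state['phospho'].matrix.shape[1]} phosphosites over "
      f"{state['mrna'].matrix.shape[0]} samples")
print(f"inputs written to {out}")
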