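"""Normalize and filter each omics view; compute net phosphorylation and
the knockout-vs-wild-type differential abundance table.
"""

from _stages import RESULTS, load_config, preprocess, simulate

from signet import io, preprocess as pp

out = RESULTS / "pipeline"
out.mkdir(parents=True, exist_ok=True)

state = preprocess(simulate(load_config()))

io.write_matrix(state["mrna_log"], out / "mrna_logcpm.csv",
                out / "samples.csv")
io.write_matrix(state["protein_s"], out / "protein_processed.csv",
                out / "samples.csv")
io.write_matrix(state["phospho_s"], out / "phospho_net_processed.csv",
                out / "samples.csv")
de = pp.differential_abundance(state["mrna_log"], ("KO", "WT"))
io.write_de_table(de, out / "de_KO_vs_WT.tsv")

n_sig = int((de["adj_p"] < 0.01).sum())
flags = state["phospho_net"].feature_meta["net_flag"].value_counts().to_dict()
print(f"genes after CPM filter: {state['mrna_f'].matrix.shape[1]}")
print(f"TMM factors span {state['tmm'].min():.3f}-{state['tmm'].max():.3f} "
      "(geometric mean 1)")
print(f"net-phosphorylation flags: {flags}")
print(f"KO vs WT: {n_sig} genes at adjusted p < 0.01")
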