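"""Select variable features per view, fit the 3-factor multi-view model,
orient signs against control samples, and report variance explained.
"""

from _stages import RESULTS, factorize, load_config, preprocess, simulate

out = RESULTS / "pipeline"
out.mkdir(parents=True, exist_ok=True)

state = factorize(preprocess(simulate(load_config())))

state["model"].scores.to_csv(out / "factor_scores.tsv", sep="\t")
for view, df in state["model"].loadings.items():
    df.to_csv(out / f"loadings_{view}.tsv", sep="\t")
state["variance_explained"].to_csv(out / "variance_explained.tsv", sep="\t")

for view, sel in state["selections"].items():
    print(f"{view}: {len(sel.features)} features selected")
print("variance explained (view x factor):")
print(state["variance_explained"].round(3).to_string())
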