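"""Infer transcription-factor activity for the knockout-vs-wild-type
contrast from the simulated regulons with the univariate linear model.
"""

from _stages import RESULTS, load_config, simulate

from signet import tf as tfa

out = RESULTS / "pipeline"
out.mkdir(parents=True, exist_ok=True)

config = load_config()
state = simulate(config)
truth = state["truth"]

res = tfa.activity_contrast(state["mrna"], ("KO", "WT"), truth.regulons,
                            min_count=config.min_count,
                            min_targets=config.min_targets)
res.rename_axis("tf").to_csv(out / "tf_activity.tsv", sep="\t")

ranked = res["t"].abs().sort_values(ascending=False)
active = {tf: a for tf, a in truth.planted_tf_activity.items() if a != 0}
print("TF activity (|t| ranked):")
print(res.loc[ranked.index].round(3).to_string())
print(f"planted active TFs: {active}; top hit: {ranked.index[0]}")
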