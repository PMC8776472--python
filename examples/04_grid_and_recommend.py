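"""Run a reduced benchmark grid and derive a best-method recommendation.

Crosses two mechanisms, three rates and all three methods with two
replicates (a scaled-down version of the full 3 x 8 x 3 study), prints the
per-cell mean RMSE, and compares the published decision rules against the
data-driven winner on this grid.  Expect a couple of minutes of runtime.
"""

import scalefit as sf

config = sf.GridConfig(
    mechanisms=("MCAR", "MNAR"),
    rates=(0.10, 0.25, 0.40),
    methods=("MS", "PMM", "RFR"),
    n_replicates=2,
    base_seed=7,
)
records = sf.run_grid(config)
tables = sf.summarize(records)
print("mean RMSE per cell (rows = overall rate):")
print(tables["rmse"].round(4).to_string())

paper = sf.recommend_path(mode="paper_rules",
                          mechanisms=config.mechanisms, rates=config.rates)
data = sf.recommend_path(records, mode="data_driven",
                         mechanisms=config.mechanisms, rates=config.rates)
print("\ncell        published-rules   data-driven")
for mech in config.mechanisms:
    for rate in config.rates:
        print(f"{mech:5} {100 * rate:3.0f}%   {paper.method_for(mech, rate):>10}"
              f"        {data.method_for(mech, rate):>6}")
# The published rules prefer mean substitution at low rates for its
# simplicity; the data-driven column picks whichever method measured the
# lowest mean RMSE here, which on synthetic cohorts is usually the forest.
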