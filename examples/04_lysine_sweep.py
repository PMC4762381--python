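"""Top-n lysine-content sweep for a rebalancing contrast.

Ranks proteins by the count test, then tracks the pooled lysine content
of the increased (up) and decreased (down) sets from the top 10 to the
top 100, against the experiment-wide average.
"""

import numpy as np

import nonzein as nz

cfg = nz.SimulationConfig(n_proteins=2000, seed=1)
counts, catalog, _ = nz.simulate_experiment(cfg)

diff = nz.rank_by_count_test(counts, nz.Contrast("o2"))
sweep = nz.topn_lysine_sweep(diff, catalog)
sweep["log2_up_down"] = np.log2(sweep["up_percent"] / sweep["down_percent"])
print(sweep.round(2).to_string())
# A rebalancing genotype shows the up-curve above the proteome average
# and the down-curve below it at every n, hence a positive log2 up/down
# lysine ratio: the abundance shift is qualitatively lysine-enriching.
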