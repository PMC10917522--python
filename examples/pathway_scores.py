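"""Pathway perturbation scoring (DRPS/DPPS) and leave-enzymes-out re-ranking.

Each reaction scores the largest between-sample range among its enzymes
(DRPS, log2 units); a pathway's DPPS is the root mean square of its
reaction scores. Removing a few high-range shared enzymes shows which
top-ranked pathways were driven by them alone.
"""

import numpy as np
import pandas as pd

import brewtrack as bt

rng = np.random.default_rng(6)
drivers = ["BAT1", "BAT2", "PDC5"]          # shared flavor-pathway enzymes
fillers = [f"ENZ{i:02d}" for i in range(30)]
background = [f"MET{i:02d}" for i in range(30)]

profiles = {d: [0.0, 5.0 + i] for i, d in enumerate(drivers)}  # big swings
for f in fillers:
    profiles[f] = list(rng.normal(0, 0.1, 2))                  # quiet
for b in background:
    profiles[b] = [0.0, float(rng.uniform(1.0, 2.0))]          # moderate
profiles = pd.DataFrame(profiles).T
profiles.columns = ["early", "late"]

table = bt.planted_driver_pathways(drivers, fillers, background,
                                   n_driver_pathways=5,
                                   n_background_pathways=12, seed=6)
pathways = bt.pathways_from_table(table)

ranked = bt.rank_pathways(bt.score_pathways(pathways, profiles), top_n=8)
print("top pathways by DPPS (log2 abundance units):")
print(ranked[["rank", "pathway_id", "dpps", "n_reactions"]].to_string(index=False))

report = bt.leave_out_rerank(pathways, profiles, excluded=set(drivers))
demoted = report[report["rank_delta"] > 0]
print(f"\nafter removing {drivers}: {len(demoted)} pathways demoted")
print(demoted[["pathway_id", "rank_before", "rank_after", "dpps_before",
               "dpps_after"]].to_string(index=False))
# Exactly the DRV pathways fall out of the top ranks: their scores were
# carried entirely by the three shared enzymes.
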