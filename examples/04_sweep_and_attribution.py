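"""Colocalisation scoring, clustering, and factor attribution.

Uses a synthetic sweep table with a planted dominant factor (pocket volume)
to demonstrate the analysis pipeline end to end: K-means clustering of the
colocalisation score, then gradient-boosted regression with exact TreeSHAP
attribution.  Running the real 72-case CFD sweep produces the same table
layout via `lumenflow.run_sweep`.
"""

from lumenflow.analysis import attribute_factors, cluster_cases, multifactor_compare
from lumenflow.oracles import synthetic_sweep

table = synthetic_sweep(seed=7, dominant="pocket_volume", effect=0.35)
print(f"sweep table: {len(table)} cases, CS in [{table.cs.min():.2f}, {table.cs.max():.2f}]")

clustered = cluster_cases(table, k=4, seed=0)
print("cluster mean CS:", {k: round(v, 3) for k, v in clustered.attrs["cluster_means"].items()})

comp = multifactor_compare(table, "pocket_volume", "cs")
print(f"pocket volume 2 vs 10 mL: Mann-Whitney p = {comp['p_value']:.2e}")

res = attribute_factors(table, seed=0)
print("factor ranking by mean |SHAP| (planted dominant factor should lead):")
for name, val in res.ranking.items():
    print(f"  {name:16s} {val:.4f}")
print(f"held-out RMSE {res.rmse:.3f}; SHAP additivity error {res.additivity_error():.1e}")
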