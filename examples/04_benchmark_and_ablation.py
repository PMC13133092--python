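"""Compare the geometric discordance metric with baseline vector measures.

Computes six per-circuitry baselines (standardized Euclidean and cosine
distances, survival/immune/tumor-normal mismatches, microenvironment
difference), their Spearman correlation matrix against dbary, and the
axis-ablation robustness of the embedding.
"""

from sigpolytope import SimulationSpec, simulate_atlas
from sigpolytope.stats import axis_ablation, baseline_metrics_table, spearman_matrix

table, _ = simulate_atlas(SimulationSpec(n_circuitries=400, seed=19))
metrics = baseline_metrics_table(table)
corr = spearman_matrix(metrics)

print("Spearman correlation of each baseline with dbary:")
print(corr["dbary"].drop("dbary").round(3).to_string())

for drop in ("survival", "immune"):
    res = axis_ablation(table, drop=drop)
    print(
        f"\ndropping {drop:9s} axes: rank correlation vs reference = "
        f"{res.spearman_vs_reference:.3f}, regime agreement = {res.regime_agreement:.3f}"
    )
print("\nSurvival axes carry 12 of the 18 coordinates, so their removal")
print("degrades the geometry far more than removing the single immune axis.")
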