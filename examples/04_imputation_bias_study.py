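"""How genotype imputation from sparse panels distorts inbreeding estimates.

For six panels covering from ~95% down to ~16% of the imputation SNP set,
the study estimates every coefficient twice per animal — from the panel's
genotyped SNP and from the full SNP set after masking and re-imputing the
rest — and correlates the two.  High-overlap panels give correlations near
1; sparse panels drift, because most of their "imputation" genotypes are
guesses.
"""

from inbredkit.pipeline import run_study

result = run_study({
    "seed": 2024,
    "simulation": {"n_founders": 100, "n_generations": 5,
                   "sires_per_generation": 4, "n_chromosomes": 3,
                   "snps_per_chromosome": 1000},
}, out_dir="scratch/example_study")

print("per-panel mean concordance (genotyped vs imputation arm):")
print(result["per_panel"][[
    "panel", "overlap_pct",
    "pearson_genotyped_vs_imputation_mean",
    "spearman_genotyped_vs_imputation_mean"]].round(4).to_string(index=False))

print("\nper-estimator mean concordance across panels:")
print(result["per_estimator"].round(4).to_string(index=False))
print("\nReading: concordance tracks the panel overlap percentage. Which "
      "estimator is most robust depends on map density; ROH-based estimates "
      "need a dense map (run at the default 5x2000-SNP scale) to shine.")
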