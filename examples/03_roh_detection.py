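"""Detect runs of homozygosity and turn them into F_roh.

A run is a stretch of consecutive homozygous SNP at least 1 Mbp long with at
least 15 SNP, tolerating one heterozygous and one missing call (absorbing
genotyping error); F_roh is the genome fraction covered by such runs.
"""

import inbredkit as ik

cfg = ik.SimulationConfig(n_founders=60, n_generations=5,
                          sires_per_generation=3, n_chromosomes=2,
                          snps_per_chromosome=1000, seed=99)
ped = ik.simulate_pedigree(cfg)
ds, _ = ik.gene_drop(ped, cfg)

params = ik.RohParameters()  # 1 Mbp, 15 SNP, 1 het, 1 missing, 1 Mbp gap
segments = ik.detect_roh(ds, params)
df = ik.roh_to_dataframe(segments)
print(f"{len(df)} ROH segments in {ds.n_samples} animals")
df["span_mbp"] = (df.end_bp - df.start_bp) / 1e6
print(df["span_mbp"].describe().round(2).to_string())

froh = ik.froh(segments, ds.map, ds.samples)
print(f"\nmean F_roh: {froh.mean():.4f} (fraction of the SNP-covered genome "
      "inside runs; long runs reflect recent inbreeding)")
print("five most inbred animals by F_roh:")
print(froh.sort_values(ascending=False).head().round(4).to_string())
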