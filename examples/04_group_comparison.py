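"""Full pipeline on a planted-deficit cohort: recover the group difference.

Generates 8 + 8 subjects whose case group has a 60 % reduction of a frontal
11.2-12.8 Hz source with eyes open, then runs preprocessing, coherence,
edge-wise Mann-Whitney + Benjamini-Hochberg FDR, and prints where the
significant case-deficit edges land.
"""

from neurocoh import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig.demo(n_per_group=8, seed=5), save_outputs=False)

print(report.to_text())
print()
cell = report.cell("alpha3", "EO")
print(f"alpha3/EO: {cell['n_deficit']} significant case-deficit edges")
print("region summary (cells with any difference edge):")
for key, v in cell["region_summary"].items():
    print(f"  {key:<32} count {v['count']:>3}  density {v['density']:.2f}")
print("\n-> the deficit concentrates in the alpha3 band, eyes-open condition, "
      "on frontal/midline edges; all other band x condition cells stay at the "
      "false-positive level.")
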