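"""A scaled-down end-to-end study: simulate, screen, image, connect, test.

Two groups of eight subjects differ only in theta-band source coupling.
The pipeline should flag exactly the theta-band global indices — higher
strength, clustering and efficiency, lower path length in the coupled
group — and leave the other five bands unflagged. Runs in about a minute.
"""

from synchnet import pipeline as pl, synthdata as sd

patient = sd.GroupSpec(8, sd.CouplingSpec(
    label="patient", coupling={"theta": 0.35}, eog_gain=0.3))
control = sd.GroupSpec(8, sd.CouplingSpec(
    label="control", coupling={"theta": 0.15}, eog_gain=0.3))
spec = sd.CohortSpec(groups=(patient, control), duration_s=60.0, fs=250.0,
                     n_sensors=62, n_sources=148, n_nodes=148, seed=21)
cohort = sd.simulate_cohort(spec)

config = pl.PipelineConfig(seed=21, n_boot=1000)
report = pl.run_study(config, cohort)

cols = ["band", "measure", "F", "p", "partial_eta2", "significant"]
print(report.global_table[cols].round(4).to_string(index=False))
sig_nodes = int(report.nodal_table["significant"].sum())
print(f"\nnodal theta-band CC comparisons: {len(report.nodal_table)} nodes, "
      f"{sig_nodes} beyond the 0.05/148 threshold")
if len(report.correlations):
    print("\ncorrelations of flagged measures with the symptom-like score:")
    print(report.correlations.round(3).to_string(index=False))
# Expected pattern: the four theta rows significant at the 0.05/24 family
# threshold with the stated directions; all other rows unflagged. This is
# the synthetic analogue of a theta-confined group difference.
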