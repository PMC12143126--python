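"""End-to-end two-condition study: simulate, fit, and build the report.

Runs the full inference chain on a small synthetic within-subject study
whose generator reverses the ATL<>IFC coupling asymmetry only in the
active condition's perception phase, then prints the bidirectional
connectivity report (paired t, FDR, Cohen's d, JZS Bayes factor,
evidence label per comparison).
"""
import warnings

from thetaflow import pipeline, stats, synthio

warnings.filterwarnings("ignore")

cfg = synthio.StudyConfig(n_subjects=8, n_samples_per_cell=1500)
report, edges = pipeline.run_connectivity_study(
    cfg, seed=4, model_kwargs={"n_hidden": 8, "max_iter": 200})

cols = ["condition", "linearity", "phase", "connection", "t", "p_fdr",
        "d", "bf10", "evidence", "significant"]
print(report[cols].round(3).to_string(index=False))
print()
flagged = report[report.significant]
print(f"{len(flagged)} of {len(report)} comparisons significant after FDR:")
print(flagged[["condition", "linearity", "phase", "connection"]]
      .to_string(index=False))

beh = synthio.simulate_behavior(n_subjects=54, seed=4)
print()
print(stats.behavioral_stats(beh).round(3).to_string(index=False))
# The flagged comparison should be the active condition's perception-phase
# ATL <> IFC asymmetry - the cell where the generator actually reverses
# the coupling - while the behavioral table shows the built-in ~16 ms
# reaction-time speedup alongside a much weaker accuracy difference.
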