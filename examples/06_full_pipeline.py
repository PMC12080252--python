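"""Full pipeline: exposure QC → dose–response → kinetics → classification → risk.

Runs every stage from a single config over the bundled synthetic fixtures
and prints the consolidated Markdown report.  The same run is available from
the shell as `daphtk run --config run.yaml`.
"""

from daphtk.data import data_path
from daphtk.pipeline import RunConfig, RunOptions, report_to_markdown, run_all

config = RunConfig(
    chemicals_csv=str(data_path("chemicals_demo_synthetic.csv")),
    exposure_csv=str(data_path("exposure_synthetic.csv")),
    reproduction_csv=str(data_path("reproduction_synthetic.csv")),
    body_burden_csv=str(data_path("body_burden_synthetic.csv")),
    species_csv=str(data_path("species_bcf_synthetic.csv")),
    options=RunOptions(
        n_boot=200,
        seed=1,
        cw_ug_per_l={"FAST": 5.0, "SLOW": 5.0},
        mec_ug_per_l={"FAST": 2.0, "SLOW": 0.5},
    ),
)

report = run_all(config)
print(report_to_markdown(report))
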