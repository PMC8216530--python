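"""Environmental predictors at labelled step locations.

Generates the monthly raster stack, computes proportional-change gradients
(front and slope proxies), extracts nearest-cell covariates at every step,
and screens the predictor set for collinearity (VIF > 3).  The model-ready
table (the export a habitat model would consume) goes to scratch/; the VIF
report to results/.
"""
import pandas as pd

from _common import CONFIG, RESULTS, SCRATCH
from sulakit.env_layers import extract_at, gradient_stack, vif_screen
from sulakit.synthetic import default_extent, generate_environment

steps = pd.read_csv(SCRATCH / "steps_labelled.csv", parse_dates=["timestamp"])
months = sorted(steps["timestamp"].dt.month.unique())
env = generate_environment(default_extent(CONFIG), months, CONFIG)
grads = gradient_stack(env)

covars = extract_at(steps, env, grads)
covars.to_csv(SCRATCH / "model_ready_covariates.csv", index=False)

predictors = ["DEP", "SST", "CHLA", "SSH", "OMLT", "GDEP", "GSST", "GCHLA", "GSSH", "GOMLT"]
retained, report = vif_screen(covars[predictors].dropna())
report.to_csv(RESULTS / "vif_report.csv", index=False)

print(f"{len(covars)} steps x {len(predictors)} candidate predictors over months {months}")
print(f"retained after VIF<=3 screening: {retained}")
print(report[report['round'] == report['round'].max()].to_string(index=False))
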