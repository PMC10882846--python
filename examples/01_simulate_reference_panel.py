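"""Generate the reference synthetic panel and inspect its structure.

30 province-like lattice units observed at 4 survey waves; the outcome is a
comorbidity prevalence fraction driven by a PM2.5 exposure whose coefficient
grows from west to east and over time.
"""

from stpanel import generate_reference_dataset

ds = generate_reference_dataset()
df = ds.panel.to_frame()

print(f"units: {len(ds.units)}, observations: {len(df)}, balanced: {ds.panel.is_balanced}")
print(f"covariates: {ds.panel.covariate_names}")
print(df.groupby("year")[["y", "pm25"]].mean().round(3))
print("\nTrue PM2.5 coefficient range:",
      round(ds.truth.beta["pm25"].min(), 5), "to", round(ds.truth.beta["pm25"].max(), 5))
# Mean prevalence sits near 0.3; PM2.5 declines secularly while its
# coefficient grows, and the true coefficient spans a ~7x range overall.
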