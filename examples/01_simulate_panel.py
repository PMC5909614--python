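"""Generate a synthetic multi-environment maize trial panel.

Builds the default study conditions — eleven site-years from upstate
New York (42.73 °N, spring sowing) to Puerto Rico (18.00 °N, November
sowing) — draws 200 lines with true genotype-specific parameters
uniform in the scanned box, and simulates their observed anthesis
dates with 1.5-day integer noise and 15% missingness.
"""

from phenoscan import (
    DEFAULT_BOX,
    make_observations,
    make_population,
    make_siteyears,
)

siteyears = make_siteyears(seed=42)
print("site-years:")
for sy in siteyears:
    print(
        f"  {sy.site_id}: lat {sy.latitude:6.2f}, sowing DOY {sy.sowing_doy:3d}"
    )

pop = make_population(200, DEFAULT_BOX, seed=43)
obs, table = make_observations(
    pop, siteyears, noise_sd=1.5, missing_rate=0.15, seed=44
)

n_complete = sum(1 for o in obs if len(o.dates) == len(siteyears))
print(f"\nlines with any data: {len(obs)}")
print(f"lines observed in all {len(siteyears)} site-years: {n_complete}")
print(
    "mean observed anthesis (days after sowing): "
    f"{table['anthesis_dap'].mean():.1f}"
)
# The complete-line count reflects the 0.85^11 survival of full panels;
# anthesis in the 50-90 day range is typical maize phenology.
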