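"""Standard aggregate measures on a phantom: %ID/g and tumor-to-heart ratio.

Computes percent injected dose per gram over the whole tumor ROI and over
its high/low sub-regions (split at the 95th percentile of voxel values),
plus the T:H ratio, for one subject at two time points.  With the default
planted clearance the heart signal falls faster than tumor uptake, so T:H
rises between hour 24 and hour 72.
"""

import topouptake as tu

cohort = tu.generate_cohort(tu.PhantomParams(seed=7))
config = tu.RunConfig()

for entry in cohort.for_subject("T1"):
    hour = entry.image.hour
    if hour not in (24.0, 72.0):
        continue
    f, heart_mean = tu.pipeline.process_image(entry, config)
    by_region = tu.roi_measures(f, entry.roi, injected_dose=entry.dose)
    heart_pidg = tu.measures.pidg_from_mean(heart_mean, entry.dose, f.voxel_volume_mm3)
    print(f"hour {hour:g}:")
    for region in ("all", "high", "low"):
        um = by_region[region]
        print(f"  {region:>4}: uptake={um.uptake_total:8.2f} µCi  "
              f"volume={um.volume:7.1f} mm³  %ID/g={um.pidg:7.2f}")
    th = tu.tumor_to_heart(by_region["all"].pidg, heart_pidg)
    print(f"  T:H ratio = {th:.2f}")
print("%ID/g = (uptake/dose x 100)/(volume/1000); T:H = tumor %ID/g / heart %ID/g.")
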