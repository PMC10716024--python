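"""Size a released genome (approach 3) and compare release workflows.

After capsid disassembly the free ssDNA genome lands as its own
population near -0.041 contrast and is sized directly on a
single-stranded nucleic acid calibration.  Heating alone leaves many
fragment (|c| < 0.030) and aggregate (|c| > 0.5) events; heating in SDS
followed by surfactant removal is much cleaner.
"""

from mpsize import (
    SimConfig,
    fit_calibration_from_measurements,
    simulate_calibrant_set,
    simulate_genome_release,
    size_approach3,
)

TRUTH = 4658.0
cfg = SimConfig(seed=1)

for workflow in ("heat", "sds"):
    m = simulate_genome_release(TRUTH, workflow, cfg, measurement_id=workflow)
    c = m.metadata["counts"]
    print(f"{workflow:>4} workflow: {c['genome']} genome, {c['fragment']} fragment, "
          f"{c['aggregate']} aggregate events")

# circular ssDNA plasmids (PhiX174 5,386 b; M13 mp18 7,249 b) + (0, 0) point
plasmid_curve = fit_calibration_from_measurements(
    simulate_calibrant_set("ssDNA_plasmid_bases", cfg), "ssDNA_plasmid_bases"
)
m = simulate_genome_release(TRUTH, "sds", cfg, measurement_id="sds_run")
est = size_approach3(m, plasmid_curve)
print(f"approach 3 estimate: {est:.0f} bases (truth {TRUTH:.0f}, "
      f"accuracy {100 * est / TRUTH:.0f}%)")
print("the overestimation reflects the configured circular-vs-linear ssDNA "
      "contrast ratio (1.19x, plus per-measurement drift): circular plasmid "
      "calibrants scatter less per base than the linear genome")
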