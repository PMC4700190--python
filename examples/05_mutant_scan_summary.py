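"""Summarise the cysteine scan: activity plus oligomer state per region.

Loads the packaged survey of 32 C-surface constructs, computes the
per-region counts (how many keep the wild-type 18-mer elution pattern)
and demonstrates the activity arithmetic on a simulated assay plate with
known true activities.
"""

from spiralscan import classify_activity, load_scan_fixture, relative_activity, summarize_scan
from spiralscan.scan import ActivityMeasurement
from spiralscan.synthetic import simulate_assay_plate

records, regions = load_scan_fixture()
summary = summarize_scan(records, regions)

for name, counts in summary.per_region.items():
    print(f"{name}: {counts.total} constructs, {counts.wild_type_pattern} with the "
          f"wild-type 18-mer pattern, {counts.altered} altered "
          f"({', '.join(counts.altered_ids)})")
print(f"oligomerization-altering substitutions in total: {summary.altered_total}")

# endpoint assay: blank anchors 0%, wild type anchors 100%
plate, truth = simulate_assay_plate({"R67C": 5.0, "Y65C": 45.0, "K68C": 95.0}, seed=1)
wells = lambda sid: [
    ActivityMeasurement(sid, a, i)
    for i, a in enumerate(plate[plate.sample_id == sid].a520)
]
print("\nsimulated picric-acid plate (true activities 5 / 45 / 95 %):")
for mutant in ("R67C", "Y65C", "K68C"):
    res = relative_activity(wells(mutant), wells("wt"), wells("blank"))
    cls = classify_activity(res.percent)
    print(f"  {mutant}: {res.percent:5.1f} +/- {res.sd:.1f} % of wild type -> {cls.value}")
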