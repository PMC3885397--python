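"""Classify ovary histology into development classes and maturity calls.

Builds a handful of ovary snapshots spanning the reproductive cycle, runs
the rule engine, and tabulates the result the way a sampling program
would summarise its histology.
"""

from matogive.histology import (
    AlphaAtresia,
    Mago,
    OvarySnapshot,
    assign_maturity,
    classify_ovary,
    mature_immature_totals,
    tabulate_classes,
)

ovaries = [
    # (description, snapshot, fork length cm)
    ("spawning, hydrated with POFs",
     OvarySnapshot(Mago.HYDRATED, True, AlphaAtresia.LT50, True, True), 95.0),
    ("spawning capable, advanced yolked",
     OvarySnapshot(Mago.ADVANCED_YOLKED, False, AlphaAtresia.NONE, False, False), 91.0),
    ("regressing, majority alpha atresia",
     OvarySnapshot(Mago.ADVANCED_YOLKED, False, AlphaAtresia.GE50, True, False), 99.0),
    ("regenerating, brown bodies only",
     OvarySnapshot(Mago.UNYOLKED, False, AlphaAtresia.NONE, False, True), 88.0),
    ("immature, unyolked",
     OvarySnapshot(Mago.UNYOLKED, False, AlphaAtresia.NONE, False, False), 78.0),
]

records = []
print("per-ovary classification:")
for label, snap, length in ovaries:
    dev = classify_ovary(snap)
    call = assign_maturity(dev, length)
    records.append((dev, call))
    print(f"  {label:38s} -> {dev.value:3s} {call.status.value}/{call.activity.value}")

# a 55 cm fish needs no histology: immature by the macroscopic rule
small = assign_maturity(None, 55.0)
print(f"  {'55 cm fish, no histology':38s} -> -   {small.status.value}")

table = tabulate_classes(records)
mature, immature = mature_immature_totals(table)
print("\ncounts by class:")
print(table.to_string(index=False))
print(f"\ntotals: {mature} mature, {immature} immature")
print("C3-C7 count as mature (active or inactive); C1-C2 as immature.")
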