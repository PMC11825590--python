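"""Classify one patient against the control cohort's box-whisker limits.

The "inter-ocular trauma test": a well is of interest when the patient's
log energy-production summary falls outside the outer limits of the
control box plot (whiskers by default, Tukey fences with method="fence").
"""

import numpy as np

from pmprofile import builtin_layout, call_wells
from pmprofile.kinetics import summarize_dataset
from pmprofile.simulate import PatientSpec, SimulationConfig, simulate_cohort
from pmprofile.plates import WellAddress

layout = builtin_layout()
config = SimulationConfig(n_controls=20, n_female=10, n_male=10, plates=("PM-M8",), seed=3)
patient = PatientSpec("P1", "case", "M")
# deficit everywhere on the hormone plate except TNF-alpha (G10)
effects = {
    ("P1", a): -1.2 for a in layout.wells_for_plate("PM-M8") if a.well != "G10"
}
cohort = simulate_cohort(config, layout, [patient], effects)
summaries = summarize_dataset(kinetics=cohort.kinetics, source="auc")

controls = cohort.samples.loc[cohort.samples.group == "control", "sample_id"]
callset = call_wells(summaries, "P1", controls, method="whisker")
counts = callset.counts()
print(f"calls for P1 over {len(callset.calls)} PM-M8 wells:")
print(f"  below the lower whisker: {counts['below']}")
print(f"  within the whiskers:     {counts['within']}")
print(f"  above the upper whisker: {counts['above']}")

g10 = next(c for c in callset.calls if c.address == WellAddress("PM-M8", "G10"))
print(
    f"G10 (TNF-alpha): value {g10.value:.3f} vs limits "
    f"[{g10.limits.lower:.3f}, {g10.limits.upper:.3f}] -> {g10.call}"
)
# Nearly every shifted well should be called "below"; G10 carries no
# effect, so it should sit within the control whiskers.
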