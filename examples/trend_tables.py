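"""Compound-level trend tables, opposite trends, and cluster fractions.

Builds single-case calls for two patient groups with partly opposing
profiles and aggregates them the way the reporting tables do.
"""

from pmprofile import builtin_layout, cluster_fraction, opposite_trends, shared_trend
from pmprofile.plates import wells_matching
from pmprofile.single_case import ControlLimits, SingleCaseCall
from pmprofile.summarize import TrendTable, direction_table

layout = builtin_layout()
LIMITS = ControlLimits(q1=2.4, q3=2.6, lower=2.3, upper=2.7, method="whisker")


def call(addr, kind, patient):
    value = {"above": 3.0, "below": 2.0, "within": 2.5}[kind]
    return SingleCaseCall(addr, patient, value, LIMITS, kind)


opposite = ["FGF-1(aFGF)", "IL-1beta", "Glu-Trp", "Gln-Gly", "Trp-Tyr"]
shared_up = ["Pectin", "Adenosine", "Pyruvic acid", "Ile-Gln", "Ser-Gln"]
opp_wells = [a for name in opposite for a in wells_matching(layout, name)]
up_wells = [a for name in shared_up for a in wells_matching(layout, name)]

dup_calls = [call(a, "above", "DUP01") for a in opp_wells + up_wells]
lof_calls = [call(a, "below", "RTT01") for a in opp_wells] + [
    call(a, "above", "RTT01") for a in up_wells
]
table = direction_table({"MRXSL": dup_calls, "RTT": lof_calls}, layout)
for group in table.groups():
    inc, dec = table.group_counts(group)
    print(f"{group}: {inc} compounds increased, {dec} decreased")

dup = TrendTable(tuple(r for r in table.rows if r.group == "MRXSL"))
lof = TrendTable(tuple(r for r in table.rows if r.group == "RTT"))
print("opposite trends:", opposite_trends(dup, lof))
print("shared increases:", shared_trend({"MRXSL": dup, "RTT": lof}, "increased"))

# cluster fraction: 12 of the 30 glycine-containing wells called decreased
gly = wells_matching(layout, "Gly")
gly_calls = [call(a, "below", "RTT01") for a in gly[:12]] + [
    call(a, "within", "RTT01") for a in gly[12:]
]
cs = cluster_fraction(gly_calls, gly, "decreased", "glycine")
print(f"glycine cluster: {cs.k}/{cs.n} wells decreased = {cs.percent}%")
# The five designed opposite-trend compounds and the five shared
# increases are recovered exactly; the glycine fraction prints 40.0%.
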