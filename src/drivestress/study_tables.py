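"""Published per-subject results and group summaries of the driving study.

The original study recorded 22 male drivers (11 elderly, 61–72 y; 11 young,
22–35 y) on a staged stressful-driving course; the raw recordings were never
deposited, but the report prints the per-subject SDI/CRT estimates, the
questionnaire score summaries and the per-stage RR-interval group means.
Those printed values are inputs here: the stats module reproduces the
report's group means, SDs and pooled t statistics from them.
"""

from __future__ import annotations

from .stats import GroupSummary

#: per-subject Safe Driving Intensity (m/s²), 11 subjects per group
SDI_ELDERLY = [3.75, 3.37, 3.96, 3.35, 2.99, 3.29, 2.79, 2.49, 2.57, 4.04, 2.90]
SDI_YOUNG = [3.18, 3.60, 3.71, 3.41, 3.23, 2.28, 3.45, 3.69, 3.29, 2.97, 3.69]

#: per-subject Cardiac Response Time (s)
CRT_ELDERLY = [13.79, 13.94, 14.83, 14.88, 13.96, 14.03, 12.71, 14.81, 13.19, 14.71, 13.54]
CRT_YOUNG = [13.52, 13.89, 12.9, 13.97, 14.49, 15.35, 13.26, 13.76, 14.4, 7.58, 16]

#: questionnaire score summaries (young, elderly) per part, n = 11 each
QUESTIONNAIRE = {
    "skill": (GroupSummary(11, 19.45, 7.35), GroupSummary(11, 18.00, 5.62)),
    "aggressiveness": (GroupSummary(11, 39.00, 10.58), GroupSummary(11, 36.18, 12.50)),
    "concentration": (GroupSummary(11, 16.09, 4.53), GroupSummary(11, 9.09, 2.66)),
}

#: per-stage RR interval summaries (ms): stage -> (young, elderly)
RR_STAGE_SUMMARIES = {
    "before": (GroupSummary(11, 649.43, 76.20), GroupSummary(11, 812.29, 63.18)),
    "driving": (GroupSummary(11, 624.63, 82.49), GroupSummary(11, 752.87, 65.66)),
    "after": (GroupSummary(11, 657.93, 85.74), GroupSummary(11, 803.36, 77.32)),
}
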