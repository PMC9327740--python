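"""Scoring INR series with the Rosendaal time-in-therapeutic-range method.

Builds three small hand-checkable series, scores them against the 2.5-3.5
therapeutic range, and summarizes them as a cohort.
"""

from warfcea import INRSeries, cohort_ttr_summary, rosendaal_ttr

examples = {
    "steady in range": [(0, 3.0), (30, 3.0)],
    "rising from 2.0": [(0, 2.0), (30, 3.0)],
    "falling 4.5->1.5": [(0, 4.5), (60, 1.5)],
}

results = []
for label, pairs in examples.items():
    res = rosendaal_ttr(INRSeries.from_pairs(pairs, patient_id=label))
    results.append(res)
    print(
        f"{label:18}: TTR {res.ttr_percent:6.2f}%  "
        f"below {res.percent_below:6.2f}%  above {res.percent_above:6.2f}%  "
        f"[{res.category}]"
    )
# The second series crosses 2.5 at day 15 (half the span in range); the
# third spends equal thirds above, within and below the range (crossings at
# days 20 and 40 under the -0.05/day slope).

summary = cohort_ttr_summary(results)
print(
    f"\ncohort: n={summary.n}, median TTR {summary.median:.1f}% "
    f"(IQR {summary.iqr_low:.1f}-{summary.iqr_high:.1f}), "
    f"categories {summary.category_counts}"
)
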