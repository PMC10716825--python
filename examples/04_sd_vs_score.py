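"""Why the SD of metric scores is a misleading selection criterion.

A model that is uniformly mediocre has zero spread across its metrics — the
smallest possible SD — yet encloses a far smaller polygon than a model that
is strong on every metric. The report keeps both rankings side by side.
"""

from mlcps import MetricsTable, compare_rankings

table = MetricsTable(
    ["steady_poor", "strong"],
    ["m1", "m2", "m3", "m4"],
    [[0.5, 0.5, 0.5, 0.5],
     [0.95, 0.90, 0.92, 0.93]],
)

report = compare_rankings(table)
print(report.to_string())
# steady_poor wins the SD ranking (rank_sd = 1, SD = 0) but loses the
# composite ranking: consistency alone is not performance.
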