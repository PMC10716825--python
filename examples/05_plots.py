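"""Render the three plot kinds: radar, ranked bars, SD-vs-score comparison.

Writes SVG files into the current directory. The same data arrays drawn
here are exposed by radar_plot_data / bar_plot_data / sd_comparison_plot_data
for programmatic use.
"""

from mlcps import (
    PlotSpec,
    compare_rankings,
    compute_mlcps_table,
    make_metric_table,
    render,
)

table = make_metric_table(n_models=5, n_metrics=6, structure="random", seed=11)
results = compute_mlcps_table(table)
report = compare_rankings(table)

for path in (
    render(table, PlotSpec("radar", "radar.svg", title="metric polygons")),
    render(results, PlotSpec("bar", "scores.svg", title="composite scores")),
    render(report, PlotSpec("sd_comparison", "sd_vs_score.svg",
                            title="SD vs composite score")),
):
    print(f"wrote {path}")
# radar: one closed polygon per model on a shared frame; bar: models sorted
# by score with rank in brackets; sd_comparison: SD bars ascending with the
# composite score overlaid on a second axis.
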