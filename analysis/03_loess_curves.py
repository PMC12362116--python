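#!/usr/bin/env python
"""Descriptive LOESS curves of sensitivity against distance from GA.

One pooled baseline curve, per-axis baseline curves, and per-visit curves
(span 0.5, local degree 1), exported as CSV and plotted.
"""

import dataclasses

from common import RESULTS, demo_annotated

from perilesion.loess import curves_by_stratum, curves_to_frame


def main() -> None:
    annotated = demo_annotated()
    baseline = annotated[annotated["visit_month"] == 0]

    pooled = [
        dataclasses.replace(c, stratum="baseline_all")
        for c in curves_by_stratum(baseline, "none", n_eval=100)
    ]
    per_axis = curves_by_stratum(baseline, "axis", n_eval=100)
    per_visit = curves_by_stratum(annotated, "visit", n_eval=100)

    frame = curves_to_frame(pooled + per_axis + per_visit)
    frame["x_deg"] = frame["x_deg"].round(3)
    frame["fitted_db"] = frame["fitted_db"].round(3)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "loess_curves.csv", index=False)

    base = pooled[0]
    lo, hi = base.fitted_y[0], base.fitted_y[-1]
    print(f"baseline pooled curve: {base.n_points} points, "
          f"{lo:.1f} dB at {base.grid_x[0]:.2f} deg -> {hi:.1f} dB at {base.grid_x[-1]:.1f} deg")
    print(f"per-axis curves: {[c.stratum for c in per_axis]}")
    print(f"per-visit curves retained: {len(per_visit)} "
          f"({[c.stratum for c in per_visit]})")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    axes[0].scatter(
        baseline.loc[~baseline.inside_ga, "ga_distance_deg"],
        baseline.loc[~baseline.inside_ga, "sensitivity_db"],
        s=6, alpha=0.25, color="grey",
    )
    axes[0].plot(base.grid_x, base.fitted_y, lw=2, color="crimson")
    axes[0].set_title("baseline, all axes")
    for c in per_visit:
        axes[1].plot(c.grid_x, c.fitted_y, label=c.stratum)
    axes[1].legend(fontsize=7)
    axes[1].set_title("by visit")
    for ax in axes:
        ax.set_xlabel("distance from GA border (deg)")
    axes[0].set_ylabel("sensitivity (dB)")
    fig.tight_layout()
    fig.savefig(RESULTS / "loess_curves.png", dpi=130)
    print(f"curves -> {RESULTS / 'loess_curves.csv'} (+ .png)")


if __name__ == "__main__":
    main()
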