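#!/usr/bin/env python
"""Fit the segmented (quadratic-then-linear) mixed model to the cohort.

Reports the estimated knot, segment coefficients, time effect and variance
components with Wald 95% CIs, plus the worked per-interval sensitivity
changes below the knot.  Also refits with the foveal-distance covariate as
a supplementary analysis.
"""

import json

from common import RESULTS, demo_annotated

from perilesion.model import KnotStraddleError, fit, fit_with_foveal_covariate, mean_function


def main() -> None:
    annotated = demo_annotated()
    result = fit(annotated)

    report = result.to_frame().round(4)
    RESULTS.mkdir(exist_ok=True)
    report.to_csv(RESULTS / "fit_report.csv", index=False)

    print(f"fit on {result.n_obs} extralesional observations in "
          f"{result.n_clusters} participant-visit clusters "
          f"(converged: {result.converged}, loglik {result.loglik:.1f})")
    print(report.to_string(index=False))

    k = result.params.knot
    print(f"\nestimated knot: {k:.2f} deg "
          f"(95% CI {result.ci95['knot'][0]:.2f}, {result.ci95['knot'][1]:.2f})")
    changes = {}
    for mid in (0.5, 1.0, 1.5):
        label = f"change_{mid - 0.5:g}_to_{mid + 0.5:g}_deg"
        try:
            ic = result.interval_change(mid)
            changes[label] = {
                "estimate_db": round(ic.estimate, 2),
                "ci95": [round(v, 2) for v in ic.ci95],
            }
            print(f"sensitivity change over [{mid - 0.5:g}, {mid + 0.5:g}] deg: "
                  f"{ic.estimate:.2f} dB (95% CI {ic.ci95[0]:.2f}, {ic.ci95[1]:.2f})")
        except KnotStraddleError:
            # interval crosses the estimated knot: difference the mean directly
            est = mean_function(mid + 0.5, 0.0, result.params) - mean_function(
                mid - 0.5, 0.0, result.params
            )
            changes[label] = {"estimate_db": round(est, 2), "ci95": None}
            print(f"sensitivity change over [{mid - 0.5:g}, {mid + 0.5:g}] deg: "
                  f"{est:.2f} dB (interval crosses the knot; direct differencing)")
    above = result.interval_change(k + 1.5)
    print(f"per-degree change beyond the knot: {above.estimate:.2f} dB "
          f"(95% CI {above.ci95[0]:.2f}, {above.ci95[1]:.2f})")

    supp = fit_with_foveal_covariate(annotated)
    print(f"\nsupplementary fit with foveal-distance covariate: "
          f"beta_f = {supp.params.beta_f:.3f} (SE {supp.se['beta_f']:.3f}), "
          f"knot moves {k:.2f} -> {supp.params.knot:.2f} deg")

    (RESULTS / "interval_changes.json").write_text(json.dumps(changes, indent=1))


if __name__ == "__main__":
    main()
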