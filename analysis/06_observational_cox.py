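"""Observational stage: Cox models per endpoint, and the comparison with MR.

Fits model-1 and model-2 Cox proportional-hazards regressions of each
cardiovascular endpoint on fasting serum glucose in the outcome cohort,
then contrasts the observational per-10 mg/dL hazard ratio with the
causal per-10 odds ratio from the univariable MR stage — under the
default negative-confounding scenario the observational estimate is
attenuated.
"""

import pandas as pd

from mrglyc import summary_io
from mrglyc.cohort import cox_fit
from mrglyc.mr_uni import ivw

from _common import RESULTS, study, summary_stats


def main():
    cfg, variants, _, out_arr = study()
    rows = []
    for endpoint in ("ASCVD", "IHD", "AMI", "stroke_total"):
        for model in ("model1", "model2"):
            try:
                res = cox_fit(out_arr, covariate_set=model, endpoint=endpoint)
            except ValueError as exc:
                print(f"{endpoint}/{model}: skipped ({exc})")
                continue
            lo, hi = res.hr_per10_ci
            rows.append({"endpoint": endpoint, "model": model,
                         "n_events": res.n_events,
                         "hr_per10": round(res.hr_per10, 3),
                         "ci": f"({lo:.3f}, {hi:.3f})",
                         "pval": res.pval, "ph_check_p": round(res.ph_check_p, 3)})
    tbl = pd.DataFrame(rows)
    tbl.to_csv(RESULTS / "cox_models.tsv", sep="\t", index=False)
    print(tbl.to_string(index=False))

    hset = summary_io.harmonize(summary_stats("exposure"), summary_stats("outcome"))
    mr_est, _ = ivw(hset)
    ascvd_m1 = next(r for r in rows if r["endpoint"] == "ASCVD" and r["model"] == "model1")
    print(f"\nASCVD per 10 mg/dL: observational HR {ascvd_m1['hr_per10']:.3f} vs "
          f"causal (IVW) OR {mr_est.or_per10:.3f} — the confounded observational "
          f"estimate is {'attenuated' if ascvd_m1['hr_per10'] < mr_est.or_per10 else 'inflated'}.")


if __name__ == "__main__":
    main()
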