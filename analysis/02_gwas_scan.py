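"""Per-variant QC and association scans.

Runs the MAF/HWE filters and the per-variant regressions (linear for
glucose, SBP and LDL in the exposure cohort; logistic for events in the
outcome cohort) and writes the four summary-statistic files that the MR
stages consume.
"""

from mrglyc import summary_io

from _common import RESULTS, study, summary_stats


def main():
    cfg, variants, _, _ = study()
    for trait in ("exposure", "sbp", "ldl", "outcome"):
        recs = summary_stats(trait)
        path = RESULTS / f"gwas_{trait}.tsv"
        summary_io.write_summary_stats(recs, path)
        top = min(recs, key=lambda r: r.pval)
        print(f"{trait:>8}: {len(recs)}/{cfg.J} variants pass QC; "
              f"top hit {top.variant.id} (beta={top.beta:.4f}, p={top.pval:.2e}) "
              f"-> {path.name}")


if __name__ == "__main__":
    main()
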