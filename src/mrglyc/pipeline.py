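"""Orchestration: simulate -> gwas -> mr / mvmr / nlmr / cohort as one run.

A run is configured by a YAML file (validated before any stage starts),
executes its stages in dependency order, writes each stage's tables
under the output directory, and records a manifest with the config
hash, seed, per-stage output digests and package version.  Outputs are
deterministic given (config, seed): rerunning a stage regenerates
byte-identical files, which the manifest digests make checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, cohort as cohort_mod, mr_uni, mvmr as mvmr_mod, nlmr, summary_io, synth

__all__ = ["RunManifest", "ConfigError", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "gwas", "mr", "mvmr", "nlmr", "cohort")

log = logging.getLogger("mrglyc")


class ConfigError(ValueError):
    pass


@dataclass
class StageRecord:
    name: str
    status: str                      # completed | failed | skipped
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    detail: str = ""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[StageRecord]
    package_version: str
    started: str
    finished: str = ""

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(
            {**asdict(self), "stages": [asdict(s) for s in self.stages]}, indent=2,
        ))


_DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "sim": {},
    "mr": {"methods": ["ivw", "egger", "wmedian"], "per_unit": 10.0},
    "mvmr": {"exposures": ["exposure", "sbp", "ldl"]},
    "nlmr": {"strata": 10},
    "cohort": {"endpoints": ["ASCVD", "IHD", "stroke_total"], "models": ["model1", "model2"]},
}

_SIM_KEYS = {
    "J", "maf", "n_exposure_cohort", "n_outcome_cohort", "beta_gx", "h2_exposure",
    "theta", "alpha", "pleiotropy_mode", "pleiotropy_mean", "pleiotropy_sd",
    "exposure_mean", "exposure_sd", "confounder_effects", "outcome_shape",
    "quadratic_coeff", "threshold_value", "baseline_hazard", "followup_years",
}


def load_config(source: str | Path | dict | None, seed: int | None = None) -> dict[str, Any]:
    """Load and validate a run configuration; errors are raised before any stage."""
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")

    cfg = {**_DEFAULT_CONFIG, **raw}
    for key in ("mr", "mvmr", "nlmr", "cohort", "sim"):
        merged = {**_DEFAULT_CONFIG.get(key, {}), **(raw.get(key) or {})}
        cfg[key] = merged
    if seed is not None:
        cfg["seed"] = seed
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer")

    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    bad_sim = set(cfg["sim"]) - _SIM_KEYS
    if bad_sim:
        raise ConfigError(f"unknown sim key(s): {sorted(bad_sim)}")
    if "mvmr" in cfg["stages"]:
        secondaries = cfg["mvmr"].get("exposures", [])
        non_primary = [e for e in secondaries if e != "exposure"]
        if not non_primary:
            raise ConfigError(
                "mvmr stage requested but config block 'mvmr.exposures' names no "
                "secondary exposures"
            )
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cohort_frame(arr: dict[str, np.ndarray], variants) -> pd.DataFrame:
    df = pd.DataFrame({
        "exposure": arr["exposure"], "time": arr["time"], "event_code": arr["event_code"],
    })
    for k in ("age", "sex", "sbp", "ldl", "hdl", "smoking", "alcohol",
              "exercise", "bmi", "tg", "income"):
        if k in arr:
            df[k] = arr[k]
    G = arr["genotypes"]
    for j, v in enumerate(variants):
        df[f"g_{v.id}"] = G[:, j]
    return df


def read_cohort_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read a cohort TSV (as written by the simulate stage) back into arrays."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    gcols = [c for c in df.columns if c.startswith("g_")]
    arr: dict[str, np.ndarray] = {
        "genotypes": df[gcols].to_numpy(dtype=np.int8),
        "variant_ids": np.array([c[2:] for c in gcols], dtype=object),
        "event_code": df["event_code"].astype(str).to_numpy(dtype=object),
    }
    arr["event"] = np.array([1.0 if c else 0.0 for c in arr["event_code"]])
    for c in df.columns:
        if c not in gcols and c != "event_code":
            arr[c] = df[c].to_numpy(dtype=float)
    return arr


def mr_table(hset: summary_io.HarmonizedSet, methods: Sequence[str],
             per_unit: float = 10.0, seed: int = 0) -> pd.DataFrame:
    """Tidy univariable-MR results table (one row per method)."""
    rows = []
    egger_p = None
    if "egger" in methods or "pleiotropy" in methods:
        egger_p = mr_uni.egger(hset)
    for m in methods:
        if m == "ivw":
            est, het = mr_uni.ivw(hset)
            extra = {"Q": het.Q, "Q_df": het.df, "Q_p": het.pval}
        elif m == "egger":
            est = egger_p.slope
            extra = {"intercept": egger_p.intercept, "pleiotropy_p": egger_p.intercept_pval}
        elif m == "wmedian":
            est = mr_uni.weighted_median(hset, seed=seed)
            extra = {}
        else:
            raise ConfigError(f"unknown MR method {m!r}")
        lo, hi = est.or_per10_ci
        rows.append({
            "method": est.method, "estimate_per_unit": est.estimate, "se": est.se,
            f"or_per{per_unit:g}": float(np.exp(per_unit * est.estimate)),
            "ci_low": float(np.exp(per_unit * est.ci_low)),
            "ci_high": float(np.exp(per_unit * est.ci_high)),
            "pval": est.pval, **extra,
        })
    return pd.DataFrame(rows)


def build_mvmr_set(exposure_stats: dict[str, list], outcome_stats: list) -> mvmr_mod.MVMRSet:
    """Assemble an MVMR set from per-exposure and outcome summary statistics,
    keeping only variants present everywhere (matched by id)."""
    out_by_id = {r.variant.id: r for r in outcome_stats}
    maps = {name: {r.variant.id: r for r in recs} for name, recs in exposure_stats.items()}
    ids = [i for i in maps[next(iter(maps))] if i in out_by_id
           and all(i in m for m in maps.values())]
    names = list(exposure_stats)
    return mvmr_mod.MVMRSet(
        gamma_mat=np.column_stack([[maps[n][i].beta for i in ids] for n in names]),
        sigma_mat=np.column_stack([[maps[n][i].se for i in ids] for n in names]),
        Gamma_out=np.array([out_by_id[i].beta for i in ids]),
        sigma_Gamma=np.array([out_by_id[i].se for i in ids]),
        exposure_names=names,
    )


def run_pipeline(config: str | Path | dict | None, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the configured stages and return the run manifest.

    A stage failure marks all downstream stages "skipped"; the manifest
    and report are written regardless.
    """
    cfg = load_config(config, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_hash=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=cfg["seed"], stages=[], package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    sim_cfg = synth.SimConfig(seed=cfg["seed"], **cfg["sim"])
    variants = sim_cfg.variants()
    state: dict[str, Any] = {}
    failed = False
    report_lines = [f"# mrglyc run report", "", f"seed: {cfg['seed']}", ""]

    def run_stage(name, fn):
        nonlocal failed
        if name not in cfg["stages"]:
            return
        if failed:
            manifest.stages.append(StageRecord(name=name, status="skipped",
                                               detail="upstream failure"))
            return
        try:
            t0 = time.time()
            outputs = fn() or []
            rec = StageRecord(name=name, status="completed",
                              outputs={p.name: _sha256(p) for p in outputs})
            log.info("[%s] completed in %.1fs (%d outputs)", name, time.time() - t0, len(outputs))
            manifest.stages.append(rec)
        except Exception as exc:
            failed = True
            log.error("[%s] failed: %s", name, exc)
            manifest.stages.append(StageRecord(name=name, status="failed", detail=str(exc)))

    def stage_simulate():
        exp_arr = synth.simulate_cohort_arrays(sim_cfg, "exposure")
        out_arr = synth.simulate_cohort_arrays(sim_cfg, "outcome")
        state["exp_arr"], state["out_arr"] = exp_arr, out_arr
        paths = []
        for tag, arr in (("exposure", exp_arr), ("outcome", out_arr)):
            p = out / f"{tag}_cohort.tsv"
            _cohort_frame(arr, variants).to_csv(p, sep="\t", index=False)
            paths.append(p)
            log.info("[simulate] %s cohort: n=%d, events=%d", tag,
                     arr["exposure"].shape[0], int(arr["event"].sum()))
        return paths

    def stage_gwas():
        paths = []
        traits = {"exposure": "exposure"}
        for name in cfg["mvmr"]["exposures"]:
            traits[name] = name
        for name in traits:
            recs = synth.cohort_to_summary_stats(state["exp_arr"], name, variants)
            state[f"ss_{name}"] = recs
            p = out / f"gwas_{name}.tsv"
            summary_io.write_summary_stats(recs, p)
            paths.append(p)
            log.info("[gwas] %s scan: %d variants pass QC", name, len(recs))
        recs = synth.cohort_to_summary_stats(state["out_arr"], "outcome", variants)
        state["ss_outcome"] = recs
        p = out / "gwas_outcome.tsv"
        summary_io.write_summary_stats(recs, p)
        paths.append(p)
        log.info("[gwas] outcome scan: %d variants pass QC", len(recs))
        return paths

    def stage_mr():
        hset = summary_io.harmonize(state["ss_exposure"], state["ss_outcome"])
        state["hset"] = hset
        log.info("[mr] harmonized J=%d, dropped=%d", len(hset), len(hset.dropped))
        tbl = mr_table(hset, cfg["mr"]["methods"], cfg["mr"]["per_unit"], seed=cfg["seed"])
        p = out / "mr_results.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        report_lines.extend(["## Univariable MR", tbl.to_string(index=False), ""])
        return [p]

    def stage_mvmr():
        names = cfg["mvmr"]["exposures"]
        mset = build_mvmr_set({n: state[f"ss_{n}"] for n in names}, state["ss_outcome"])
        res = mvmr_mod.mvmr_fit(mset)
        rows = [{
            "exposure": n, "direct_effect": e.estimate, "se": e.se, "pval": e.pval,
            "or_per10": e.or_per10, "conditional_F": f,
        } for n, e, f in zip(res.exposure_names, res.direct_effects, res.conditional_F)]
        tbl = pd.DataFrame(rows)
        p = out / "mvmr_results.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        q = res.q_validity
        line = (f"Q-statistic for instrument validity was {q.Q:.2f} on {q.df} "
                f"degrees of freedom (p={q.pval:.3f})")
        log.info("[mvmr] %s", line)
        report_lines.extend(["## Multivariable MR", tbl.to_string(index=False), "", line, ""])
        (out / "mvmr_validity.txt").write_text(line + "\n")
        return [p, out / "mvmr_validity.txt"]

    def stage_nlmr():
        arr = state["out_arr"]
        weights = np.array([
            {r.variant.id: r.beta for r in state["ss_exposure"]}.get(v.id, 0.0)
            for v in variants
        ])
        resid, score, bx = nlmr.iv_free_exposure(arr["genotypes"], arr["exposure"], weights)
        strata = nlmr.stratify_and_lace(arr["exposure"], score, arr["event"], resid,
                                        S=cfg["nlmr"]["strata"], beta_x=bx)
        st_tbl = pd.DataFrame([asdict(s) for s in strata])
        p1 = out / "nlmr_strata.tsv"
        st_tbl.to_csv(p1, sep="\t", index=False)
        fp = nlmr.fracpoly_fit(strata)
        pw = nlmr.piecewise_fit(strata, reference=fp.reference,
                                x_range=(float(arr["exposure"].min()),
                                         float(arr["exposure"].max())))
        xs = np.linspace(min(s.x_mean for s in strata), max(s.x_mean for s in strata), 101)
        v1, lo1, hi1 = fp.curve_band(xs)
        v2, lo2, hi2 = pw.curve_band(xs)
        curve_tbl = pd.DataFrame({
            "exposure": xs,
            "fracpoly_logor": v1, "fracpoly_lo": lo1, "fracpoly_hi": hi1,
            "piecewise_logor": v2, "piecewise_lo": lo2, "piecewise_hi": hi2,
        })
        p2 = out / "nlmr_curves.tsv"
        curve_tbl.to_csv(p2, sep="\t", index=False)
        state["fracpoly"] = fp
        log.info("[nlmr] best power %s, non-linearity p=%.3f", fp.power, fp.nonlinearity_p)
        report_lines.extend([
            "## Non-linear MR",
            f"best fractional-polynomial power: {fp.power}",
            f"non-linearity p-value: {fp.nonlinearity_p:.3f}", "",
        ])
        p3 = out / "nlmr_curve.png"
        _plot_curves(xs, fp, pw, p3)
        return [p1, p2]

    def stage_cohort():
        rows = []
        for endpoint in cfg["cohort"]["endpoints"]:
            for model in cfg["cohort"]["models"]:
                try:
                    res = cohort_mod.cox_fit(state["out_arr"], covariate_set=model,
                                             endpoint=endpoint)
                except ValueError as exc:
                    log.warning("[cohort] %s/%s skipped: %s", endpoint, model, exc)
                    continue
                lo, hi = res.hr_per10_ci
                rows.append({
                    "endpoint": endpoint, "model": model, "n_events": res.n_events,
                    "hr_per10": res.hr_per10, "ci_low": lo, "ci_high": hi,
                    "pval": res.pval, "ph_check_p": res.ph_check_p,
                })
        tbl = pd.DataFrame(rows)
        p = out / "cox_results.tsv"
        tbl.to_csv(p, sep="\t", index=False)
        report_lines.extend(["## Observational Cox models", tbl.to_string(index=False), ""])
        return [p]

    run_stage("simulate", stage_simulate)
    run_stage("gwas", stage_gwas)
    run_stage("mr", stage_mr)
    run_stage("mvmr", stage_mvmr)
    run_stage("nlmr", stage_nlmr)
    run_stage("cohort", stage_cohort)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(out / "manifest.json")
    (out / "report.md").write_text("\n".join(report_lines))
    log.removeHandler(fh)
    fh.close()
    return manifest


def _plot_curves(xs, fp, pw, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, fit, title in ((axes[0], fp, f"fractional polynomial (p={fp.power:g})"),
                           (axes[1], pw, "piecewise linear")):
        v, lo, hi = fit.curve_band(xs)
        ax.plot(xs, v, "k-")
        ax.plot(xs, lo, "k:", xs, hi, "k:")  # dotted 95% band
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("fasting serum glucose (mg/dL)")
        ax.set_title(title)
    axes[0].set_ylabel("log odds ratio vs reference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
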