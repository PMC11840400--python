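"""Shared setup for the numbered analysis scripts.

Every script regenerates the same synthetic two-cohort study from one
master seed, so each is independently runnable and all agree on inputs.
"""

from pathlib import Path

from mrglyc import synth

SEED = 2025
RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

_cache: dict = {}


def study():
    """(config, variants, exposure-cohort arrays, outcome-cohort arrays)."""
    if not _cache:
        cfg = synth.SimConfig(seed=SEED)
        _cache["cfg"] = cfg
        _cache["variants"] = cfg.variants()
        _cache["exp"] = synth.simulate_cohort_arrays(cfg, "exposure")
        _cache["out"] = synth.simulate_cohort_arrays(cfg, "outcome")
    return _cache["cfg"], _cache["variants"], _cache["exp"], _cache["out"]


def summary_stats(trait: str):
    cfg, variants, exp_arr, out_arr = study()
    key = f"ss_{trait}"
    if key not in _cache:
        arr = out_arr if trait == "outcome" else exp_arr
        _cache[key] = synth.cohort_to_summary_stats(arr, trait, variants)
    return _cache[key]
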