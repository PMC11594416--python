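"""Separation and spread of the output-layer evidence distributions.

The evidence variable is the network's pre-sigmoid output logit, analyzed
per true stimulus class: separation = mu_S2 - mu_S1 and spread = the mean
of the two class-conditional SDs (sample SD, n-1).  The logit rather than
the sigmoid output is used because each network represents evidence on its
own unbounded internal axis; the sigmoid would compress both statistics
near its saturation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stimuli
from .behavior import trial_table, paired_ttest, rm_anova
from .stimuli import ENERGY_CONDITIONS, LEVELS

__all__ = ["evidence_stats", "evidence_table", "run_factorized_manipulation"]


def evidence_stats(trials: pd.DataFrame) -> pd.DataFrame:
    """Per instance x condition evidence statistics from a trial table.

    Requires columns instance_id, condition, true_label, logit; every
    (instance, condition) cell must contain >= 2 trials of each class.
    """
    rows = []
    for (inst, cond), g in trials.groupby(["instance_id", "condition"],
                                          sort=False):
        s1 = g.loc[g["true_label"] == 0, "logit"].to_numpy()
        s2 = g.loc[g["true_label"] == 1, "logit"].to_numpy()
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError(
                f"instance {inst}, condition {cond}: need >= 2 trials per class"
            )
        mu1, mu2 = s1.mean(), s2.mean()
        sd1 = s1.std(ddof=1)
        sd2 = s2.std(ddof=1)
        rows.append({"instance_id": inst, "condition": cond,
                     "mu_s1": mu1, "mu_s2": mu2,
                     "separation": mu2 - mu1,
                     "avg_sd": (sd1 + sd2) / 2.0,
                     "n_trials": len(g)})
    return pd.DataFrame(rows)


evidence_table = evidence_stats  # convenience alias


_AXIS_PARAMS = {
    # which condition parameter each manipulation axis moves, per experiment
    "gabor_array": {"contrast": "contrast", "variability": "orientation_sd"},
    "superimposed": {"contrast": "contrast", "variability": "nondominant_contrast"},
    "single_gabor": {"contrast": "contrast", "variability": "noise_sd"},
    "color_array": {"contrast": "color_intensity", "variability": "color_spread"},
}


def run_factorized_manipulation(ensemble, experiment: str, axis: str,
                                levels=None, n_per_level: int = 1000,
                                seed: int = 0):
    """Manipulate contrast or variability alone, holding the other fixed.

    By default the manipulated axis takes its three energy-condition
    values while the fixed axis stays at its mid-energy value.  Returns
    ``(stats, tests)``: evidence statistics per instance x level and
    paired-test / RM-ANOVA summaries on separation and spread.
    """
    if axis not in ("contrast", "variability"):
        raise ValueError("axis must be 'contrast' or 'variability'")
    moved = _AXIS_PARAMS[experiment][axis]
    fixed = _AXIS_PARAMS[experiment]["variability" if axis == "contrast" else "contrast"]
    table = ENERGY_CONDITIONS[experiment]
    if levels is None:
        levels = [table[lvl][moved] for lvl in LEVELS]
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    fixed_value = table["mid"][fixed]
    frames = []
    for k, value in enumerate(levels):
        cparams = {moved: value, fixed: fixed_value}
        if experiment == "superimposed":
            # keep the dominance constraint satisfiable at every level
            cparams["contrast"] = max(cparams["contrast"],
                                      cparams["nondominant_contrast"] + 0.01)
        samples = stimuli.make_test_set(experiment, cparams, n=n_per_level,
                                        seed=seed + k)
        for i, net in enumerate(ensemble):
            frames.append(trial_table(net, samples, instance_id=i,
                                      condition=f"level{k}"))
    trials = pd.concat(frames, ignore_index=True)
    st = evidence_stats(trials)
    lo, hi = "level0", f"level{len(levels) - 1}"
    tests = {}
    for dv in ("separation", "avg_sd"):
        tests[dv] = {
            "paired_low_high": paired_ttest(st, (lo, hi), dv=dv),
        }
        if len(ensemble) >= 2 and len(levels) >= 2:
            tests[dv]["rm_anova"] = rm_anova(st, dv=dv)
    return st, tests
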