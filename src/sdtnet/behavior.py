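"""Decisions, confidence, and ensemble-level behavioral statistics.

The network's single sigmoid output ``a`` is read out with the standard
piecewise rule: respond S2 when ``a >= 0.5`` (ties to S2), S1 otherwise;
confidence is ``a`` for S2 responses and ``1 - a`` for S1 responses, so
``c`` always lies in [0.5, 1].

`run_energy_experiment` tests every instance of a trained ensemble on the
three energy conditions of an experiment and returns a per-trial table and
a per-instance x condition summary; `rm_anova` and `paired_ttest` apply the
within-subject statistics used at the ensemble level (instances play the
role of subjects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import stimuli
from .stimuli import EnergyCondition, LEVELS

__all__ = ["decide_and_score", "trial_table", "run_energy_experiment",
           "summarize_conditions", "rm_anova", "paired_ttest"]


def decide_and_score(a):
    """Piecewise readout of responses and confidence from activations.

    Parameters
    ----------
    a : array-like of float in [0, 1]
        Sigmoid activations.

    Returns
    -------
    response : ndarray of int
        1 (S2) where ``a >= 0.5``, else 0 (S1).
    confidence : ndarray of float in [0.5, 1]
        ``a`` for S2 responses, ``1 - a`` for S1 responses.
    """
    a = np.asarray(a, dtype=float)
    if a.size and (np.isnan(a).any() or a.min() < 0 or a.max() > 1):
        raise ValueError("activations must lie in [0, 1]")
    response = (a >= 0.5).astype(int)
    confidence = np.where(response == 1, a, 1.0 - a)
    return response, confidence


def trial_table(net, samples, instance_id=0, condition="") -> pd.DataFrame:
    """Run one network on a stimulus set and tabulate the trials."""
    X = stimuli.stack_pixels(samples)
    y = stimuli.labels_of(samples)
    z = net.decision_function(X)
    a = net.predict_proba(X)[:, 1]
    r, c = decide_and_score(a)
    return pd.DataFrame({
        "instance_id": instance_id,
        "condition": condition,
        "true_label": y,
        "logit": z,
        "activation": a,
        "response": r,
        "confidence": c,
        "correct": (r == y).astype(int),
    })


def summarize_conditions(trials: pd.DataFrame) -> pd.DataFrame:
    """Per instance x condition accuracy and mean confidence."""
    g = trials.groupby(["instance_id", "condition"], sort=False)
    out = g.agg(accuracy=("correct", "mean"),
                mean_confidence=("confidence", "mean"),
                n_trials=("correct", "size")).reset_index()
    return out


def run_energy_experiment(ensemble, experiment: str, conditions=LEVELS,
                          n_per_condition: int = 1000, seed: int = 0):
    """Test every ensemble instance on each energy condition.

    Each condition's stimulus set is generated once and shared across
    instances.  Returns ``(trials, summaries)`` DataFrames.
    """
    frames = []
    for k, level in enumerate(conditions):
        cond = EnergyCondition(experiment, level)
        samples = stimuli.make_test_set(experiment, cond, n=n_per_condition,
                                        seed=seed + k)
        for i, net in enumerate(ensemble):
            frames.append(trial_table(net, samples, instance_id=i,
                                      condition=level))
    trials = pd.concat(frames, ignore_index=True)
    return trials, summarize_conditions(trials)


def rm_anova(summaries: pd.DataFrame, dv: str = "mean_confidence"):
    """One-way repeated-measures ANOVA with condition as the within factor
    and network instances as subjects.

    Returns a dict with F, df_effect = k-1, df_error = (k-1)(n-1), and p.
    Requires a complete, balanced instance x condition design.
    """
    from statsmodels.stats.anova import AnovaRM

    if dv not in summaries.columns:
        raise ValueError(f"unknown dependent variable {dv!r}")
    counts = summaries.groupby("instance_id")["condition"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal conditions per instance")
    res = AnovaRM(summaries, depvar=dv, subject="instance_id",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return {
        "F": float(row["F Value"]),
        "df_effect": float(row["Num DF"]),
        "df_error": float(row["Den DF"]),
        "p": float(row["Pr > F"]),
        # textbook within-subject df (k-1, (k-1)(n-1)) are reported; some
        # published analyses of this design print df_error = n-1 instead
        "df_note": "df_error = (k-1)(n-1)",
    }


def paired_ttest(summaries: pd.DataFrame, condition_pair=("low", "high"),
                 dv: str = "mean_confidence"):
    """Two-sided paired t-test between two conditions across instances."""
    a, b = condition_pair
    pa = summaries[summaries["condition"] == a].sort_values("instance_id")[dv].to_numpy()
    pb = summaries[summaries["condition"] == b].sort_values("instance_id")[dv].to_numpy()
    if len(pa) != len(pb) or len(pa) < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = pb - pa
    if np.allclose(d.std(ddof=1), 0):
        return {"t": 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean()),
                "df": len(d) - 1, "p": np.nan, "mean_diff": float(d.mean()),
                "degenerate": True}
    t, p = stats.ttest_rel(pb, pa)
    return {"t": float(t), "df": len(d) - 1, "p": float(p),
            "mean_diff": float(d.mean()), "degenerate": False}
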