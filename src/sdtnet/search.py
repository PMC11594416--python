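"""Accuracy-matching parameter search.

For each energy level the contrast-like parameter is fixed and the
variability-like parameter is tuned so that observed accuracy hits a
target (default 70%): a coarse scan in large steps brackets the region
whose accuracy falls in an acceptance band (default 65-75%), then
bisection refines the value until the accuracy is within tolerance of the
target.  Accuracy is assumed monotone decreasing in the variability
parameter over the interval; the coarse stage checks this empirically and
aborts with the trace if it fails badly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import stimuli
from .evidence import _AXIS_PARAMS

__all__ = ["SearchSpec", "match_accuracy", "ensemble_accuracy_fn"]


@dataclass
class SearchSpec:
    experiment: str
    contrasts: tuple                      # fixed contrast per level
    variability_interval: tuple           # (lo, hi) search range
    target: float = 0.70
    band: tuple = (0.65, 0.75)
    tolerance: float = 0.01
    coarse_steps: int = 8
    n_eval: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.band[0] <= self.target <= self.band[1]:
            raise ValueError("target must lie inside the coarse band")


@dataclass
class SearchResult:
    variability: list
    accuracy: list
    trace: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def ensemble_accuracy_fn(ensemble, experiment: str):
    """Build an accuracy evaluator from a trained ensemble: mean accuracy
    over instances on a fresh stimulus set at (contrast, variability)."""
    cparam = _AXIS_PARAMS[experiment]["contrast"]
    vparam = _AXIS_PARAMS[experiment]["variability"]

    def accuracy(contrast: float, variability: float, seed: int) -> float:
        cparams = {cparam: contrast, vparam: variability}
        samples = stimuli.make_test_set(experiment, cparams, n=1000, seed=seed)
        X = stimuli.stack_pixels(samples)
        y = stimuli.labels_of(samples)
        return float(np.mean([net.score(X, y) for net in ensemble]))

    return accuracy


def match_accuracy(accuracy_fn, spec: SearchSpec) -> SearchResult:
    """Find, per level, the variability value whose accuracy matches the
    target.

    ``accuracy_fn(contrast, variability, seed) -> fraction`` is typically
    :func:`ensemble_accuracy_fn` but any observer model works (the unit
    tests use a closed-form ideal observer).  Fresh evaluation seeds are
    used per probe so the search does not overfit one stimulus sample.
    """
    lo, hi = spec.variability_interval
    results = SearchResult([], [])
    probe_counter = [0]

    def probe(contrast, v):
        probe_counter[0] += 1
        acc = accuracy_fn(contrast, v, spec.seed + probe_counter[0])
        results.trace.append({"contrast": contrast, "variability": v,
                              "accuracy": acc})
        return acc

    for contrast in spec.contrasts:
        grid = np.linspace(lo, hi, spec.coarse_steps)
        accs = [probe(contrast, v) for v in grid]
        # degenerate: flat accuracy everywhere (e.g. zero-signal stimuli)
        if np.ptp(accs) < 1e-3:
            msg = (f"accuracy flat ({np.mean(accs):.3f}) over the interval at "
                   f"contrast {contrast}; returning the midpoint")
            warnings.warn(msg)
            results.warnings.append(msg)
            results.variability.append(float((lo + hi) / 2))
            results.accuracy.append(float(np.mean(accs)))
            continue
        # monotone-decreasing check (allow small sampling jitter)
        increases = np.diff(accs)
        if np.any(increases > 0.05):
            raise RuntimeError(
                "accuracy is not monotone decreasing in the variability "
                f"parameter at contrast {contrast}: {list(zip(grid, accs))}"
            )
        # bracket the target inside the acceptance band
        idx = [i for i, a in enumerate(accs) if spec.band[0] <= a <= spec.band[1]]
        if idx:
            i0 = min(idx[0], len(grid) - 2) if accs[idx[0]] < spec.target else idx[0]
        else:
            i0 = None
        # find adjacent grid points straddling the target
        bracket = None
        for i in range(len(grid) - 1):
            if accs[i] >= spec.target >= accs[i + 1]:
                bracket = (grid[i], grid[i + 1], accs[i], accs[i + 1])
                break
        if bracket is None:
            # target unreachable on this interval: report boundary value
            j = int(np.argmin(np.abs(np.array(accs) - spec.target)))
            msg = (f"target {spec.target} unreachable at contrast {contrast}; "
                   f"boundary value {grid[j]} (accuracy {accs[j]:.3f})")
            results.warnings.append(msg)
            results.variability.append(float(grid[j]))
            results.accuracy.append(float(accs[j]))
            continue
        a, b = bracket[0], bracket[1]
        acc_mid = None
        for _ in range(20):
            mid = (a + b) / 2.0
            acc_mid = probe(contrast, mid)
            if abs(acc_mid - spec.target) <= spec.tolerance:
                break
            if acc_mid > spec.target:
                a = mid
            else:
                b = mid
        results.variability.append(float((a + b) / 2.0 if acc_mid is None else mid))
        results.accuracy.append(float(acc_mid))
    return results
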