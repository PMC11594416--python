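"""Signal detection measures: d', criterion, meta-d', and calibration.

Type-1 sensitivity follows the classical equal-variance model,

    d' = Phi^-1(HR) - Phi^-1(FAR),     c = -(Phi^-1(HR) + Phi^-1(FAR)) / 2,

with S2 treated as the target class.  Type-2 (metacognitive) sensitivity,
meta-d', is the d' an ideal equal-variance SDT observer would need in order
to produce the observed confidence-rating data, estimated by maximum
likelihood of the response-conditional rating counts (Maniscalco & Lau
style).  The type-1 criterion of the meta-observer is tied to the observed
one by the usual convention meta_c = c * (meta_d' / d'), and the type-2
criteria are free parameters fitted jointly with meta-d'.  Response-specific
meta-d' restricts the likelihood to trials with one response.

`TemperatureScaler` implements post-hoc confidence calibration: logits are
divided by a scalar T fitted by minimizing binary cross-entropy on held-out
trials; scaling never changes any decision (z/T has the sign of z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

__all__ = ["SDTCounts", "SDTMeasures", "dprime", "bin_confidence",
           "counts_from_trials", "fit_meta_d", "TemperatureScaler",
           "fit_temperature", "CalibrationFit"]

_norm = stats.norm


def dprime(hit_rate: float, false_alarm_rate: float):
    """Equal-variance d' and criterion c from hit and false-alarm rates.

    Rates must lie strictly inside (0, 1); apply a cell correction first
    (see :func:`counts_from_trials`, which loglinear-corrects counts).
    """
    hr, far = float(hit_rate), float(false_alarm_rate)
    for name, v in (("hit_rate", hr), ("false_alarm_rate", far)):
        if not 0.0 < v < 1.0:
            raise ValueError(
                f"{name}={v} is outside (0,1); apply the cell correction "
                "to degenerate counts before computing d'"
            )
    zh, zf = _norm.ppf(hr), _norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def bin_confidence(confidence, k: int = 4):
    """Quantile-bin continuous confidence into ratings 1..k.

    Bin edges are the pooled quantiles of ``confidence``; ties collapse
    duplicate edges, so heavily clustered confidence can produce fewer
    occupied ratings (a warning is emitted in the fully degenerate case).

    Returns ``(ratings, edges)`` with ratings monotone in confidence.
    """
    c = np.asarray(confidence, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 rating levels")
    if c.size == 0:
        return np.zeros(0, int), np.zeros(0)
    edges = np.quantile(c, np.linspace(0, 1, k + 1)[1:-1])
    if np.all(c == c.flat[0]):
        warnings.warn("all confidence values identical; single rating bin")
    ratings = np.searchsorted(edges, c, side="left") + 1
    return ratings, edges


@dataclass
class SDTCounts:
    """Trial counts by (rating 1..K, response, stimulus); response/stimulus
    indices are 0 = S1, 1 = S2."""

    counts: np.ndarray  # (K, 2, 2)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3 or self.counts.shape[1:] != (2, 2):
            raise ValueError("counts must have shape (K, 2, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def corrected(self) -> "SDTCounts":
        """Log-linear cell correction: add 1/(4K) (one pseudo-trial spread
        over all 4K cells), making every rate strictly interior."""
        return SDTCounts(self.counts + 1.0 / (4.0 * self.k))

    def type1_rates(self):
        """(HR, FAR) with S2 as target."""
        resp_by_stim = self.counts.sum(axis=0)  # (resp, stim)
        n_s1, n_s2 = resp_by_stim[:, 0].sum(), resp_by_stim[:, 1].sum()
        return resp_by_stim[1, 1] / n_s2, resp_by_stim[1, 0] / n_s1


def counts_from_trials(stimulus, response, rating, k: int) -> SDTCounts:
    """Tabulate per-trial (stimulus, response, rating) into an SDTCounts."""
    stimulus = np.asarray(stimulus, int)
    response = np.asarray(response, int)
    rating = np.asarray(rating, int)
    counts = np.zeros((k, 2, 2))
    np.add.at(counts, (np.clip(rating, 1, k) - 1, response, stimulus), 1.0)
    return SDTCounts(counts)


@dataclass
class SDTMeasures:
    d_prime: float
    criterion_c: float
    meta_d: Optional[float] = None
    meta_d_s1: Optional[float] = None
    meta_d_s2: Optional[float] = None
    fit_loglik: Optional[float] = None
    details: dict = field(default_factory=dict)


def _type2_probs(meta_d: float, meta_c: float, t2c_s1: np.ndarray,
                 t2c_s2: np.ndarray):
    """Joint P(response, rating | stimulus) under the equal-variance meta
    model.  Stimulus means are -meta_d/2 (S1) and +meta_d/2 (S2).

    Returns (p_s1resp, p_s2resp), each (K, 2): columns = stimulus S1, S2.
    ``t2c_s1`` ascending, all < meta_c; ``t2c_s2`` ascending, all > meta_c.
    Rating regions: S1 responses count confidence outward to the left of
    meta_c, S2 responses outward to the right.
    """
    k = len(t2c_s1) + 1
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    # boundaries from -inf up to meta_c for S1 responses
    b_s1 = np.concatenate([[-np.inf], t2c_s1, [meta_c]])
    # boundaries from meta_c to +inf for S2 responses
    b_s2 = np.concatenate([[meta_c], t2c_s2, [np.inf]])
    p_s1 = np.empty((k, 2))
    p_s2 = np.empty((k, 2))
    for j, mu in enumerate(mus):
        cdf1 = _norm.cdf(b_s1 - mu)
        cdf2 = _norm.cdf(b_s2 - mu)
        seg1 = np.diff(cdf1)          # region i: (b_i, b_i+1), i = 0 leftmost
        seg2 = np.diff(cdf2)
        # leftmost S1 region has highest confidence -> rating K..1
        p_s1[:, j] = seg1[::-1]
        p_s2[:, j] = seg2
    return p_s1, p_s2


def _pack(meta_d: float, incr_s1: np.ndarray, incr_s2: np.ndarray,
          cprime: float):
    meta_c = cprime * meta_d
    t2c_s1 = meta_c - np.cumsum(np.exp(incr_s1))[::-1]
    t2c_s2 = meta_c + np.cumsum(np.exp(incr_s2))
    return meta_c, t2c_s1, t2c_s2


def _neg_loglik(theta: np.ndarray, counts: np.ndarray, cprime: float,
                which: Optional[int]) -> float:
    k = counts.shape[0]
    meta_d = theta[0]
    meta_c, t2c_s1, t2c_s2 = _pack(meta_d, theta[1:k], theta[k:2 * k - 1], cprime)
    p_s1, p_s2 = _type2_probs(meta_d, meta_c, t2c_s1, t2c_s2)
    eps = 1e-12
    ll = 0.0
    # response-conditional likelihood: P(rating | response, stimulus)
    if which in (None, 0):
        denom = p_s1.sum(axis=0)
        ll += float(np.sum(counts[:, 0, :] * np.log(np.maximum(p_s1 / np.maximum(denom, eps), eps))))
    if which in (None, 1):
        denom = p_s2.sum(axis=0)
        ll += float(np.sum(counts[:, 1, :] * np.log(np.maximum(p_s2 / np.maximum(denom, eps), eps))))
    return -ll


def _fit_one(counts: np.ndarray, cprime: float, d_obs: float,
             which: Optional[int]):
    k = counts.shape[0]
    x0 = np.concatenate([[d_obs], np.full(2 * (k - 1), np.log(0.5))])
    bounds = [(-10.0, 10.0)] + [(-7.0, 3.0)] * (2 * (k - 1))
    res = optimize.minimize(_neg_loglik, x0, args=(counts, cprime, which),
                            method="L-BFGS-B", bounds=bounds)
    if not res.success and not np.isfinite(res.fun):
        return None, None
    return float(res.x[0]), -float(res.fun)


def fit_meta_d(counts: SDTCounts, response_specific: bool = False) -> SDTMeasures:
    """Maximum-likelihood meta-d' from a confidence-rating count table.

    The observed type-1 d' and criterion c are computed from the corrected
    counts; the meta-observer's type-1 criterion is constrained to
    ``meta_c = c * meta_d / d'`` and its K-1 type-2 criteria per response
    side are fitted jointly with meta-d' by maximizing the multinomial
    likelihood of the rating counts conditional on response.  With
    ``response_specific`` the S1-response and S2-response data are fitted
    separately in addition to the overall fit.
    """
    cc = counts.corrected()
    hr, far = cc.type1_rates()
    d_obs, c_obs = dprime(hr, far)
    cprime = c_obs / d_obs if abs(d_obs) > 1e-8 else 0.0
    meta_d, ll = _fit_one(cc.counts, cprime, d_obs, None)
    out = SDTMeasures(d_prime=d_obs, criterion_c=c_obs, meta_d=meta_d,
                      fit_loglik=ll,
                      details={"hr": hr, "far": far,
                               "correction": "loglinear 1/(4K)"})
    if response_specific:
        for which, attr in ((0, "meta_d_s1"), (1, "meta_d_s2")):
            n_resp = counts.counts[:, which, :].sum()
            if n_resp == 0:
                setattr(out, attr, None)
                continue
            md, _ = _fit_one(cc.counts, cprime, d_obs, which)
            setattr(out, attr, md)
    return out


@dataclass
class CalibrationFit:
    temperature: float
    pre_mean_confidence: float
    post_mean_confidence: float
    pre_gap: float   # mean confidence - accuracy
    post_gap: float


class TemperatureScaler:
    """Post-hoc confidence calibration by logit temperature scaling.

    ``fit(z, y)`` finds T > 0 minimizing the binary cross-entropy of
    ``sigmoid(z / T)`` against labels on held-out trials;
    ``transform(z)`` returns the rescaled activations.  Decisions are
    invariant: sign(z/T) = sign(z).
    """

    def __init__(self):
        pass

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError("TemperatureScaler has no parameters")
        return self

    def fit(self, z, y):
        z = np.asarray(z, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("temperature fitting needs both classes present")

        def nll(log_t):
            a = 1.0 / (1.0 + np.exp(-np.clip(z / np.exp(log_t), -500, 500)))
            a = np.clip(a, 1e-12, 1 - 1e-12)
            return -np.mean(y * np.log(a) + (1 - y) * np.log(1 - a))

        res = optimize.minimize_scalar(nll, bounds=(-6.0, 6.0), method="bounded")
        self.temperature_ = float(np.exp(res.x))
        return self

    def transform(self, z) -> np.ndarray:
        """Rescaled sigmoid activations a = sigmoid(z / T)."""
        self._check_fitted()
        z = np.asarray(z, dtype=float)
        return 1.0 / (1.0 + np.exp(-z / self.temperature_))

    def fit_transform(self, z, y):
        return self.fit(z, y).transform(z)

    def _check_fitted(self):
        if not hasattr(self, "temperature_"):
            raise RuntimeError("TemperatureScaler is not fitted")


def fit_temperature(fit_logits, fit_labels, eval_logits, eval_labels) -> CalibrationFit:
    """Fit T on held-out trials and report calibration before/after on an
    evaluation set (disjoint from the fitting set by construction of the
    caller)."""
    from .behavior import decide_and_score

    scaler = TemperatureScaler().fit(fit_logits, fit_labels)
    z = np.asarray(eval_logits, dtype=float)
    y = np.asarray(eval_labels, dtype=int)
    a_pre = 1.0 / (1.0 + np.exp(-z))
    a_post = scaler.transform(z)
    r_pre, c_pre = decide_and_score(a_pre)
    r_post, c_post = decide_and_score(a_post)
    assert (r_pre == r_post).all(), "temperature scaling altered a decision"
    acc = float(np.mean(r_pre == y))
    return CalibrationFit(
        temperature=scaler.temperature_,
        pre_mean_confidence=float(c_pre.mean()),
        post_mean_confidence=float(c_post.mean()),
        pre_gap=float(c_pre.mean() - acc),
        post_gap=float(c_post.mean() - acc),
    )
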