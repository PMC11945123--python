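"""Minimal Tree-structured Parzen Estimator for hyperparameter search.

Sequential model-based optimization: after a handful of random startup
trials, observed losses are split at the gamma quantile into "good" and "bad"
sets; each dimension gets a pair of Parzen mixtures (truncated Gaussians
centred on the observed values, plus a flat prior component), candidates are
drawn from the good mixture and the one maximizing l(x)/g(x) is evaluated
next.  Integer dimensions round samples; log dimensions operate in log space.
All sampled values stay inside their stated closed intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    is_int: bool = False
    log: bool = False

    def _bounds(self):
        return (math.log(self.low), math.log(self.high)) if self.log else (self.low, self.high)

    def sample_prior(self, rng) -> float:
        lo, hi = self._bounds()
        return self.clip(self._from_internal(rng.uniform(lo, hi)))

    def _from_internal(self, x: float) -> float:
        v = math.exp(x) if self.log else x
        return round(v) if self.is_int else v

    def _to_internal(self, v: float) -> float:
        return math.log(v) if self.log else float(v)

    def clip(self, v):
        v = min(max(v, self.low), self.high)
        return int(round(v)) if self.is_int else float(v)


@dataclass
class Trial:
    number: int
    params: dict
    loss: float


class TPESampler:
    """Suggest/observe interface over a list of :class:`Dimension`."""

    def __init__(self, dimensions: list[Dimension], seed: int = 0,
                 n_startup: int = 5, gamma: float = 0.25, n_candidates: int = 24):
        self.dimensions = dimensions
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[Trial] = []

    def suggest(self) -> dict:
        finite = [t for t in self.trials if math.isfinite(t.loss)]
        if len(finite) < self.n_startup:
            return {d.name: d.sample_prior(self.rng) for d in self.dimensions}
        losses = np.array([t.loss for t in finite])
        n_good = max(1, math.ceil(self.gamma * len(finite)))
        order = np.argsort(losses, kind="stable")
        good = [finite[i] for i in order[:n_good]]
        bad = [finite[i] for i in order[n_good:]] or good
        params = {}
        for d in self.dimensions:
            good_v = np.array([d._to_internal(t.params[d.name]) for t in good])
            bad_v = np.array([d._to_internal(t.params[d.name]) for t in bad])
            lo, hi = d._bounds()
            cands = self._sample_mixture(good_v, lo, hi)
            score = (self._log_pdf(cands, good_v, lo, hi)
                     - self._log_pdf(cands, bad_v, lo, hi))
            params[d.name] = d.clip(d._from_internal(float(cands[int(np.argmax(score))])))
        return params

    def observe(self, params: dict, loss: float) -> None:
        self.trials.append(Trial(number=len(self.trials), params=dict(params), loss=loss))

    # -- Parzen machinery ---------------------------------------------------
    def _bandwidth(self, values, lo, hi):
        spread = (hi - lo) / max(math.sqrt(len(values)), 1.0)
        return max(spread, 1e-3 * (hi - lo), 1e-12)

    def _sample_mixture(self, values, lo, hi):
        bw = self._bandwidth(values, lo, hi)
        centers = self.rng.choice(values, size=self.n_candidates)
        draws = self.rng.normal(centers, bw)
        # one candidate from the flat prior keeps exploration alive
        draws[0] = self.rng.uniform(lo, hi)
        return np.clip(draws, lo, hi)

    def _log_pdf(self, x, values, lo, hi):
        bw = self._bandwidth(values, lo, hi)
        diffs = (x[:, None] - values[None, :]) / bw
        comp = -0.5 * diffs ** 2 - math.log(bw * math.sqrt(2 * math.pi))
        # mixture of kernels plus a uniform-prior component
        kernel = np.logaddexp.reduce(comp, axis=1) - math.log(len(values))
        prior = -math.log(hi - lo)
        return np.logaddexp(kernel + math.log(0.75), prior + math.log(0.25))


def minimize(objective, dimensions: list[Dimension], max_evals: int,
             seed: int = 0) -> tuple[dict, list[Trial]]:
    """Run TPE for at most ``max_evals`` trials; crashed trials score +inf.

    Returns the best parameter dict and the full trial log.
    """
    sampler = TPESampler(dimensions, seed=seed)
    for _ in range(max_evals):
        params = sampler.suggest()
        try:
            loss = float(objective(params))
        except Exception:  # noqa: BLE001 - a failed trial must not stop the search
            loss = float("inf")
        sampler.observe(params, loss)
    best = min(sampler.trials, key=lambda t: (t.loss, t.number))
    return best.params, sampler.trials
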