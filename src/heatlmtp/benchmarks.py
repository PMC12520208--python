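"""A small discrete single-period instance with exactly computable truth.

Binary baseline covariate W, exposure A in {0, 1, 2} with known
conditional pmf g(a | w), deterministic shift policy d(a) = min(a + 1, 2),
and a linear outcome mean m(w, a).  Because everything is discrete and
known, the counterfactual mean E[m(W, d(A))] and the per-period density
ratios g^d(a | w) / g(a | w) have closed forms, making this instance an
exhaustive g-computation oracle for the TMLE machinery and for
double-robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import ExposurePanel, ShiftPolicy
from .ratios import DensityRatioPanel


@dataclass
class DiscreteInstance:
    """One-period discrete data-generating process with known truth."""

    p_w: float = 0.5
    #: g[a | w]: rows indexed by w in {0, 1}, columns by a in {0, 1, 2}
    pmf: np.ndarray = field(
        default_factory=lambda: np.array([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])
    )
    #: outcome mean m(w, a) = b0 + bw * w + ba * a, noise sd on top
    b0: float = 0.35
    bw: float = 0.10
    ba: float = -0.08
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.shape != (2, 3) or np.any(self.pmf < 0):
            raise ValueError("pmf must be a nonnegative 2 x 3 table")
        if not np.allclose(self.pmf.sum(axis=1), 1.0):
            raise ValueError("each conditional pmf must sum to 1")

    def shift(self, a: np.ndarray) -> np.ndarray:
        """The policy d(a) = min(a + 1, 2)."""
        return np.minimum(a + 1, 2)

    def outcome_mean(self, w: np.ndarray, a: np.ndarray) -> np.ndarray:
        return self.b0 + self.bw * w + self.ba * a

    def true_shift_mean(self) -> float:
        """Exhaustive g-computation: E over (W, A) of m(W, d(A))."""
        total = 0.0
        for w in (0, 1):
            pw = self.p_w if w == 1 else 1.0 - self.p_w
            for a in (0, 1, 2):
                total += pw * self.pmf[w, a] * float(
                    self.outcome_mean(np.array(w), self.shift(np.array(a)))
                )
        return total

    def true_natural_mean(self) -> float:
        total = 0.0
        for w in (0, 1):
            pw = self.p_w if w == 1 else 1.0 - self.p_w
            for a in (0, 1, 2):
                total += pw * self.pmf[w, a] * float(
                    self.outcome_mean(np.array(w), np.array(a))
                )
        return total

    def true_ratio(self, w: np.ndarray, a: np.ndarray) -> np.ndarray:
        """Analytic density ratio g^d(a | w) / g(a | w) at observed (w, a).

        The pmf of d(A) puts mass g(0 | w) on a = 1 and
        g(1 | w) + g(2 | w) on a = 2, and none on a = 0.
        """
        shifted_pmf = np.zeros((2, 3))
        shifted_pmf[:, 1] = self.pmf[:, 0]
        shifted_pmf[:, 2] = self.pmf[:, 1] + self.pmf[:, 2]
        return shifted_pmf[w, a] / self.pmf[w, a]

    def sample(self, n: int, seed: int = 0):
        """Draw a dataset and package it for the TMLE interface.

        Returns ``(outcome, factual_panel, counterfactual_panel,
        true_ratio_panel, covariates)`` with one exposure period.
        """
        rng = np.random.default_rng(seed)
        w = rng.binomial(1, self.p_w, size=n)
        u = rng.random(n)
        cum = np.cumsum(self.pmf, axis=1)
        a = (u[:, np.newaxis] > cum[w, :2]).sum(axis=1)
        y = np.clip(
            self.outcome_mean(w, a) + rng.normal(0.0, self.noise_sd, size=n),
            0.0,
            1.0,
        )
        a_shift = self.shift(a)
        ids = np.arange(1, n + 1)
        policy = ShiftPolicy(k=1.0, threshold_value=0.0)
        zeros = np.zeros((n, 1), dtype=int)
        factual = ExposurePanel(
            child_ids=ids, counts=a[:, np.newaxis], cold_counts=zeros,
            policy=ShiftPolicy(k=0.0, threshold_value=0.0), provenance="factual",
        )
        counterfactual = ExposurePanel(
            child_ids=ids, counts=a_shift[:, np.newaxis], cold_counts=zeros,
            policy=policy, provenance="counterfactual",
        )
        ratio_panel = DensityRatioPanel(
            ratios=self.true_ratio(w, a)[:, np.newaxis]
        )
        covariates = pd.DataFrame({"w": w.astype(float)})
        return y, factual, counterfactual, ratio_panel, covariates
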