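"""Cross-world counterfactual mediator simulation under the sensitivity
parameter rho.

The joint law of the first mediator's two counterfactuals (M1(0), M1(1))
given confounders is not identified from data: within one world each
marginal is Gaussian around the fitted conditional mean with residual
variance sigma1^2, but the data say nothing about how the two worlds'
residuals co-vary.  We parameterize this with rho in [0, 1], the proportion
of residual variance shared across worlds, via the shared-component
construction ::

    eps(x) = sqrt(rho) * U + sqrt(1 - rho) * V_x,      x = 0, 1

with U, V_0, V_1 independent N(0, sigma1^2).  Each marginal is N(0, sigma1^2)
for every rho, and Corr(eps(0), eps(1)) = rho, so the shared-variance
proportion and the cross-world residual correlation coincide.  rho = 1 gives
perfect cross-world correlation (eps(0) = eps(1) exactly), rho = 0
independence.

The second mediator needs no cross-world coupling: within any single nested
counterfactual Y(a0, M1(a1), M2(a2, M1(a3))) only one M2 world appears, so
contrasts across worlds can use independent M2 residual draws without
changing any expectation.

The standard-normal variates (U, V_0, V_1, the four M2 draws, and optionally
a Y residual) are drawn once per pseudo-subject, independent of rho, so a
grid of rho values reuses common random numbers: sensitivity curves are
smooth and rho-free effects are near-exactly invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .models import FittedLinearModel


@dataclass(frozen=True)
class SensitivityConfig:
    """Monte-Carlo settings: cross-world rho, master seed, expansion factor K."""

    rho: float = 1.0
    seed: int = 0
    K: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")


@dataclass
class CrossworldNoise:
    """Pre-allocated standard-normal streams for one expanded dataset.

    ``u``, ``v0``, ``v1`` drive the cross-world M1 residuals; ``z2`` holds
    one stream per (a2, a1-world) M2 draw; ``zy`` is the optional Y residual
    stream.  Drawn once, reused across every rho of a sensitivity grid.
    """

    u: np.ndarray
    v0: np.ndarray
    v1: np.ndarray
    z2: dict[tuple[int, int], np.ndarray]
    zy: np.ndarray | None = None

    @classmethod
    def draw(cls, n_rows: int, rng: np.random.Generator, y_draw: bool = False) -> "CrossworldNoise":
        return cls(
            u=rng.standard_normal(n_rows),
            v0=rng.standard_normal(n_rows),
            v1=rng.standard_normal(n_rows),
            z2={
                (a2, a1w): rng.standard_normal(n_rows)
                for a2 in (0, 1)
                for a1w in (0, 1)
            },
            zy=rng.standard_normal(n_rows) if y_draw else None,
        )


def crossworld_residuals(
    noise: CrossworldNoise, rho: float, sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """The coupled residual pair (eps(0), eps(1)) at a given rho."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    shared = np.sqrt(rho) * noise.u
    eps0 = sigma * (shared + np.sqrt(1.0 - rho) * noise.v0)
    eps1 = sigma * (shared + np.sqrt(1.0 - rho) * noise.v1)
    return eps0, eps1


def draw_crossworld_m1(
    model: FittedLinearModel,
    data: Mapping[str, np.ndarray],
    rho: float,
    noise: CrossworldNoise,
    exposure: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint draws of (M1(0), M1(1)) for every pseudo-subject.

    ``data`` carries the (expanded) confounder columns; the exposure column
    is overridden to 0 and 1 for the two worlds.  The same coupled residual
    pair is added to both conditional means, so the worlds differ only
    through the mean function when rho = 1.
    """
    if model.role != "m1":
        raise ValueError(f"expected a model with role 'm1', got {model.role!r}")
    n = len(noise.u)
    eps0, eps1 = crossworld_residuals(noise, rho, model.sigma)
    zeros = {**data, exposure: np.zeros(n)}
    ones = {**data, exposure: np.ones(n)}
    m1_0 = model.predict_mean(zeros, n=n) + eps0
    m1_1 = model.predict_mean(ones, n=n) + eps1
    return m1_0, m1_1


def draw_m2_counterfactuals(
    model: FittedLinearModel,
    data: Mapping[str, np.ndarray],
    x_m2: int,
    m1_value: np.ndarray,
    z: np.ndarray,
    exposure: str,
    m1_col: str,
) -> np.ndarray:
    """A draw of M2(x_m2, m1_value) per pseudo-subject.

    Single-world: conditional mean of the M2 model at exposure ``x_m2`` and
    the supplied M1 values, plus sigma2 times the pre-allocated standard
    normals ``z``.
    """
    if model.role != "m2":
        raise ValueError(f"expected a model with role 'm2', got {model.role!r}")
    n = len(m1_value)
    cf = {**data, exposure: np.full(n, float(x_m2)), m1_col: m1_value}
    return model.predict_mean(cf, n=n) + model.sigma * z
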