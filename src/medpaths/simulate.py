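"""Synthetic data from a known linear structural equation model (SEM).

The generator plays the role the analysis dataset would play in an applied
study of a binary exposure, two causally ordered continuous mediators and a
continuous outcome -- e.g. heavy drinking acting on systolic blood pressure
through (log) BMI and (log) GGT -- but with every structural coefficient and
the cross-world residual correlation known.  It provides:

* observed datasets (the estimator's input),
* the full table of potential outcomes Y(a0, M1(a1), M2(a2, M1(a3))) for all
  16 index combinations, with cross-world M1 residuals coupled at a known
  ``rho_true``, and
* a population-level "truth oracle": every path-specific estimand evaluated
  as a sample mean of potential-outcome contrasts at large n.

Structural equations (C = (c_num, c_cat) baseline confounders):

    M1 = b0 + bx*X + b_c'C + e1,                     e1 ~ N(0, s1^2)
    M2 = g0 + gx*X + gm*M1 + gxm*X*M1 + g_c'C + e2,  e2 ~ N(0, s2^2)
    Y  = t0 + tx*X + t1*M1 + t2*M2 + tx1*X*M1 + tx2*X*M2
         + t12*M1*M2 + tx12*X*M1*M2 + t_c'C + eY,    eY ~ N(0, sY^2)

The cross-world pair (e1(0), e1(1)) uses the same shared-component
construction as the estimator; e2 is drawn independently per (a2, a1-world)
pair, and eY is shared across all 16 indices of one subject (it cancels in
every contrast).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import algebra
from .models import Dataset

#: Levels of the categorical confounder (smoking-status-like).
CAT_LEVELS: tuple[str, ...] = ("current", "ex", "never")


@dataclass(frozen=True)
class TrueSEMParams:
    """Structural coefficients of the generating SEM.

    Defaults are the "izhevsk-like" fixture: a heavy-drinking-style exposure
    with prevalence 0.25, a log-BMI-like first mediator, a log-GGT-like
    second mediator, and an SBP-like outcome in mmHg, with weak
    exposure--mediator interactions and ``rho_true`` = 0.5.  Illustrative of
    that study's structure, not a reproduction of it.
    """

    p_x: float = 0.25
    # confounders: one standardized continuous (age-like), one categorical
    cat_probs: tuple[float, ...] = (0.5, 0.25, 0.25)
    # M1 (log-BMI-like)
    m1_intercept: float = 3.2
    m1_x: float = 0.03
    m1_cnum: float = 0.02
    m1_cat: tuple[float, ...] = (0.0, -0.01, 0.02)  # per CAT_LEVELS
    sigma1: float = 0.15
    # M2 (log-GGT-like)
    m2_intercept: float = 1.5
    m2_x: float = 0.40
    m2_m1: float = 0.45
    m2_x_m1: float = 0.10
    m2_cnum: float = 0.05
    m2_cat: tuple[float, ...] = (0.0, -0.02, -0.05)
    sigma2: float = 0.50
    # Y (SBP-like, mmHg)
    y_intercept: float = 95.0
    y_x: float = 4.0
    y_m1: float = 6.0
    y_m2: float = 3.0
    y_x_m1: float = 1.0
    y_x_m2: float = 0.5
    y_m1_m2: float = 0.3
    y_x_m1_m2: float = 0.1
    y_cnum: float = 2.0
    y_cat: tuple[float, ...] = (0.0, -1.0, -2.0)
    sigma_y: float = 16.0
    rho_true: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_x < 1.0:
            raise ValueError(f"p_x must be in (0, 1), got {self.p_x}")
        if not 0.0 <= self.rho_true <= 1.0:
            raise ValueError(f"rho_true must be in [0, 1], got {self.rho_true}")
        for s in (self.sigma1, self.sigma2, self.sigma_y):
            if s < 0:
                raise ValueError("error SDs must be >= 0")

    @classmethod
    def product_of_coefficients(
        cls,
        direct: float = 1.0,
        x_to_m1: float = 0.5,
        m1_to_m2: float = 0.4,
        x_to_m2: float = 0.3,
        m1_to_y: float = 0.6,
        m2_to_y: float = 0.7,
        sigma1: float = 1.0,
        sigma2: float = 1.0,
        sigma_y: float = 1.0,
        rho_true: float = 0.5,
    ) -> "TrueSEMParams":
        """An interaction-free SEM whose path effects are coefficient products:
        NDE = direct, NIE1 = x_to_m1 * m1_to_y, NIE2 = x_to_m2 * m2_to_y,
        NIE12 = x_to_m1 * m1_to_m2 * m2_to_y, identical for every type."""
        return cls(
            p_x=0.5,
            m1_intercept=0.0, m1_x=x_to_m1, m1_cnum=0.0, m1_cat=(0.0, 0.0, 0.0),
            sigma1=sigma1,
            m2_intercept=0.0, m2_x=x_to_m2, m2_m1=m1_to_m2, m2_x_m1=0.0,
            m2_cnum=0.0, m2_cat=(0.0, 0.0, 0.0), sigma2=sigma2,
            y_intercept=0.0, y_x=direct, y_m1=m1_to_y, y_m2=m2_to_y,
            y_x_m1=0.0, y_x_m2=0.0, y_m1_m2=0.0, y_x_m1_m2=0.0,
            y_cnum=0.0, y_cat=(0.0, 0.0, 0.0), sigma_y=sigma_y,
            rho_true=rho_true,
        )


def _cat_effect(codes: np.ndarray, effects: tuple[float, ...]) -> np.ndarray:
    return np.asarray(effects, dtype=float)[codes]


def _mean_m1(p: TrueSEMParams, x, cnum, ccode):
    return p.m1_intercept + p.m1_x * x + p.m1_cnum * cnum + _cat_effect(ccode, p.m1_cat)


def _mean_m2(p: TrueSEMParams, x, m1, cnum, ccode):
    return (
        p.m2_intercept + p.m2_x * x + p.m2_m1 * m1 + p.m2_x_m1 * x * m1
        + p.m2_cnum * cnum + _cat_effect(ccode, p.m2_cat)
    )


def _mean_y(p: TrueSEMParams, x, m1, m2, cnum, ccode):
    return (
        p.y_intercept + p.y_x * x + p.y_m1 * m1 + p.y_m2 * m2
        + p.y_x_m1 * x * m1 + p.y_x_m2 * x * m2 + p.y_m1_m2 * m1 * m2
        + p.y_x_m1_m2 * x * m1 * m2
        + p.y_cnum * cnum + _cat_effect(ccode, p.y_cat)
    )


def _draw_baseline(p: TrueSEMParams, n: int, rng: np.random.Generator):
    cnum = rng.standard_normal(n)
    ccode = rng.choice(len(CAT_LEVELS), size=n, p=p.cat_probs)
    x = (rng.random(n) < p.p_x).astype(float)
    return x, cnum, ccode


def generate_observed(params: TrueSEMParams, n: int, seed: int) -> Dataset:
    """Sample an observed dataset of size ``n`` from the SEM."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    x, cnum, ccode = _draw_baseline(params, n, rng)
    m1 = _mean_m1(params, x, cnum, ccode) + params.sigma1 * rng.standard_normal(n)
    m2 = _mean_m2(params, x, m1, cnum, ccode) + params.sigma2 * rng.standard_normal(n)
    y = _mean_y(params, x, m1, m2, cnum, ccode) + params.sigma_y * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "x": x.astype(int),
            "m1": m1,
            "m2": m2,
            "y": y,
            "c_num": cnum,
            "c_cat": np.asarray(CAT_LEVELS, dtype=object)[ccode],
        }
    )
    return Dataset(
        df=df, exposure="x", m1="m1", m2="m2", outcome="y",
        confounders=("c_num", "c_cat"),
    )


def generate_potential_outcomes(
    params: TrueSEMParams, n: int, seed: int
) -> pd.DataFrame:
    """The full potential-outcome table for ``n`` subjects.

    Columns: baseline (x, c_num, c_cat), counterfactual mediators m1_0, m1_1,
    m2_a2_a1w for (a2, a1-world) in {0,1}^2, the sixteen outcomes
    ``y_a0a1a2a3``, and the factual (m1, m2, y) rows implied by consistency.
    The cross-world M1 residual pair has correlation ``rho_true``; e2 is
    drawn per (a2, a1-world); eY is shared across all 16 indices of a row.
    """
    rng = np.random.default_rng(seed)
    x, cnum, ccode = _draw_baseline(params, n, rng)
    # shared-component cross-world pair at rho_true
    u, v0, v1 = (rng.standard_normal(n) for _ in range(3))
    r = params.rho_true
    eps1_0 = params.sigma1 * (np.sqrt(r) * u + np.sqrt(1.0 - r) * v0)
    eps1_1 = params.sigma1 * (np.sqrt(r) * u + np.sqrt(1.0 - r) * v1)
    m1_w = {
        0: _mean_m1(params, 0.0, cnum, ccode) + eps1_0,
        1: _mean_m1(params, 1.0, cnum, ccode) + eps1_1,
    }
    m2_w = {}
    for a2 in (0, 1):
        for a1w in (0, 1):
            m2_w[(a2, a1w)] = (
                _mean_m2(params, float(a2), m1_w[a1w], cnum, ccode)
                + params.sigma2 * rng.standard_normal(n)
            )
    eps_y = params.sigma_y * rng.standard_normal(n)
    out = {
        "x": x.astype(int),
        "c_num": cnum,
        "c_cat": np.asarray(CAT_LEVELS, dtype=object)[ccode],
        "m1_0": m1_w[0],
        "m1_1": m1_w[1],
    }
    for (a2, a1w), v in m2_w.items():
        out[f"m2_{a2}{a1w}"] = v
    for a0, a1, a2, a3 in itertools.product((0, 1), repeat=4):
        out[f"y_{a0}{a1}{a2}{a3}"] = (
            _mean_y(params, float(a0), m1_w[a1], m2_w[(a2, a3)], cnum, ccode) + eps_y
        )
    df = pd.DataFrame(out)
    # factual rows by consistency: M1 = M1(X), M2 = M2(X, M1(X)), Y = Y(X,...)
    xi = x.astype(int)
    df["m1"] = np.where(xi == 1, df["m1_1"], df["m1_0"])
    df["m2"] = np.choose(xi, [df["m2_00"].to_numpy(), df["m2_11"].to_numpy()])
    y_fact = np.empty(n)
    for val in (0, 1):
        mask = xi == val
        y_fact[mask] = df.loc[mask, f"y_{val}{val}{val}{val}"]
    df["y"] = y_fact
    return df


def true_effects_oracle(
    params: TrueSEMParams, n_large: int = 200_000, seed: int = 2026
) -> dict[str, float]:
    """Population truths for every estimand, by brute-force potential outcomes.

    Evaluates each contrast as a mean over a large simulated potential-outcome
    table: the 32 path-specific effects, TCE, the four summary effects, the
    four weighted variabilities, and both MS families.  Monte-Carlo error
    shrinks as 1/sqrt(n_large).
    """
    po = generate_potential_outcomes(params, n_large, seed)

    def cell(idx):
        return po[f"y_{idx[0]}{idx[1]}{idx[2]}{idx[3]}"].to_numpy()

    truths: dict[str, float] = {}
    truths["TCE"] = float(np.mean(cell((1, 1, 1, 1)) - cell((0, 0, 0, 0))))
    for c in algebra.enumerate_effects():
        truths[c.name] = float(np.mean(cell(c.plus) - cell(c.minus)))
    weights = algebra.summary_weights()
    for path in algebra.PATHS:
        label = algebra.PATH_LABELS[path]
        vals = {
            bits: truths[f"{label}-{algebra.bits_str(bits)}"] for bits in weights
        }
        s = sum(float(w) * vals[b] for b, w in weights.items())
        truths[f"S{label}"] = s
        truths[f"var-{label}"] = sum(
            float(w) * (vals[b] - s) ** 2 for b, w in weights.items()
        )
    for family in ("MS1", "MS2"):
        for c in algebra.enumerate_ms_effects(family):
            truths[c.name] = float(np.mean(cell(c.plus) - cell(c.minus)))
    return truths
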