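"""Linear regression models for the mediators and the outcome.

Three models underpin the g-computation estimator: M1 | X, C; M2 | X, M1, C;
and Y | X, M1, M2, C, all linear with Gaussian errors, optionally including
every two- and three-way exposure--mediator interaction so that the different
types of each path-specific effect can differ as much as the data dictate.
Fits are ordinary least squares via statsmodels on a design matrix built by a
small term evaluator (:class:`DesignBuilder`); the same builder evaluates the
design at counterfactual regressor values, which is the hot path of the
Monte-Carlo estimator.

Terms are strings: a numeric column name, a categorical column name (expanded
to treatment-coded indicators with the alphabetically first level as
reference), ``"a:b"`` products of factors, or ``"a^2"`` quadratics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


class ModelError(ValueError):
    """Raised for invalid model specifications or degenerate designs."""


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A rectangular mediation dataset with declared column roles.

    One row per subject: binary exposure, two continuous mediators with
    ``m1`` causally prior to ``m2``, a continuous outcome, and baseline
    confounders (numeric or categorical).  Mediators may be log-transformed
    on construction; effects are always on the outcome scale.
    """

    df: pd.DataFrame
    exposure: str
    m1: str
    m2: str
    outcome: str
    confounders: tuple[str, ...] = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.confounders = tuple(self.confounders)
        cols = [self.exposure, self.m1, self.m2, self.outcome, *self.confounders]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ModelError(f"columns not in data: {missing}")
        x = self.df[self.exposure]
        bad = sorted(set(x.unique()) - {0, 1})
        if bad:
            raise ModelError(
                f"exposure column {self.exposure!r} must be binary 0/1; "
                f"found value(s) {bad}"
            )
        if self.df[cols].isna().any().any():
            raise ModelError(
                "missing values in analysis columns; use medpaths.io.read_dataset "
                "or Dataset.from_dataframe to drop incomplete rows"
            )
        if x.nunique() < 2:
            raise ModelError(f"exposure column {self.exposure!r} is constant")
        for m in (self.m1, self.m2):
            if np.isclose(float(self.df[m].std()), 0.0):
                raise ModelError(f"mediator column {m!r} has zero variance")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        exposure: str,
        m1: str,
        m2: str,
        outcome: str,
        confounders: Sequence[str] = (),
        log_m1: bool = False,
        log_m2: bool = False,
    ) -> "Dataset":
        """Build a Dataset, dropping incomplete rows (complete-case analysis)."""
        cols = [exposure, m1, m2, outcome, *confounders]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ModelError(f"columns not in data: {missing}")
        sub = df[cols].copy()
        complete = sub.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        sub = sub.loc[complete].reset_index(drop=True)
        for col, flag in ((m1, log_m1), (m2, log_m2)):
            if flag:
                if (sub[col] <= 0).any():
                    raise ModelError(f"cannot log-transform {col!r}: non-positive values")
                sub[col] = np.log(sub[col].astype(float))
        return cls(
            df=sub,
            exposure=exposure,
            m1=m1,
            m2=m2,
            outcome=outcome,
            confounders=tuple(confounders),
            n_dropped=n_dropped,
        )

    @property
    def n(self) -> int:
        return len(self.df)

    def schema(self) -> dict[str, object]:
        """Column typing used by the design builder: numeric, or the sorted
        level tuple for categorical (object/category) columns."""
        out: dict[str, object] = {}
        for col in self.df.columns:
            s = self.df[col]
            if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                out[col] = tuple(sorted(map(str, pd.unique(s.astype(str)))))
            else:
                out[col] = "numeric"
        return out

    def columns_dict(self) -> dict[str, np.ndarray]:
        return {c: self.df[c].to_numpy() for c in self.df.columns}


# ---------------------------------------------------------------------------
# Model specification and design building
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Term list of one regression model (intercept always included)."""

    terms: tuple[str, ...]

    def __init__(self, terms: Sequence[str]):
        object.__setattr__(self, "terms", tuple(terms))

    def variables(self) -> set[str]:
        out: set[str] = set()
        for t in self.terms:
            for f in t.split(":"):
                out.add(f.split("^")[0].strip())
        return out


def default_specs(
    dataset: Dataset, interactions: bool = True
) -> dict[str, ModelSpec]:
    """The three working models.

    With ``interactions=True`` the M2 model includes X:M1 and the Y model all
    two- and three-way exposure--mediator interactions; otherwise all three
    are main-effects-only (the LSEM comparator's specs).
    """
    x, m1, m2 = dataset.exposure, dataset.m1, dataset.m2
    c = list(dataset.confounders)
    spec_m1 = ModelSpec([x, *c])
    if interactions:
        spec_m2 = ModelSpec([x, m1, f"{x}:{m1}", *c])
        spec_y = ModelSpec(
            [x, m1, m2, f"{x}:{m1}", f"{x}:{m2}", f"{m1}:{m2}", f"{x}:{m1}:{m2}", *c]
        )
    else:
        spec_m2 = ModelSpec([x, m1, *c])
        spec_y = ModelSpec([x, m1, m2, *c])
    return {"m1": spec_m1, "m2": spec_m2, "y": spec_y}


class DesignBuilder:
    """Evaluate a term list into a design matrix with named columns.

    Categorical columns expand to indicator columns for every level except
    the alphabetically first (the reference); interactions are elementwise
    products of the expanded factor columns.  The expansion is deterministic
    given the schema, so counterfactual data evaluate to comparable designs.
    """

    def __init__(self, spec: ModelSpec, schema: Mapping[str, object]):
        self.spec = spec
        self.schema = dict(schema)
        for v in spec.variables():
            if v not in self.schema:
                raise ModelError(f"term references unknown column {v!r}")
        self.column_names: list[str] = ["Intercept"]
        self._plan: list[list[tuple[str, int, str | None]]] = [[]]
        for term in spec.terms:
            for cols in self._expand_term(term):
                name = ":".join(n for n, _, _ in cols)
                self.column_names.append(name)
                self._plan.append(cols)

    def _expand_term(self, term: str):
        factor_cols: list[list[tuple[str, int, str | None]]] = []
        for factor in term.split(":"):
            factor = factor.strip()
            if "^" in factor:
                base, pow_ = factor.split("^")
                base, power = base.strip(), int(pow_)
                if self.schema.get(base) == "numeric":
                    factor_cols.append([(f"{base}^{power}", power, base)])
                else:
                    raise ModelError(f"cannot raise non-numeric column {base!r} to a power")
            elif self.schema.get(factor) == "numeric":
                factor_cols.append([(factor, 1, factor)])
            else:
                levels = self.schema[factor]
                factor_cols.append(
                    [(f"{factor}[{lv}]", 1, f"{factor}=={lv}") for lv in levels[1:]]
                )
        # cartesian product over the factors' expanded columns
        out = [[]]
        for cols in factor_cols:
            out = [prev + [c] for prev in out for c in cols]
        return out

    def build(self, data: Mapping[str, np.ndarray], n: int | None = None) -> np.ndarray:
        """Design matrix for ``data`` (a mapping of column name -> array)."""
        if n is None:
            n = len(next(iter(data.values())))
        X = np.empty((n, len(self.column_names)))
        X[:, 0] = 1.0
        for j, cols in enumerate(self._plan[1:], start=1):
            col = np.ones(n)
            for _, power, source in cols:
                if source is None:
                    continue
                if "==" in source:
                    base, lv = source.split("==")
                    if base not in data:
                        raise ModelError(f"missing regressor column {base!r}")
                    col = col * (np.asarray(data[base]).astype(str) == lv)
                else:
                    if source not in data:
                        raise ModelError(f"missing regressor column {source!r}")
                    vals = np.asarray(data[source], dtype=float)
                    col = col * (vals**power if power != 1 else vals)
            X[:, j] = col
        return X


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------

@dataclass
class FittedLinearModel:
    """An OLS fit: named coefficients, residual variance, design builder."""

    role: str
    spec: ModelSpec
    builder: DesignBuilder
    params: pd.Series
    sigma2: float  # residual variance, n - p denominator
    nobs: int

    @property
    def sigma(self) -> float:
        return float(np.sqrt(self.sigma2))

    def predict_mean(self, data: Mapping[str, np.ndarray], n: int | None = None) -> np.ndarray:
        """Linear predictor (conditional mean) at the supplied regressor values."""
        X = self.builder.build(data, n=n)
        return X @ self.params.to_numpy()


_ROLE_FORBIDDEN = {
    "m1": ("m1", "m2", "outcome"),
    "m2": ("m2", "outcome"),
    "y": ("outcome",),
}


def fit_model(dataset: Dataset, spec: ModelSpec, role: str) -> FittedLinearModel:
    """OLS fit of one of the three working models.

    ``role`` is ``"m1"``, ``"m2"`` or ``"y"``; it fixes the response column
    and forbids causally downstream regressors (the M1 model may not contain
    mediators, the M2 model may not contain M2 or Y).  Rank-deficient designs
    raise an error naming the collinear columns; so does n <= p.
    """
    if role not in _ROLE_FORBIDDEN:
        raise ModelError(f"role must be one of {tuple(_ROLE_FORBIDDEN)}, got {role!r}")
    response = {"m1": dataset.m1, "m2": dataset.m2, "y": dataset.outcome}[role]
    forbidden = {getattr(dataset, attr) for attr in _ROLE_FORBIDDEN[role]}
    bad = spec.variables() & forbidden
    if bad:
        raise ModelError(f"role {role!r} model may not include regressors {sorted(bad)}")

    builder = DesignBuilder(spec, dataset.schema())
    X = builder.build(dataset.columns_dict(), n=dataset.n)
    y = dataset.df[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ModelError(f"cannot fit {role!r} model: n={n} <= p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # pivoted QR flags the columns that add no rank
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        collinear = [builder.column_names[j] for j in sorted(piv[rank:])]
        raise ModelError(f"design for {role!r} model is rank-deficient; "
                         f"collinear term(s): {collinear}")
    res = sm.OLS(y, X).fit()
    return FittedLinearModel(
        role=role,
        spec=spec,
        builder=builder,
        params=pd.Series(res.params, index=builder.column_names),
        sigma2=float(res.ssr / res.df_resid),
        nobs=n,
    )


def predict_mean(model: FittedLinearModel, record: Mapping[str, object]) -> float:
    """Conditional mean for a single record (scalar convenience wrapper)."""
    data = {k: np.atleast_1d(np.asarray(v)) for k, v in record.items()}
    return float(model.predict_mean(data, n=1)[0])
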