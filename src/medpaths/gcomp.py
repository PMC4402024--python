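"""Parametric g-computation of natural path-specific effects by Monte Carlo.

The estimator posits linear models for M1 | X, C; M2 | X, M1, C and
Y | X, M1, M2, C, estimates them by OLS on the original sample, and then
simulates every nested counterfactual on a K-fold expanded dataset:

1. copy each subject's confounders K times;
2. per pseudo-subject, draw the cross-world pair (M1(0), M1(1)) jointly,
   coupling residuals through the sensitivity parameter rho;
3. per (a2, a1-world) pair, draw M2(a2, M1(a1));
4. fill the 16-cell table of Y(a0, M1(a1), M2(a2, M1(a3))) with the Y-model
   conditional mean (optionally plus a Y residual draw), sharing the SAME
   mediator draws across all 16 cells of one pseudo-subject;
5. estimate each effect as the mean over pseudo-subjects of the cell
   contrast, and the TCE as mean(cell(1,1,1,1) - cell(0,0,0,0)).

Because all 16 cells share one set of draws, every one of the 24
decompositions sums to the TCE exactly (to floating point), not merely
statistically.  Standard errors come from the nonparametric bootstrap:
subjects are resampled with replacement, all three models refitted, and the
full simulation re-run per replicate.  An interaction-free LSEM
product-of-coefficients comparator is provided; it coincides with the
natural effects when no interactions are present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import algebra
from .crossworld import CrossworldNoise, SensitivityConfig, draw_crossworld_m1, draw_m2_counterfactuals
from .models import Dataset, DesignBuilder, FittedLinearModel, ModelSpec, ModelError, fit_model

ALL_CELLS: tuple[tuple[int, int, int, int], ...] = tuple(
    itertools.product((0, 1), repeat=4)
)


@dataclass(frozen=True)
class EstimationConfig:
    """Settings of a full estimation run.

    ``rho_grid`` is the sensitivity grid (common random numbers are used
    across it); ``K`` the per-subject expansion factor; ``B`` the number of
    bootstrap replicates (0 disables inference); ``ci_method`` is "normal"
    (estimate +/- 1.96 * bootstrap SE) or "percentile"; ``y_draw`` adds a
    residual draw to the Y stage instead of using the conditional mean
    (identical in expectation, higher Monte-Carlo variance); ``reduced``
    drops the M1 -> M2 path (unordered mediators: 12 effects, 6
    decompositions).
    """

    rho_grid: tuple[float, ...] = (1.0, 0.5, 0.0)
    K: int = 200
    B: int = 0
    seed: int = 0
    ci_method: str = "normal"
    y_draw: bool = False
    reduced: bool = False

    def __post_init__(self) -> None:
        if not self.rho_grid:
            raise ValueError("rho_grid must be non-empty")
        for r in self.rho_grid:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rho values must be in [0, 1], got {r}")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.B < 0:
            raise ValueError(f"B must be >= 0, got {self.B}")
        if self.ci_method not in ("normal", "percentile"):
            raise ValueError(f"ci_method must be 'normal' or 'percentile', got {self.ci_method!r}")
        if self.ci_method == "percentile" and 0 < self.B < 40:
            raise ValueError(
                f"percentile CIs need B >= 40 replicates, got B={self.B}"
            )


@dataclass
class CounterfactualTable:
    """Simulated counterfactual outcomes for every pseudo-subject.

    ``cells`` maps a counterfactual index (a0, a1, a2, a3) to the vector of
    simulated outcomes (length n_subjects * K).  Reduced-system tables key
    cells by 3-tuples (a0, a1, a2) instead.
    """

    cells: dict[tuple, np.ndarray]
    n_subjects: int
    K: int
    rho: float
    seed: int
    reduced: bool = False

    @property
    def provenance(self) -> tuple:
        return (self.rho, self.seed, self.K, self.n_subjects, self.reduced)

    def cell_mean(self, idx: tuple) -> float:
        return float(np.mean(self.cells[idx]))


@dataclass
class EffectTable:
    """Point estimates of TCE and path-specific effects from one table."""

    df: pd.DataFrame  # columns: effect, path, type, estimate
    provenance: tuple

    def __getitem__(self, effect: str) -> float:
        vals = self.df.loc[self.df["effect"] == effect, "estimate"]
        if vals.empty:
            raise KeyError(effect)
        return float(vals.iloc[0])

    @property
    def tce(self) -> float:
        return self["TCE"]


# ---------------------------------------------------------------------------
# Fast fitting cache (design matrices built once; bootstrap refits by row
# slicing — preserves the categorical schema even when a resample drops a
# rare level)
# ---------------------------------------------------------------------------

class PipelineCache:
    """Precomputed designs and expanded baseline columns for repeated runs."""

    def __init__(self, dataset: Dataset, specs: Mapping[str, ModelSpec]):
        self.dataset = dataset
        self.specs = dict(specs)
        schema = dataset.schema()
        cols = dataset.columns_dict()
        self.builders = {
            role: DesignBuilder(specs[role], schema) for role in ("m1", "m2", "y")
        }
        self.designs = {
            role: self.builders[role].build(cols, n=dataset.n)
            for role in ("m1", "m2", "y")
        }
        self.responses = {
            "m1": dataset.df[dataset.m1].to_numpy(dtype=float),
            "m2": dataset.df[dataset.m2].to_numpy(dtype=float),
            "y": dataset.df[dataset.outcome].to_numpy(dtype=float),
        }
        # columns the counterfactual predictions need besides X/M1/M2
        needed = set()
        for spec in specs.values():
            needed |= spec.variables()
        needed -= {dataset.exposure, dataset.m1, dataset.m2, dataset.outcome}
        self.baseline_cols = tuple(sorted(needed))
        # full-data fit validates the designs (rank, n > p) once
        self.full_fit = {
            role: fit_model(dataset, specs[role], role) for role in ("m1", "m2", "y")
        }

    def fit(self, idx: np.ndarray | None = None) -> dict[str, FittedLinearModel]:
        """Refit all three models, optionally on a row resample ``idx``."""
        if idx is None:
            return self.full_fit
        out = {}
        for role in ("m1", "m2", "y"):
            X = self.designs[role][idx]
            y = self.responses[role][idx]
            res = sm.OLS(y, X).fit()
            builder = self.builders[role]
            out[role] = FittedLinearModel(
                role=role,
                spec=self.specs[role],
                builder=builder,
                params=pd.Series(res.params, index=builder.column_names),
                sigma2=float(res.ssr / res.df_resid),
                nobs=len(y),
            )
        return out

    def expand_baseline(self, K: int, idx: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Baseline confounder columns tiled K times (subjects x K rows)."""
        df = self.dataset.df if idx is None else self.dataset.df.iloc[idx]
        return {c: np.tile(df[c].to_numpy(), K) for c in self.baseline_cols}


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def _needed_worlds(cells: Iterable[tuple], reduced: bool):
    m1_worlds, m2_pairs = set(), set()
    for c in cells:
        if reduced:
            a0, a1, a2 = c
            m1_worlds.add(a1)
            m2_pairs.add((a2, 0))  # world-independent M2 in the reduced system
        else:
            a0, a1, a2, a3 = c
            m1_worlds.update((a1, a3))
            m2_pairs.add((a2, a3))
    return m1_worlds, m2_pairs


def build_counterfactual_table(
    models: Mapping[str, FittedLinearModel],
    dataset: Dataset,
    config: SensitivityConfig,
    *,
    baseline: Mapping[str, np.ndarray] | None = None,
    noise: CrossworldNoise | None = None,
    cells: Sequence[tuple] | None = None,
    y_draw: bool = False,
    reduced: bool = False,
) -> CounterfactualTable:
    """Simulate the counterfactual outcome table at one rho.

    ``baseline``/``noise`` allow a caller managing a rho grid or bootstrap to
    pre-expand the confounders and pre-draw the standard-normal streams
    (common random numbers); by default they are derived from
    ``config.seed``.  ``cells`` restricts which counterfactual indices are
    populated (e.g. only the TCE's two corners).
    """
    for role in ("m1", "m2", "y"):
        if role not in models:
            raise ModelError(f"missing fitted model for role {role!r}")
    n, K = dataset.n, config.K
    n_rows = n * K
    if cells is None:
        cells = (
            tuple(itertools.product((0, 1), repeat=3)) if reduced else ALL_CELLS
        )
    cells = [tuple(c) for c in cells]
    if baseline is None:
        needed = set()
        for m in models.values():
            needed |= m.spec.variables()
        needed -= {dataset.exposure, dataset.m1, dataset.m2, dataset.outcome}
        baseline = {c: np.tile(dataset.df[c].to_numpy(), K) for c in sorted(needed)}
    if noise is None:
        rng = np.random.default_rng(config.seed)
        noise = CrossworldNoise.draw(n_rows, rng, y_draw=y_draw)

    m1_worlds, m2_pairs = _needed_worlds(cells, reduced)
    m1_0, m1_1 = draw_crossworld_m1(
        models["m1"], baseline, config.rho, noise, dataset.exposure
    )
    m1_by_world = {0: m1_0, 1: m1_1}

    m2_draws: dict[tuple[int, int], np.ndarray] = {}
    for a2, a1w in m2_pairs:
        if reduced:
            # no M1 -> M2 path: the M2 model has no M1 regressor, one draw per a2
            cf = {**baseline, dataset.exposure: np.full(n_rows, float(a2))}
            m2_draws[(a2, a1w)] = (
                models["m2"].predict_mean(cf, n=n_rows)
                + models["m2"].sigma * noise.z2[(a2, a1w)]
            )
        else:
            m2_draws[(a2, a1w)] = draw_m2_counterfactuals(
                models["m2"], baseline, a2, m1_by_world[a1w],
                noise.z2[(a2, a1w)], dataset.exposure, dataset.m1,
            )

    y_model = models["y"]
    out: dict[tuple, np.ndarray] = {}
    for c in cells:
        if reduced:
            a0, a1, a2 = c
            m2_val = m2_draws[(a2, 0)]
            m1_val = m1_by_world[a1]
        else:
            a0, a1, a2, a3 = c
            m2_val = m2_draws[(a2, a3)]
            m1_val = m1_by_world[a1]
        cf = {
            **baseline,
            dataset.exposure: np.full(n_rows, float(a0)),
            dataset.m1: m1_val,
            dataset.m2: m2_val,
        }
        vals = y_model.predict_mean(cf, n=n_rows)
        if y_draw:
            vals = vals + y_model.sigma * noise.zy
        out[c] = vals
    return CounterfactualTable(
        cells=out, n_subjects=n, K=K, rho=config.rho, seed=config.seed,
        reduced=reduced,
    )


# ---------------------------------------------------------------------------
# Effect estimation
# ---------------------------------------------------------------------------

def estimate_effects(table: CounterfactualTable) -> EffectTable:
    """TCE and every path-specific effect as cell-contrast means."""
    rows = []
    if table.reduced:
        ones, zeros = (1, 1, 1), (0, 0, 0)
        contrasts = algebra.enumerate_reduced_effects()
    else:
        ones, zeros = (1, 1, 1, 1), (0, 0, 0, 0)
        contrasts = algebra.enumerate_effects()
    rows.append(
        {
            "effect": "TCE", "path": "total", "type": "",
            "estimate": float(np.mean(table.cells[ones] - table.cells[zeros])),
        }
    )
    for c in contrasts:
        if c.plus not in table.cells or c.minus not in table.cells:
            continue
        rows.append(
            {
                "effect": c.name,
                "path": c.path,
                "type": algebra.bits_str(c.bits),
                "estimate": float(np.mean(table.cells[c.plus] - table.cells[c.minus])),
            }
        )
    return EffectTable(df=pd.DataFrame(rows), provenance=table.provenance)


def estimate_decompositions(effects: EffectTable) -> pd.DataFrame:
    """All decompositions with component estimates and their (exact) sums.

    Requires every effect to come from one shared counterfactual table: the
    sums then equal the TCE to floating-point cancellation.
    """
    if not isinstance(effects, EffectTable):
        raise TypeError("estimate_decompositions expects an EffectTable")
    reduced = bool(effects.provenance[-1])
    tce = effects.tce
    rows = []
    if reduced:
        for i, comps in enumerate(algebra.enumerate_reduced_decompositions(), 1):
            row = {"decomposition": i}
            for c in comps:
                row[algebra.PATH_LABELS[c.path]] = effects[c.name]
                row[f"{algebra.PATH_LABELS[c.path]}_type"] = algebra.bits_str(c.bits)
            row["sum"] = sum(effects[c.name] for c in comps)
            row["TCE"] = tce
            rows.append(row)
    else:
        for d in algebra.enumerate_decompositions():
            row = {"decomposition": d.table_row}
            for c in d.components:
                row[algebra.PATH_LABELS[c.path]] = effects[c.name]
                row[f"{algebra.PATH_LABELS[c.path]}_code"] = c.type_code
            row["sum"] = sum(effects[c.name] for c in d.components)
            row["TCE"] = tce
            rows.append(row)
    return pd.DataFrame(rows)


def combine_effect_tables(tables: Sequence[EffectTable]) -> EffectTable:
    """Concatenate effect tables; errors if their provenance differs."""
    provs = {t.provenance for t in tables}
    if len(provs) != 1:
        raise ValueError(
            f"cannot combine effects with mismatched provenance: {sorted(provs)}"
        )
    return EffectTable(
        df=pd.concat([t.df for t in tables], ignore_index=True).drop_duplicates("effect"),
        provenance=tables[0].provenance,
    )


# ---------------------------------------------------------------------------
# LSEM comparator
# ---------------------------------------------------------------------------

def lsem_comparator(
    dataset: Dataset, specs: Mapping[str, ModelSpec]
) -> dict[str, float]:
    """Product-of-coefficients path effects from an interaction-free LSEM.

    direct = Y-model X coefficient; via_m1 = (M1-model X) * (Y-model M1);
    via_m2 = (M2-model X) * (Y-model M2); via_both = (M1-model X) *
    (M2-model M1) * (Y-model M2).  Raises if any spec contains an
    interaction: coefficient products are not valid in that case.
    """
    for role, spec in specs.items():
        inter = [t for t in spec.terms if ":" in t]
        if inter:
            raise ModelError(
                f"LSEM comparator requires interaction-free specs; "
                f"{role!r} model contains {inter}"
            )
    fits = {role: fit_model(dataset, specs[role], role) for role in ("m1", "m2", "y")}
    x, m1, m2 = dataset.exposure, dataset.m1, dataset.m2
    a = float(fits["m1"].params[x])
    gx = float(fits["m2"].params[x])
    gm = float(fits["m2"].params[m1])
    ty = float(fits["y"].params[x])
    t1 = float(fits["y"].params[m1])
    t2 = float(fits["y"].params[m2])
    out = {
        "direct": ty,
        "via_m1": a * t1,
        "via_m2": gx * t2,
        "via_both": a * gm * t2,
    }
    out["total"] = sum(out.values())
    return out


# ---------------------------------------------------------------------------
# Full analysis driver with bootstrap inference
# ---------------------------------------------------------------------------

def _all_quantities(table: CounterfactualTable) -> dict[str, float]:
    """Every reported scalar from one table: TCE, 32 effects, summaries,
    variabilities, and both MS families (full system only)."""
    from .summaries import effect_variability, mediator_specific_effects, summary_effects

    effects = estimate_effects(table)
    out = dict(zip(effects.df["effect"], effects.df["estimate"]))
    if not table.reduced and len(table.cells) == len(ALL_CELLS):
        out.update(summary_effects(effects))
        out.update(effect_variability(effects))
        out.update(mediator_specific_effects(table))
    return out


@dataclass
class MediationResults:
    """Results of a sensitivity-grid analysis with optional bootstrap."""

    point: dict[float, dict[str, float]]  # rho -> quantity -> estimate
    replicates: dict[float, pd.DataFrame]  # rho -> B x quantity frame
    decompositions: dict[float, pd.DataFrame]
    config: EstimationConfig
    lsem: dict[str, float] | None = None
    fits: dict[str, FittedLinearModel] | None = None

    def effects_frame(self) -> pd.DataFrame:
        """Long-format estimates with bootstrap SEs and 95% CIs per rho."""
        rows = []
        for rho, est in self.point.items():
            reps = self.replicates.get(rho)
            for name, value in est.items():
                row = {"rho": rho, "effect": name, "estimate": value}
                if reps is not None and name in reps.columns:
                    se = float(reps[name].std(ddof=1))
                    row["se"] = se
                    if self.config.ci_method == "percentile":
                        row["ci_low"] = float(reps[name].quantile(0.025))
                        row["ci_high"] = float(reps[name].quantile(0.975))
                    else:
                        row["ci_low"] = value - 1.96 * se
                        row["ci_high"] = value + 1.96 * se
                rows.append(row)
        return pd.DataFrame(rows)


def analyze(
    dataset: Dataset,
    specs: Mapping[str, ModelSpec] | None = None,
    config: EstimationConfig = EstimationConfig(),
    *,
    cells: Sequence[tuple] | None = None,
    lsem: bool = False,
) -> MediationResults:
    """Point estimation over the rho grid plus nonparametric bootstrap.

    Models are always fitted on the original sample; the Monte-Carlo
    expansion uses ``config.K`` pseudo-subjects per subject.  Within each
    replicate (and the point estimate) the rho grid shares one set of random
    draws, so rho-free effects are invariant across the grid by construction.
    Bootstrap replicates resample subjects with replacement, refit all three
    models and re-run the simulation with fresh draws.
    """
    if specs is None:
        from .models import default_specs

        specs = default_specs(dataset, interactions=not config.reduced)
        if config.reduced:
            x = dataset.exposure
            specs["m2"] = ModelSpec([x, *dataset.confounders])
    cache = PipelineCache(dataset, specs)
    master = np.random.SeedSequence(config.seed)
    point_ss, boot_ss = master.spawn(2)

    def run(models, baseline, noise_seed) -> dict[float, dict[str, float]]:
        n_rows = len(next(iter(baseline.values()))) if baseline else dataset.n * config.K
        rng = np.random.default_rng(noise_seed)
        noise = CrossworldNoise.draw(n_rows, rng, y_draw=config.y_draw)
        out = {}
        for rho in config.rho_grid:
            table = build_counterfactual_table(
                models, dataset, SensitivityConfig(rho=rho, seed=config.seed, K=config.K),
                baseline=baseline, noise=noise, cells=cells,
                y_draw=config.y_draw, reduced=config.reduced,
            )
            out[rho] = (_all_quantities(table), table)
        return out

    baseline = cache.expand_baseline(config.K)
    point_runs = run(cache.fit(), baseline, point_ss)
    point = {rho: q for rho, (q, _) in point_runs.items()}
    full = len(ALL_CELLS) if not config.reduced else 8
    decomps = {
        rho: estimate_decompositions(estimate_effects(t))
        for rho, (_, t) in point_runs.items()
        if len(t.cells) == full
    }

    replicates: dict[float, pd.DataFrame] = {}
    if config.B > 0:
        rep_rows: dict[float, list[dict[str, float]]] = {r: [] for r in config.rho_grid}
        children = boot_ss.spawn(config.B)
        for b in range(config.B):
            rng_b = np.random.default_rng(children[b])
            idx = rng_b.integers(0, dataset.n, dataset.n)
            models_b = cache.fit(idx)
            baseline_b = cache.expand_baseline(config.K, idx)
            # fresh noise per replicate, shared across the rho grid
            runs_b = run(models_b, baseline_b, children[b].spawn(1)[0])
            for rho, (q, _) in runs_b.items():
                rep_rows[rho].append(q)
        replicates = {rho: pd.DataFrame(rows) for rho, rows in rep_rows.items()}

    lsem_out = None
    if lsem:
        from .models import default_specs

        lsem_out = lsem_comparator(dataset, default_specs(dataset, interactions=False))
    return MediationResults(
        point=point, replicates=replicates, decompositions=decomps,
        config=config, lsem=lsem_out, fits=cache.fit(),
    )
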