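"""Dataset reading, run configuration and results serialization.

CSV (RFC-4180, UTF-8, '.' decimal) is the single tabular dialect.  Reading
validates the exposure as strictly binary, drops incomplete rows with a
logged count (complete-case analysis), and leaves categorical confounders as
strings — they expand to treatment-coded indicators (alphabetical reference
level) inside the design builder, so the encoding is deterministic and
recorded in the run log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .gcomp import EstimationConfig, MediationResults
from .models import Dataset, ModelError

logger = logging.getLogger("medpaths")


@dataclass
class RunConfig:
    """Column mapping and estimation settings for one run."""

    exposure: str
    m1: str
    m2: str
    outcome: str
    confounders: tuple[str, ...] = ()
    log_m1: bool = False
    log_m2: bool = False
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    #: optional explicit term lists per model role ("m1", "m2", "y");
    #: None means the default interaction specs
    model_specs: dict[str, tuple[str, ...]] | None = None

    def specs(self) -> dict[str, "ModelSpec"] | None:
        from .models import ModelSpec

        if self.model_specs is None:
            return None
        return {role: ModelSpec(terms) for role, terms in self.model_specs.items()}

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        est = d.pop("estimation", {})
        est["rho_grid"] = tuple(est.get("rho_grid", (1.0, 0.5, 0.0)))
        d["confounders"] = tuple(d.get("confounders", ()))
        if d.get("model_specs") is not None:
            d["model_specs"] = {
                role: tuple(terms) for role, terms in d["model_specs"].items()
            }
        return cls(estimation=EstimationConfig(**est), **d)


def read_dataset(path: str | Path, config: RunConfig) -> Dataset:
    """Read and validate a mediation dataset from CSV.

    Non-binary exposure values raise an error naming the offending value;
    rows with missing analysis columns are dropped and the count logged.
    """
    df = pd.read_csv(path)
    cols = [config.exposure, config.m1, config.m2, config.outcome, *config.confounders]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ModelError(f"{path}: missing column(s) {missing}")
    dataset = Dataset.from_dataframe(
        df,
        exposure=config.exposure,
        m1=config.m1,
        m2=config.m2,
        outcome=config.outcome,
        confounders=config.confounders,
        log_m1=config.log_m1,
        log_m2=config.log_m2,
    )
    if dataset.n_dropped:
        logger.info(
            "dropped %d row(s) with missing analysis values (%d remain)",
            dataset.n_dropped, dataset.n,
        )
    return dataset


def write_results(
    results: MediationResults,
    out_dir: str | Path,
    config: RunConfig | None = None,
    truths: dict | None = None,
) -> dict[str, Path]:
    """Write effects/decompositions/summary/MS CSVs plus a run log.

    Output is bit-stable given identical inputs and seeds: floats are
    serialized with repr-roundtrip precision by pandas.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frame = results.effects_frame()
    is_ms = frame["effect"].str.startswith(("MS1", "MS2"))
    is_summary = frame["effect"].str.match(r"^(S(NDE|NIE)|var-)")
    written["effects"] = out / "effects.csv"
    frame[~is_ms & ~is_summary].to_csv(written["effects"], index=False)
    written["summary_effects"] = out / "summary_effects.csv"
    frame[is_summary].to_csv(written["summary_effects"], index=False)
    if is_ms.any():
        written["ms_effects"] = out / "ms_effects.csv"
        frame[is_ms].to_csv(written["ms_effects"], index=False)

    dec = pd.concat(
        [d.assign(rho=rho) for rho, d in results.decompositions.items()],
        ignore_index=True,
    )
    written["decompositions"] = out / "decompositions.csv"
    dec.to_csv(written["decompositions"], index=False)

    if results.fits is not None:
        coef_rows = [
            {"model": role, "term": term, "coefficient": value,
             "sigma2": fit.sigma2}
            for role, fit in results.fits.items()
            for term, value in fit.params.items()
        ]
        written["coefficients"] = out / "coefficients.csv"
        pd.DataFrame(coef_rows).to_csv(written["coefficients"], index=False)

    if truths is not None:
        written["truths"] = out / "truths.json"
        written["truths"].write_text(json.dumps(truths, indent=2, sort_keys=True))

    cfg = results.config
    log_lines = [
        f"medpaths {__version__}",
        f"seed: {cfg.seed}",
        f"K: {cfg.K}",
        f"B: {cfg.B}",
        f"rho_grid: {list(cfg.rho_grid)}",
        f"ci_method: {cfg.ci_method}",
        f"y_draw: {cfg.y_draw}",
        f"reduced: {cfg.reduced}",
        "mediator order: m1 causally prior to m2 (m1 may affect m2)",
        "categorical encoding: treatment coding, alphabetical reference level",
    ]
    if config is not None:
        log_lines.append("config:")
        log_lines.append(config.to_json())
    if results.lsem is not None:
        log_lines.append(f"lsem_comparator: {json.dumps(results.lsem, sort_keys=True)}")
    written["run_log"] = out / "run_log.txt"
    written["run_log"].write_text("\n".join(log_lines) + "\n")
    return written
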