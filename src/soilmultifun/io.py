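"""Table readers/writers, schema validation, configuration, and the
pipeline driver chaining simulation through inference.

All tabular exchange uses RFC-4180 CSV (UTF-8, '.' decimal, empty cell
for missing); ``plot_id`` is the join key everywhere. Floats are written
with Python's shortest-repr formatting, which round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, fd, inference, multifun, synthetic
from .errors import SchemaError

__all__ = [
    "TableSchema",
    "SCHEMAS",
    "read_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("soilmultifun")


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one CSV table.

    ``required`` columns must be present; ``numeric`` ones (or, with
    ``rest_numeric``, every non-required column) must parse as floats.
    ``key`` enforces uniqueness.
    """

    name: str
    key: str | None
    required: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    rest_numeric: bool = False


SCHEMAS = {
    "design": TableSchema(
        "design",
        key="plot_id",
        required=("plot_id", "ring", "co2", "n", "sown_richness",
                  "sown_species", "n_functional_groups"),
        numeric=("ring", "sown_richness", "n_functional_groups"),
    ),
    "covers": TableSchema("covers", key="plot_id", required=("plot_id",),
                          rest_numeric=True),
    "traits": TableSchema("traits", key="species", required=("species",),
                          rest_numeric=True),
    "functions": TableSchema(
        "functions",
        key="plot_id",
        required=("plot_id",) + synthetic.FUNCTION_NAMES,
        numeric=synthetic.FUNCTION_NAMES,
    ),
    "respiration": TableSchema(
        "respiration",
        key=None,
        required=("plot_id", "hour", "rate", "glucose"),
        numeric=("hour", "rate"),
    ),
    "sieving": TableSchema(
        "sieving",
        key=None,
        required=("plot_id", "duplicate", "wsf_g", "coarse_g"),
        numeric=("duplicate", "wsf_g", "coarse_g"),
    ),
}


def read_table(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read and validate one CSV table against its schema.

    Returns a DataFrame indexed by the schema key (if any). Schema
    violations raise :class:`SchemaError` citing the offending column
    and, for cell-level problems, the row.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{schema.name}: file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(f"{schema.name}: missing column {col!r}")
    numeric = set(schema.numeric)
    if schema.rest_numeric:
        numeric |= set(df.columns) - set(schema.required)
    for col in numeric:
        # Python's float() is correctly rounded, so shortest-repr output
        # read back through here is bit-exact
        parsed = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            if raw == "":
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(raw)
            except ValueError:
                raise SchemaError(
                    f"{schema.name}: non-numeric value {raw!r} "
                    f"in column {col!r}, row {i + 2}"
                ) from None
        df[col] = parsed
    if schema.key is not None:
        dupes = df[schema.key][df[schema.key].duplicated()]
        if len(dupes):
            raise SchemaError(
                f"{schema.name}: duplicate {schema.key} {dupes.iloc[0]!r}"
            )
        df = df.set_index(schema.key)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with exact float round-trip."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, lineterminator="\n")


@dataclass
class PipelineConfig:
    """All pipeline options, overridable from a flat YAML/JSON file."""

    seed: int = 0
    out_dir: str = "."
    in_dir: str | None = None  # read inputs instead of simulating
    replicates: tuple[int, int, int, int] = (32, 32, 15, 12)
    detect_threshold: float = 0.0
    focal_thresholds: tuple[float, ...] = (20, 40, 60, 80)
    threshold_range: tuple[int, int] = (1, 99)
    slope_regressor: str = "log"
    fd_correction: str = "cailliez"
    sir_factor: float = 38.0
    wsa_initial_mass_g: float = 4.0
    basal_window: tuple[int, int] = (14, 24)
    satterthwaite: bool = False
    exclude_monocultures: bool = False
    realized_richness: bool = False
    anova_responses: tuple[str, ...] | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        for key in ("replicates", "focal_thresholds", "threshold_range", "basal_window",
                    "anova_responses"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _species_join(species: tuple) -> str:
    return ";".join(species)


def simulate_stage(config: PipelineConfig):
    """Generate design, covers, traits, and functions; write them out."""
    params = synthetic.SimulationParams(seed=config.seed, replicates=config.replicates)
    pool = synthetic.build_species_pool()
    design = synthetic.generate_design(params)
    traits = synthetic.generate_traits(pool, params)
    covers = synthetic.generate_covers(design, params)
    functions = synthetic.generate_soil_functions(design, params)
    out = Path(config.out_dir)
    design_out = design.copy()
    design_out["sown_species"] = design_out["sown_species"].map(_species_join)
    write_table(design_out, out / "design.csv")
    write_table(covers, out / "covers.csv")
    write_table(traits, out / "traits.csv")
    write_table(functions, out / "functions.csv")
    log.info("simulate: %d plots, %d species", len(design), len(pool.species))
    return design, covers, traits, functions


def load_inputs(config: PipelineConfig):
    """Read previously written inputs from ``in_dir``."""
    src = Path(config.in_dir)
    design = read_table(src / "design.csv", "design")
    design["sown_species"] = design["sown_species"].map(
        lambda s: tuple(s.split(";")) if s else ()
    )
    covers = read_table(src / "covers.csv", "covers")
    traits = read_table(src / "traits.csv", "traits")
    functions = read_table(src / "functions.csv", "functions")
    return design, covers, traits, functions


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> metrics -> fd -> multifun -> inference.

    Writes every stage's CSV/JSON output under ``config.out_dir`` plus a
    ``run.log``; identical config and seed give byte-identical outputs.
    Returns the in-memory results keyed by stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("soilmultifun")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("seed=%d numpy=%s pandas=%s", config.seed,
                 np.__version__, pd.__version__)
        if config.in_dir:
            design, covers, traits, functions = load_inputs(config)
            log.info("loaded inputs from %s: %d plots", config.in_dir, len(design))
        else:
            design, covers, traits, functions = simulate_stage(config)

        diversity = community.diversity_table(covers, config.detect_threshold)
        write_table(diversity, out / "diversity.csv")
        log.info("metrics: %d plots", len(diversity))

        fd_table = fd.community_fd(covers, traits, correction=config.fd_correction)
        write_table(fd_table, out / "fd.csv")
        log.info("fd: %d plots", len(fd_table))

        mf = multifun.multifunctionality_table(functions, config.focal_thresholds)
        write_table(mf, out / "multifun.csv")
        lo, hi = config.threshold_range
        profile = multifun.threshold_slope_profile(
            functions.dropna(),
            design["sown_richness"],
            range(int(lo), int(hi) + 1),
            regressor=config.slope_regressor,
        )
        write_table(profile.set_index("t"), out / "threshold_profile.csv")
        log.info("multifun: %d plots, thresholds %d-%d", len(mf), lo, hi)

        analysis = design.join([functions, diversity, fd_table, mf])
        analysis_out = analysis.copy()
        analysis_out["sown_species"] = analysis_out["sown_species"].map(_species_join)
        write_table(analysis_out, out / "analysis.csv")

        responses = config.anova_responses or (
            synthetic.FUNCTION_NAMES
            + ("avg_multifunctionality",)
            + tuple(f"count_t{t:g}" for t in config.focal_thresholds)
            + ("H_func", "evenness_func")
        )
        anovas = {}
        for resp in responses:
            spec = inference.ModelSpec(
                response=resp,
                richness_col="realized_richness" if config.realized_richness
                else "sown_richness",
                exclude_monocultures=config.exclude_monocultures,
                satterthwaite=config.satterthwaite,
            )
            result = inference.type3_anova(analysis, spec)
            anovas[resp] = result
            write_table(result.table, out / f"anova_{resp}.csv")
        log.info("anova: %d responses", len(responses))

        correlations = inference.pearson_matrix(functions)
        write_table(correlations.set_index(["var1", "var2"]), out / "correlations.csv")
        log.info("correlations: %d pairs", len(correlations))

        sem_data = pd.DataFrame(
            {
                "ln_psr": np.log(analysis["sown_richness"].astype(float)),
                "fdis": analysis["FDis"],
                "evenness_func": analysis["evenness_func"],
                "avg_multifunctionality": analysis["avg_multifunctionality"],
            }
        )
        path_fit = inference.fit_path_model(sem_data)
        fit_json = {
            "n": path_fit.n,
            "chi2": path_fit.chi2,
            "df": path_fit.df,
            "p": path_fit.p,
            "aic": path_fit.aic,
            **{f"coef {src}->{dst}": v for (src, dst), v in path_fit.coefficients.items()},
            **{f"std {src}->{dst}": v for (src, dst), v in path_fit.standardized.items()},
            **{f"r2 {v}": val for v, val in path_fit.r2.items()},
        }
        (out / "path_fit.json").write_text(json.dumps(fit_json, indent=2) + "\n")
        log.info("path: n=%d chi2=%.4f df=%d", path_fit.n, path_fit.chi2, path_fit.df)

        return {
            "design": design,
            "covers": covers,
            "traits": traits,
            "functions": functions,
            "diversity": diversity,
            "fd": fd_table,
            "multifun": mf,
            "threshold_profile": profile,
            "analysis": analysis,
            "anova": anovas,
            "correlations": correlations,
            "path_fit": path_fit,
        }
    finally:
        root.removeHandler(handler)
        handler.close()
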