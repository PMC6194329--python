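"""Table schemas, config handling, and the end-to-end pipeline.

All tables are RFC-4180 CSV with header rows (hit tables may also be
tab-separated, mirroring BLAST outfmt 6 plus read-count and lineage
columns); configs are YAML; reports are JSON. `validate_and_load`
checks a table against its schema and reports every offending row with
its line number rather than stopping at the first.

`run_pipeline` chains the stages — simulate (or load) -> filter hits ->
diet tables and indices -> accumulation curves -> community statistics
-> electivity -> prior calibration -> mixing models -> temporal
validation — writing each artifact plus a manifest (inputs, parameters,
seeds, version) sufficient to reproduce any output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trophimix import __version__
from trophimix import community, diet, electivity, filtering, mixing, synthetic, turnover


class SchemaError(ValueError):
    """Raised when a table fails validation; message lists all offenses."""


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


SCHEMAS: dict[str, dict] = {
    "prey_records": {
        "required": ["stomach_id", "predator_group", "prey_taxon", "digestion_level", "method"],
        "row_checks": {
            "digestion_level": (
                lambda v: pd.isna(v) or (_is_number(v) and float(v) in (1, 2, 3, 4)),
                "digestion_level must be 1-4",
            ),
            "weight": (
                lambda v: pd.isna(v) or (_is_number(v) and float(v) >= 0),
                "weight must be a nonnegative number",
            ),
            "method": (lambda v: v in ("visual", "dna"), "method must be visual|dna"),
        },
    },
    "hits": {
        "required": ["stomach_id", "contig_id", "assigned_taxon", "pairwise_identity",
                     "fragment_length", "read_count"],
        "row_checks": {
            "pairwise_identity": (
                lambda v: _is_number(v) and 0 <= float(v) <= 100,
                "pairwise_identity must be in [0, 100]",
            ),
            "fragment_length": (
                lambda v: _is_number(v) and float(v) > 0,
                "fragment_length must be > 0",
            ),
            "read_count": (
                lambda v: _is_number(v) and float(v) >= 1 and float(v) == int(float(v)),
                "read_count must be an integer >= 1",
            ),
        },
    },
    "consumers": {
        "required": ["consumer_id", "tissue", "d13C", "d15N"],
        "row_checks": {
            "d13C": (_is_number, "d13C must be numeric"),
            "d15N": (_is_number, "d15N must be numeric"),
            "tissue": (lambda v: v in synthetic.TISSUES, "tissue must be plasma|RBC|muscle"),
        },
    },
    "sources": {
        "required": ["family", "isotope", "mean", "sd", "n"],
        "row_checks": {
            "mean": (_is_number, "mean must be numeric"),
            "sd": (lambda v: _is_number(v) and float(v) >= 0, "sd must be >= 0"),
        },
    },
    "tdf": {
        "required": ["tissue", "isotope", "mean", "sd"],
        "row_checks": {
            "mean": (_is_number, "mean must be numeric"),
            "sd": (lambda v: _is_number(v) and float(v) >= 0, "sd must be >= 0"),
        },
    },
    "surveys": {
        "required": ["reef", "family", "count"],
        "row_checks": {
            "count": (
                lambda v: _is_number(v) and float(v) >= 0,
                "count must be a nonnegative number",
            ),
        },
    },
}


def validate_and_load(path, schema: str | dict) -> pd.DataFrame:
    """Load a CSV/TSV table and validate it against a schema.

    All violations are collected and reported together, each with its
    1-based data line number (header is line 1).
    """
    path = Path(path)
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    problems: list[str] = []
    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        problems.append(f"missing column(s): {missing}")
    for col, (check, msg) in schema.get("row_checks", {}).items():
        if col not in df.columns:
            continue
        bad = [i for i, v in enumerate(df[col]) if not check(v)]
        problems.extend(f"line {i + 2}: {msg} (got {df[col].iloc[i]!r})" for i in bad)
    if problems:
        raise SchemaError(f"{path.name}: " + "; ".join(problems))
    return df


def write_csv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, lineterminator="\r\n")
    return path


def scenario_to_yaml(scenario: synthetic.TruthScenario, path) -> Path:
    d = dataclasses.asdict(scenario)

    def plain(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, dict):
            return {k: plain(x) for k, x in v.items()}
        if isinstance(v, (np.integer, np.floating)):
            return v.item()
        return v

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump({k: plain(v) for k, v in d.items()}, sort_keys=False))
    return path


def scenario_from_yaml(path) -> synthetic.TruthScenario:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("true_diet", "env_proportions"):
        d[key] = {k: np.asarray(v, dtype=float) for k, v in d[key].items()}
    for key in ("source_means", "source_sds", "residual_sd"):
        d[key] = np.asarray(d[key], dtype=float)
    for key in ("tdf_means", "tdf_sds"):
        d[key] = {k: np.asarray(v, dtype=float) for k, v in d[key].items()}
    return synthetic.TruthScenario(**d)


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic-scenario driven)."""

    outdir: str = "results/pipeline"
    seed: int = 0
    n_predators: int = 60
    n_consumers: int = 40
    reads_per_stomach: int = 10_000
    tissue: str = "muscle"
    prior_se: float = mixing.DEFAULT_PRIOR_SE
    ci_level: float = 0.75
    mcmc_iter: int = 6000
    mcmc_chains: int = 4
    run_mixing: bool = True
    run_electivity: bool = True
    run_community: bool = True
    scenario_yaml: str | None = None

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return RunConfig(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic workflow; returns the manifest.

    Stage order: simulate -> filter -> diet tables/indices/curves ->
    community statistics -> electivity -> prior calibration -> mixing
    (with and without prior) -> temporal validation. Outputs are written
    incrementally, so on a stage failure prior artifacts survive and the
    raised error names the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
    }
    if config.scenario_yaml:
        scenario = scenario_from_yaml(config.scenario_yaml)
        scenario = scenario.replace(seed=config.seed)
    else:
        scenario = synthetic.default_scenario(seed=config.seed)
    scenario_to_yaml(scenario, out / "scenario.yaml")
    manifest["outputs"]["scenario"] = "scenario.yaml"

    stage = "simulate"
    try:
        records = synthetic.simulate_stomachs(scenario, config.n_predators)
        hits = synthetic.simulate_hit_table(records, scenario, config.reads_per_stomach)
        consumers = synthetic.simulate_consumers(scenario, config.tissue, config.n_consumers)
        surveys = synthetic.simulate_surveys(scenario)
        write_csv(records, out / "prey_records.csv")
        write_csv(hits, out / "hit_table.csv")
        write_csv(consumers, out / "consumers.csv")
        write_csv(surveys, out / "surveys.csv")
        manifest["stages"].append(stage)

        stage = "filter"
        kept, report = filtering.filter_hits(hits.drop(columns=["is_contaminant"]))
        dna_records, dna_comp = filtering.hits_to_prey(
            kept, all_stomach_ids=list(records.attrs.get("stomach_ids", []))
        )
        write_csv(kept, out / "kept_hits.csv")
        (out / "filter_report.json").write_text(json.dumps(report, indent=2))
        manifest["stages"].append(stage)

        stage = "diet_tables"
        indices = diet.compute_indices(records)
        write_csv(indices.reset_index(names="category"), out / "diet_indices.csv")
        comp = dna_comp if not dna_comp.empty else diet.composition_from_counts(records)
        comp.rename_axis("category").reset_index().to_csv(out / "dna_composition.csv", index=False)
        curve = diet.accumulation_curve(
            diet.presence_matrix(dna_records), n_permutations=200, seed=config.seed
        )
        write_csv(curve, out / "accumulation_curve.csv")
        manifest["stages"].append(stage)

        if config.run_community:
            stage = "community"
            pres = diet.presence_matrix(dna_records)
            labels = pres.index.to_series().str.split("|").str[0].to_numpy()
            bc = community.bray_curtis(pres, presence_absence=True)
            res = community.anosim(bc, labels, n_permutations=499, seed=config.seed)
            (out / "anosim.json").write_text(
                json.dumps(dataclasses.asdict(res), indent=2)
            )
            coords, stress = community.nmds(bc, seed=config.seed)
            write_csv(coords.reset_index(), out / "nmds_coordinates.csv")
            manifest["outputs"]["nmds_stress"] = stress
            manifest["stages"].append(stage)

        if config.run_electivity:
            stage = "electivity"
            prof = electivity.electivity_profile(comp, surveys)
            write_csv(
                prof.drop(columns=["D_per_reef"]).reset_index(), out / "electivity.csv"
            )
            manifest["stages"].append(stage)

        mix_report = None
        if config.run_mixing:
            stage = "mixing"
            prior = mixing.calibrate_prior(
                comp.reindex(scenario.prey_categories, fill_value=0.0)
                .pipe(lambda s: s / s.sum())
                .to_numpy(),
                target_se=config.prior_se,
            )
            problem = mixing.MixingProblem(
                consumers=consumers[["d13C", "d15N"]].to_numpy(),
                source_names=scenario.prey_categories,
                source_means=scenario.source_means,
                source_sds=scenario.source_sds,
                tdf_means=scenario.tdf_means[config.tissue],
                tdf_sds=scenario.tdf_sds[config.tissue],
                prior_alpha=prior.alpha,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                summ = mixing.fit_mixing_model(
                    problem,
                    n_iter=config.mcmc_iter,
                    n_chains=config.mcmc_chains,
                    seed=config.seed,
                    ci_level=config.ci_level,
                )
                flat = dataclasses.replace(
                    problem, prior_alpha=np.ones(problem.n_sources)
                )
                summ_flat = mixing.fit_mixing_model(
                    flat,
                    n_iter=config.mcmc_iter,
                    n_chains=config.mcmc_chains,
                    seed=config.seed + 1,
                    ci_level=config.ci_level,
                )
            write_csv(summ.to_frame().reset_index(names="source"), out / "mixing_summary.csv")
            overlap = mixing.compare_models(summ, summ_flat)
            stage = "temporal_validation"
            truth_comp = pd.Series(
                scenario.true_diet[scenario.groups[0]], index=scenario.prey_categories
            )
            mix_report = turnover.validate_against_stomachs(summ, comp)
            mix_report["truth_check"] = turnover.validate_against_stomachs(summ, truth_comp)
            mix_report["with_without_prior_overlap"] = overlap.index
            mix_report["converged"] = summ.converged
            (out / "validation_report.json").write_text(json.dumps(mix_report, indent=2))
            manifest["stages"].append("mixing")
            manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"].update(
        {p.name: p.name for p in sorted(out.glob("*.csv"))}
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
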