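"""End-to-end orchestration: configuration, stage sequencing, file I/O.

Stage order is fixed: occupancy filtering -> decontamination ->
agglomeration -> per-locus index -> ensemble -> terrestrial removal ->
correlation significance -> network modules -> environment association.
A run is fully reproducible from its configuration and seed; the
manifest records what every stage consumed and dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ednanet import correlation, decontam, environment, index as index_mod, network, occupancy
from ednanet.synthetic import (
    CommunityScenario,
    GeneratorOutput,
    simulate,
    write_generator_output,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "read_counts",
    "read_metadata",
    "read_taxonomy",
    "read_environment",
    "load_inputs",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    seed: int
    scenario: CommunityScenario | None = None
    input_dir: str | None = None
    occupancy_threshold: float = 0.8
    bray_curtis_threshold: float = 0.49
    alpha: float = 0.05
    edge_view_threshold: float = 0.2
    hub_fraction: float = 0.10
    min_module_size: int = 5
    beta: int | str = "auto"
    n_permutations: int = 100
    contamination_estimator: str = "max"
    run_occupancy: bool = True
    run_decontamination: bool = True
    record_timestamps: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.scenario is None and self.input_dir is None:
            raise ValueError("need either a synthetic scenario or an input_dir")
        for name, lo, hi in (("occupancy_threshold", 0.0, 1.0),
                             ("bray_curtis_threshold", 0.0, 1.0),
                             ("alpha", 0.0, 1.0),
                             ("edge_view_threshold", 0.0, 1.0),
                             ("hub_fraction", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.beta != "auto" and int(self.beta) < 1:
            raise ValueError("beta must be 'auto' or an integer >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        thresholds = data.pop("thresholds", {})
        rename = {"occupancy": "occupancy_threshold",
                  "bray_curtis": "bray_curtis_threshold",
                  "edge_view": "edge_view_threshold",
                  "alpha": "alpha",
                  "hub_fraction": "hub_fraction",
                  "min_module_size": "min_module_size"}
        for key, value in thresholds.items():
            if key not in rename:
                raise ValueError(f"unknown threshold {key!r}")
            data[rename[key]] = value
        stages = data.pop("stages", {})
        if "occupancy" in stages:
            data["run_occupancy"] = bool(stages["occupancy"])
        if "decontamination" in stages:
            data["run_decontamination"] = bool(stages["decontamination"])
        scenario = data.pop("scenario", None)
        if scenario is not None:
            scenario = CommunityScenario.from_dict(scenario)
        return cls(scenario=scenario, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def snapshot(self) -> dict:
        data = asdict(self)
        if self.scenario is not None:
            data["scenario"] = self.scenario.to_dict()
        return data


# ---------------------------------------------------------------------------
# table I/O (TSV interchange)

def read_counts(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.astype(float)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0,
                       dtype={"sample_type": str})


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                        dtype={"family": str, "order": str, "class": str,
                               "habitat": str})
    return table


def read_environment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_inputs(directory: str | Path) -> GeneratorOutput:
    """Read a generator-style input directory (counts_*.tsv + tables)."""
    directory = Path(directory)
    counts = {}
    for path in sorted(directory.glob("counts_*.tsv")):
        locus = path.stem[len("counts_"):]
        counts[locus] = read_counts(path)
    if not counts:
        raise FileNotFoundError(f"no counts_*.tsv tables under {directory}")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return GeneratorOutput(
        counts=counts,
        metadata=read_metadata(directory / "metadata.tsv"),
        taxonomy=read_taxonomy(directory / "taxonomy.tsv"),
        environment=read_environment(directory / "environment.tsv"),
        truth=truth,
    )


def _write_tsv(table: pd.DataFrame, path: Path, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineResult:
    manifest: dict
    inputs: GeneratorOutput
    per_locus_index: dict[str, index_mod.IndexTable]
    ensemble: index_mod.IndexTable
    marine: index_mod.IndexTable
    correlations: correlation.CorrelationResult | None
    model: network.NetworkModel | None
    associations: pd.DataFrame | None
    profiles: dict[str, pd.DataFrame] = dc_field(default_factory=dict)


def _now(config: PipelineConfig) -> str | None:
    if not config.record_timestamps:
        return None
    return datetime.now(timezone.utc).isoformat()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages, writing TSV outputs and a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.snapshot(),
        "version": _package_version(),
        "started": _now(config),
        "stages": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    try:
        result = _run_stages(config, outdir, manifest, record)
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "_ednanet_stage", "unknown")
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise
    manifest["finished"] = _now(config)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return result


def _stage_error(stage: str, exc: Exception) -> Exception:
    exc._ednanet_stage = stage  # type: ignore[attr-defined]
    return exc


def _package_version() -> str:
    from ednanet import __version__

    return __version__


def _run_stages(config, outdir: Path, manifest, record) -> PipelineResult:
    # -- inputs -------------------------------------------------------------
    if config.scenario is not None:
        scenario = config.scenario
        if scenario.seed != config.seed:
            scenario = CommunityScenario.from_dict(
                {**scenario.to_dict(), "seed": config.seed})
        data = simulate(scenario)
        write_generator_output(data, outdir / "inputs", scenario=scenario)
        record("simulate", n_loci=len(data.counts),
               n_otus={k: int(v.shape[0]) for k, v in data.counts.items()},
               n_samples={k: int(v.shape[1]) for k, v in data.counts.items()})
    else:
        data = load_inputs(config.input_dir)
        record("load", input_dir=str(config.input_dir),
               n_loci=len(data.counts))

    metadata = data.metadata
    field_meta = metadata[metadata["sample_type"] == "field"]
    control_ids = list(metadata.index[metadata["sample_type"] != "field"])
    replicate_groups = {
        int(t): list(grp.index)
        for t, grp in field_meta.groupby("timepoint", sort=True)
    }

    # -- occupancy filter (per locus) --------------------------------------
    per_locus_counts: dict[str, pd.DataFrame] = {}
    occ_info = {}
    for locus, counts in data.counts.items():
        if config.run_occupancy:
            try:
                retained, audit = occupancy.occupancy_report(
                    counts, metadata, threshold=config.occupancy_threshold)
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise _stage_error("occupancy_filter", exc)
            _write_tsv(audit, outdir / f"occupancy_{locus}.tsv")
            kept = [o for o in counts.index if o in retained]
            per_locus_counts[locus] = counts.loc[kept]
            occ_info[locus] = {"before": int(counts.shape[0]),
                               "after": len(kept)}
        else:
            per_locus_counts[locus] = counts
            occ_info[locus] = {"before": int(counts.shape[0]),
                               "after": int(counts.shape[0])}
    record("occupancy_filter", skipped=not config.run_occupancy, otus=occ_info)

    # -- decontamination + replicate QC (per locus) ------------------------
    cleaned_counts: dict[str, pd.DataFrame] = {}
    retained_by_locus: dict[str, list[int]] = {}
    qc_frames = []
    for locus, counts in per_locus_counts.items():
        try:
            props, _empty = decontam.proportionalize(counts)
            if config.run_decontamination:
                profile = decontam.estimate_contamination(
                    props, control_ids, estimator=config.contamination_estimator)
                cleaned = decontam.subtract_contamination(props, profile)
            else:
                cleaned = props
            field_cols = [c for c in counts.columns if c not in set(control_ids)]
            cleaned = cleaned[field_cols]
            if config.run_decontamination:
                dissim = decontam.replicate_dissimilarity(cleaned, replicate_groups)
                retained, report = decontam.drop_dissimilar_samples(
                    dissim, threshold=config.bray_curtis_threshold)
                report.insert(0, "locus", locus)
                qc_frames.append(report)
            else:
                retained = list(replicate_groups)
            retained_by_locus[locus] = list(retained)
            depths = counts[field_cols].sum(axis=0)
            cleaned_counts[locus] = cleaned * depths  # pseudo-counts at original depth
        except Exception as exc:
            raise _stage_error("decontamination", exc)
    if qc_frames:
        _write_tsv(pd.concat(qc_frames), outdir / "qc_report.tsv",
                   index_label="timepoint")
    shared_timepoints = sorted(
        set.intersection(*(set(v) for v in retained_by_locus.values())))
    if not shared_timepoints:
        raise _stage_error("decontamination",
                           ValueError("no time point survived replicate QC "
                                      "in every locus"))
    record("decontamination", skipped=not config.run_decontamination,
           retained_timepoints=shared_timepoints,
           dropped_timepoints={
               locus: sorted(set(replicate_groups) - set(kept))
               for locus, kept in retained_by_locus.items()})

    # -- agglomeration + per-locus index -----------------------------------
    tables: list[index_mod.IndexTable] = []
    taxon_tables = []
    agglomeration_audit = {}
    all_taxa: set[str] = set()
    collapsed: dict[str, pd.DataFrame] = {}
    for locus, counts in cleaned_counts.items():
        try:
            taxon_counts, taxon_table, audit = index_mod.agglomerate_taxa(
                counts, data.taxonomy)
            agglomeration_audit[locus] = audit
            taxon_tables.append(taxon_table)
            props, _ = decontam.proportionalize(taxon_counts)
            groups = {t: [c for c in replicate_groups[t] if c in props.columns]
                      for t in shared_timepoints}
            collapsed[locus] = decontam.collapse_replicates(props, groups)
            all_taxa.update(taxon_counts.index)
        except Exception as exc:
            raise _stage_error("agglomerate", exc)
    taxon_universe = sorted(all_taxa)
    for locus in collapsed:
        aligned = collapsed[locus].reindex(taxon_universe, fill_value=0.0)
        table = index_mod.edna_index(aligned, locus=locus)
        _write_tsv(table.values, outdir / f"index_{locus}.tsv",
                   index_label="taxon")
        tables.append(table)
    record("agglomerate", audit=agglomeration_audit,
           n_taxa=len(taxon_universe))
    record("per_locus_index", loci=sorted(collapsed))

    taxon_table = pd.concat(taxon_tables)
    taxon_table = taxon_table[~taxon_table.index.duplicated(keep="first")]

    # -- ensemble + terrestrial removal ------------------------------------
    try:
        ensemble = index_mod.ensemble_index(tables)
        marine, removed = index_mod.remove_terrestrial(ensemble, taxon_table)
    except Exception as exc:
        raise _stage_error("ensemble_index", exc)
    _write_tsv(ensemble.values, outdir / "index_ensemble.tsv",
               index_label="taxon")
    _write_tsv(marine.values, outdir / "index_marine.tsv", index_label="taxon")
    record("ensemble", n_taxa=int(ensemble.values.shape[0]))
    record("terrestrial_removal", removed=removed,
           n_taxa_after=int(marine.values.shape[0]))

    # -- correlation significance ------------------------------------------
    values = marine.values
    nonconstant = values.index[values.nunique(axis=1) > 1]
    testable = values.loc[nonconstant]
    if len(testable) < 2:
        raise _stage_error("correlation_significance",
                           ValueError("fewer than 2 non-constant taxa"))
    try:
        corr = correlation.analyze(testable, n_perm=config.n_permutations,
                                   alpha=config.alpha, seed=config.seed)
    except Exception as exc:
        raise _stage_error("correlation_significance", exc)
    _write_tsv(corr.pair_table(), outdir / "pairs.tsv", index=False)
    np.savetxt(outdir / "null_taus.tsv", corr.null_taus, fmt="%.6f")
    record("correlation_significance",
           n_taxa=int(len(testable)),
           n_pairs=int(len(testable) * (len(testable) - 1) // 2),
           n_null=int(corr.null_taus.size),
           critical_tau=(None if np.isinf(corr.critical_tau)
                         else float(corr.critical_tau)),
           constant_excluded=sorted(set(values.index) - set(nonconstant)))

    # -- network modules ----------------------------------------------------
    try:
        model = network.build_network(
            corr.tau, beta=config.beta, min_size=config.min_module_size)
    except Exception as exc:
        raise _stage_error("network_modules", exc)
    modules_table = pd.DataFrame({
        "module": model.modules,
        "intramodular_k": model.connectivity,
    })
    _write_tsv(modules_table, outdir / "modules.tsv", index_label="taxon")
    edges = network.edge_list(model.adjacency, model.modules,
                              threshold=config.edge_view_threshold)
    _write_tsv(edges, outdir / "edges.tsv", index=False)
    hub_table = network.hubs(model.connectivity, model.modules,
                             fraction=config.hub_fraction)
    _write_tsv(hub_table, outdir / "hubs.tsv", index=False)
    if model.fits:
        _write_tsv(pd.DataFrame([asdict(f) for f in model.fits]),
                   outdir / "scale_free.tsv", index=False)
    (outdir / "dendrogram.txt").write_text(
        network.dendrogram_to_newick(model.dendrogram, model.modules.index))
    module_sizes = model.modules.value_counts().to_dict()
    record("network_modules", beta=int(model.beta),
           modules={str(k): int(v) for k, v in module_sizes.items()})

    # -- environment association -------------------------------------------
    env = data.environment
    env = env.loc[[t for t in env.index if t in set(values.columns)]]
    try:
        profiles = environment.module_richness(marine, model.modules)
        module_assoc = environment.module_env_correlation(profiles, env)
        taxon_assoc = environment.taxon_env_correlation(marine, env)
    except Exception as exc:
        raise _stage_error("environment_association", exc)
    _write_tsv(profiles["richness"], outdir / "module_richness.tsv",
               index_label="module")
    _write_tsv(profiles["mean_index"], outdir / "module_mean_index.tsv",
               index_label="module")

    conn_rows = []
    for label in sorted(set(model.modules) - {"unassigned"}):
        members = model.modules.index[model.modules == label]
        if len(members) < 4:
            continue
        sub = module_assoc[(module_assoc["module"] == label)
                           & (module_assoc["summary"] == "mean_index")
                           & (module_assoc["method"] == "spearman")]
        sub = sub.dropna(subset=["r"])
        if sub.empty:
            continue
        best = sub.loc[sub["r"].abs().idxmax()]
        r, p = environment.connectivity_env_relationship(
            model.connectivity, taxon_assoc, model.modules,
            label, best["variable"])
        conn_rows.append({"module": label, "variable": best["variable"],
                          "module_env_r": best["r"],
                          "connectivity_env_r": r,
                          "connectivity_env_p": p})
    associations = pd.concat([
        module_assoc.assign(entity_type="module").rename(
            columns={"module": "entity"}),
        taxon_assoc.assign(entity_type="taxon").rename(
            columns={"taxon": "entity"}),
    ], ignore_index=True)
    _write_tsv(associations, outdir / "associations.tsv", index=False)
    if conn_rows:
        _write_tsv(pd.DataFrame(conn_rows),
                   outdir / "connectivity_env.tsv", index=False)
    record("environment_association",
           n_module_rows=int(len(module_assoc)),
           n_taxon_rows=int(len(taxon_assoc)))

    return PipelineResult(
        manifest=manifest, inputs=data, per_locus_index={
            t.locus: t for t in tables},
        ensemble=ensemble, marine=marine, correlations=corr, model=model,
        associations=associations, profiles=profiles)
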