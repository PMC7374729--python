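"""End-to-end orchestration: catalogs -> ddG join -> contrasts -> LEM fits.

A run is described by a :class:`RunConfig` (usually loaded from YAML).
Outputs land in the run's output directory: a machine-readable
``summary.json``, a human-readable ``report.txt``, per-curve fit JSON and
audit TSVs, the joined ddG table, and a JSON-lines stage log. Two runs
with identical config and seed produce identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import compare as cmp
from . import io as sio
from .catalog import (
    DEFAULT_DOMAIN_MAP,
    dataset_overlap,
    domain_stats,
    parse_variant_table,
)
from .constants import ALPHA_MAX_DEFAULT, ALPHA_MIN_DEFAULT, R_KCAL, T_DEFAULT
from .denaturation import FitConfig, analyze_curve, ddg_relative
from .errors import StageError
from .simulate import (
    DEFAULT_CATALOG_SPEC,
    CatalogSpec,
    simulate_catalogs,
)

logger = logging.getLogger("stabscan")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class CurveInput:
    path: str | None = None          # CSV file; None -> simulate
    sample_id: str | None = None
    theta_folded: float | None = None
    theta_unfolded: float | None = None
    dg0: float | None = None         # simulation parameters
    m_value: float | None = None
    noise_sd: float = 0.0


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    output_dir: str = "stabscan_out"
    seed: int = 0
    # catalog stage: either variant-table paths keyed by dataset name, or
    # simulate with the spec below
    variant_tables: dict[str, str] = field(default_factory=dict)
    column_map: dict[str, str] = field(default_factory=dict)
    simulate_catalog: bool = True
    catalog_spec: CatalogSpec | None = None
    # ddG stage: FoldX Dif files (empty -> use simulated ddG table)
    ddg_files: list[str] = field(default_factory=list)
    # contrasts: pairs of class labels, on "sources" or "phenotype"
    contrasts: list[dict] = field(default_factory=lambda: [
        {"column": "sources", "a": "HGMD", "b": "polymorphism"},
        {"column": "phenotype", "a": "CAIS", "b": "PAIS"},
    ])
    test_method: str = "welch"
    # denaturation stage
    curves: list[CurveInput] = field(default_factory=list)
    wt_sample_id: str | None = None
    temperature_K: float = T_DEFAULT
    gas_constant: float = R_KCAL
    alpha_min: float = ALPHA_MIN_DEFAULT
    alpha_max: float = ALPHA_MAX_DEFAULT


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    curves = [CurveInput(**c) for c in raw.pop("curves", [])]
    spec_raw = raw.pop("catalog_spec", None)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw, curves=curves)
    if spec_raw is not None:
        from .simulate import ClassSpec
        classes = {
            k: ClassSpec(**spec_raw.pop(k))
            for k in ("disease", "somatic", "polymorphism")
        }
        cfg.catalog_spec = CatalogSpec(**classes, **spec_raw)
    return cfg


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []

    def log(self, stage: str, **info):
        entry = {"stage": stage, **info}
        self.entries.append(entry)
        logger.info("%s: %s", stage, info)

    def flush(self):
        with open(self.path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True, default=str) + "\n")


def _catalog_stage(config: RunConfig, log: _StageLog):
    if config.variant_tables:
        catalogs = {}
        for name, path in config.variant_tables.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"variant table not found: {path}")
            records, rejects = parse_variant_table(path, config.column_map)
            catalogs[name] = records
            log.log("catalog.parse", dataset=name, path=str(path),
                    accepted=len(records), rejected=len(rejects))
        ddg_records = None
    else:
        spec = config.catalog_spec or dataclasses.replace(
            DEFAULT_CATALOG_SPEC, seed=config.seed
        )
        catalogs, ddg_records = simulate_catalogs(spec)
        log.log("catalog.simulate", seed=spec.seed,
                sizes={k: len(v) for k, v in catalogs.items()})
    return catalogs, ddg_records


def _ddg_stage(config: RunConfig, simulated_ddg, log: _StageLog):
    if config.ddg_files:
        records = []
        for path in config.ddg_files:
            if not Path(path).exists():
                raise FileNotFoundError(f"ddG file not found: {path}")
            recs = cmp.parse_foldx_dif(path)
            records.extend(recs)
            log.log("ddg.parse", path=str(path), records=len(recs))
        return records
    if simulated_ddg is None:
        raise ValueError("no ddG inputs: supply ddg_files or simulate catalogs")
    log.log("ddg.simulated", records=len(simulated_ddg))
    return simulated_ddg


def _denaturation_stage(config: RunConfig, outdir: Path, log: _StageLog):
    from .simulate import CurveSpec, simulate_curve

    fits = {}
    for ci in config.curves:
        if ci.path is not None:
            if not Path(ci.path).exists():
                raise FileNotFoundError(f"curve file not found: {ci.path}")
            curve = sio.read_curve_csv(ci.path, sample_id=ci.sample_id)
        else:
            if ci.dg0 is None or ci.m_value is None:
                raise ValueError(
                    f"curve '{ci.sample_id}': need a path or (dg0, m_value)"
                )
            spec = CurveSpec(
                dg0=ci.dg0, m_value=ci.m_value, noise_sd=ci.noise_sd,
                seed=config.seed, sample_id=ci.sample_id or "sim",
                temperature_K=config.temperature_K,
                gas_constant=config.gas_constant,
            )
            curve = simulate_curve(spec)
            if ci.theta_folded is None:
                ci = dataclasses.replace(
                    ci, theta_folded=spec.theta_folded,
                    theta_unfolded=spec.theta_unfolded,
                )
        fit_config = FitConfig(
            theta_folded=ci.theta_folded,
            theta_unfolded=ci.theta_unfolded,
            alpha_min=config.alpha_min,
            alpha_max=config.alpha_max,
            temperature_K=config.temperature_K,
            gas_constant=config.gas_constant,
        )
        fit, audit = analyze_curve(curve, fit_config)
        fits[fit.sample_id] = fit
        sio.write_fit_json(fit, outdir / f"fit_{fit.sample_id}.json")
        sio.write_audit_tsv(audit, outdir / f"audit_{fit.sample_id}.tsv")
        log.log("denature.fit", sample=fit.sample_id,
                n_points=fit.n_points_used, dg0=fit.dg0, m=fit.m_value)
    deltas = {}
    if config.wt_sample_id and config.wt_sample_id in fits:
        wt = fits[config.wt_sample_id]
        for sid, fit in fits.items():
            if sid == config.wt_sample_id:
                continue
            d = ddg_relative(fit, wt)
            deltas[sid] = d
            log.log("denature.ddg", sample=sid, ddg=d.ddg_experimental)
    return fits, deltas


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes.

    Any stage error is re-raised as :class:`StageError` carrying the stage
    name; partial outputs and the stage log up to the failure are kept.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(outdir / "stages.jsonl")
    summary: dict = {"seed": config.seed}
    try:
        try:
            catalogs, simulated_ddg = _catalog_stage(config, log)
        except Exception as exc:
            raise StageError("catalog", exc) from exc

        flat = [rec for records in catalogs.values() for rec in records]
        unique = {rec.key: rec for rec in flat}
        stats_df = domain_stats(list(unique.values()), DEFAULT_DOMAIN_MAP)
        stats_df.to_csv(outdir / "domain_stats.tsv", sep="\t", index=False)
        summary["domain_stats"] = stats_df.to_dict(orient="records")
        log.log("catalog.stats", domains=len(stats_df),
                unique_variants=len(unique))

        if len(catalogs) == 3:
            venn = dataset_overlap(catalogs)
            venn_json = {"+".join(k): v for k, v in venn.items()}
            summary["venn"] = venn_json
            with open(outdir / "venn.json", "w", encoding="utf-8") as fh:
                json.dump(venn_json, fh, indent=2, sort_keys=True)
            log.log("catalog.venn", union=sum(venn.values()))

        try:
            ddg_records = _ddg_stage(config, simulated_ddg, log)
        except Exception as exc:
            raise StageError("ddg", exc) from exc

        joined, accounting = cmp.join_ddg(list(unique.values()), ddg_records)
        joined.to_csv(outdir / "joined_ddg.tsv", sep="\t", index=False)
        summary["join_accounting"] = accounting
        log.log("join", **accounting)

        comparisons = []
        for contrast in config.contrasts:
            try:
                gc = cmp.compare_by_column(
                    joined, contrast["column"], contrast["a"], contrast["b"],
                    method=config.test_method,
                )
            except Exception as exc:
                raise StageError("compare", exc) from exc
            comparisons.append(dataclasses.asdict(gc))
            log.log("compare", a=gc.group_a, b=gc.group_b,
                    p=gc.p_value, stat=gc.test_statistic)
        summary["comparisons"] = comparisons

        try:
            fits, deltas = _denaturation_stage(config, outdir, log)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("denature", exc) from exc
        summary["fits"] = {
            sid: dataclasses.asdict(fit) for sid, fit in fits.items()
        }
        summary["ddg_experimental"] = {
            sid: d.ddg_experimental for sid, d in deltas.items()
        }
    finally:
        log.flush()

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_report(summary, outdir / "report.txt")
    return summary


def _write_report(summary: dict, path: Path):
    lines = ["stabscan run report", "=" * 19, ""]
    if "domain_stats" in summary:
        lines.append("Per-domain mutation statistics:")
        for row in summary["domain_stats"]:
            lines.append(
                f"  {row['domain']:>6}: {row['residues_mutated']}/"
                f"{row['residues_total']} residues mutated "
                f"({100 * row['fraction_mutated']:.0f}%), "
                f"{row['variant_count']} variants"
            )
        lines.append("")
    if "comparisons" in summary:
        lines.append("Group comparisons (predicted ddG):")
        for c in summary["comparisons"]:
            lines.append(
                f"  {c['group_a']} (n={c['n_a']}, mean {c['mean_a']:.2f}) vs "
                f"{c['group_b']} (n={c['n_b']}, mean {c['mean_b']:.2f}): "
                f"{c['test_name']} stat={c['test_statistic']:.2f} "
                f"p={c['p_value']:.2g}"
            )
        lines.append("")
    if summary.get("fits"):
        lines.append("Two-state denaturation fits:")
        for sid, f in summary["fits"].items():
            lines.append(
                f"  {sid:>8}: dG0 = {f['dg0']:.2f} +/- {f['dg0_se']:.2f} "
                f"kcal/mol, m = {f['m_value']:.2f} +/- {f['m_se']:.2f}, "
                f"C1/2 = {f['c_half']:.2f} M (n={f['n_points_used']}, "
                f"r2={f['r_squared']:.4f})"
            )
        for sid, ddg in summary.get("ddg_experimental", {}).items():
            lines.append(f"  ddG({sid} - WT) = {ddg:.2f} kcal/mol")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
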