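"""End-to-end orchestration: configuration, manifests, stage running, reports.

A YAML configuration names the stages to run and their inputs; each run
writes tab-delimited result tables, JSON summaries, and a manifest with
input digests, the config snapshot, seeds and per-stage row counts, so a
rerun with identical inputs is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import expression as expr
from . import gwas, simulate, variants

logger = logging.getLogger(__name__)

# exit-code contract
EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_STATS = 4


class ConfigError(ValueError):
    exit_code = EXIT_CONFIG


class DataFormatError(ValueError):
    exit_code = EXIT_DATA


class StatsPreconditionError(ValueError):
    exit_code = EXIT_STATS


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, round_to: int | None = None):
    if round_to is not None:
        df = df.round(round_to)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_dimorphism(cfg: dict, out: Path, manifest: dict) -> None:
    summary_path = Path(cfg["summary"])
    if not summary_path.exists():
        raise DataFormatError(f"summary-statistics file not found: {summary_path}")
    column_map = cfg.get("column_map")
    if column_map is None:
        raise ConfigError("dimorphism stage requires a column_map")
    records = gwas.read_summary_stats(summary_path, column_map)
    skipped = gwas.read_summary_stats.last_skipped

    if "regions_file" in cfg:
        regions = gwas.read_regions(cfg["regions_file"])
    elif "regions" in cfg:
        regions = [
            gwas.GeneRegion(r["name"], str(r["chrom"]), int(r["start"]),
                            int(r["end"]), flank=int(r.get("flank", gwas.DEFAULT_FLANK)))
            for r in cfg["regions"]
        ]
    else:
        regions = list(gwas.DEFAULT_REGIONS)

    z_thr = float(cfg.get("z_threshold", gwas.DIMORPHISM_Z))
    p_thr = float(cfg.get("gwas_threshold", gwas.GENOME_WIDE_P))
    summaries = []
    frames = []
    analyzed = 0
    for region in regions:
        results = gwas.analyze_region(
            records, region, z_threshold=z_thr, gwas_threshold=p_thr,
            force_unharmonized=bool(cfg.get("force_unharmonized", False)),
        )
        analyzed += len(results)
        frame = gwas.results_to_frame(results)
        frame.insert(0, "region", region.name)
        frames.append(frame)
        summaries.append(gwas.region_summary(results, region))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames else gwas.results_to_frame([])
    )
    _write_table(table, out / "dimorphism.tsv")
    (out / "dimorphism_summary.json").write_text(
        json.dumps(summaries, indent=2) + "\n"
    )
    manifest["stages"]["dimorphism"] = {
        "rows_read": len(records) + skipped,
        "rows_skipped": skipped,
        "rows_analyzed": analyzed,
    }


def _stage_assoc(cfg: dict, out: Path, manifest: dict) -> None:
    counts_path = Path(cfg["counts"])
    if not counts_path.exists():
        raise DataFormatError(f"counts file not found: {counts_path}")
    counts = variants.read_genotype_counts(counts_path)
    cases_label = cfg.get("cases", "cases")
    controls_label = cfg.get("controls", "controls")
    test = cfg.get("test", "auto")
    rows = []
    variants_seen = sorted({v for v, _ in counts})
    for var in variants_seen:
        case = counts.get((var, cases_label))
        ctrl = counts.get((var, controls_label))
        if case is None or ctrl is None:
            logger.warning("variant %s lacks one group; skipped", var)
            continue
        try:
            res = variants.associate(case, ctrl, test=test)
            hwe_p = variants.hwe_exact(ctrl)
        except ValueError as exc:
            raise StatsPreconditionError(str(exc)) from exc
        rows.append(
            {
                "variant": var,
                "method": res.method,
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p_two_sided,
                "case_freq": res.case_freq,
                "control_freq": res.control_freq,
                "case_maf": variants.maf(case),
                "control_maf": variants.maf(ctrl),
                "hwe_p_controls": hwe_p,
            }
        )
    _write_table(pd.DataFrame(rows), out / "association.tsv")
    manifest["stages"]["assoc"] = {"variants_tested": len(rows)}


def _stage_tdt(cfg: dict, out: Path, manifest: dict) -> None:
    excluded = 0
    if "trios" in cfg:
        trios_path = Path(cfg["trios"])
        if not trios_path.exists():
            raise DataFormatError(f"trio file not found: {trios_path}")
        triples = variants.read_trio_genotypes(trios_path)
        counts, excluded = variants.count_transmissions(triples)
    else:
        try:
            counts = variants.TrioCounts(int(cfg["b"]), int(cfg["c"]))
        except KeyError as exc:
            raise ConfigError("tdt stage needs either 'trios' or 'b'/'c'") from exc
    try:
        res = variants.tdt(counts)
    except ValueError as exc:
        raise StatsPreconditionError(str(exc)) from exc
    payload = dataclasses.asdict(res)
    payload["mendelian_errors_excluded"] = excluded
    (out / "tdt.json").write_text(json.dumps(payload, indent=2) + "\n")
    manifest["stages"]["tdt"] = {
        "informative_transmissions": counts.informative,
        "mendelian_errors_excluded": excluded,
    }


def _stage_corr(cfg: dict, out: Path, manifest: dict) -> None:
    for key in ("expr", "meta"):
        if key not in cfg:
            raise ConfigError(f"corr stage requires '{key}'")
        if not Path(cfg[key]).exists():
            raise DataFormatError(f"file not found: {cfg[key]}")
    values = pd.read_csv(cfg["expr"], sep=None, engine="python", index_col=0)
    meta = pd.read_csv(cfg["meta"], sep=None, engine="python", index_col=0)
    dataset = expr.ExpressionDataset(values, meta)
    if cfg.get("adjust_covariates", False):
        dataset = expr.ExpressionDataset(
            expr.adjust_covariates(dataset.values, dataset.sample_meta),
            dataset.sample_meta,
        )
    genes = cfg.get("genes") or dataset.genes
    phenotypes = cfg.get("phenotypes") or [
        c for c in expr.PHENOTYPE_COLUMNS if c in meta.columns
    ]
    frames = []
    for depot in cfg.get("depots", ["VAT", "SAT"]):
        try:
            results = expr.correlation_screen(
                dataset, genes, phenotypes, depot=depot,
                max_age=cfg.get("max_age"),
            )
        except ValueError as exc:
            raise StatsPreconditionError(str(exc)) from exc
        frame = expr.correlations_to_frame(results)
        frame.insert(0, "depot", depot)
        frames.append(frame)
    _write_table(pd.concat(frames, ignore_index=True), out / "correlations.tsv")
    manifest["stages"]["corr"] = {
        "pairs": int(sum(len(f) for f in frames)),
    }


def _stage_compare(cfg: dict, out: Path, manifest: dict) -> None:
    for key in ("expr", "meta"):
        if key not in cfg:
            raise ConfigError(f"compare stage requires '{key}'")
        if not Path(cfg[key]).exists():
            raise DataFormatError(f"file not found: {cfg[key]}")
    values = pd.read_csv(cfg["expr"], sep=None, engine="python", index_col=0)
    meta = pd.read_csv(cfg["meta"], sep=None, engine="python", index_col=0)
    dataset = expr.ExpressionDataset(values, meta)
    strata = cfg.get("strata", ["depot", "group"])
    labels = meta[strata].astype(str).agg("|".join, axis=1)
    rows = []
    pairwise_rows = []
    for gene in cfg.get("genes") or dataset.genes:
        try:
            res = expr.kruskal_dunn(dataset.values.loc[gene], labels)
        except ValueError as exc:
            raise StatsPreconditionError(str(exc)) from exc
        rows.append(
            {
                "gene": gene,
                "H": res.h_statistic,
                "df": res.df,
                "p": res.p_value,
                "epsilon_squared": res.epsilon_squared,
            }
        )
        for pw in res.pairwise:
            pairwise_rows.append(
                {
                    "gene": gene, "group_a": pw.group_a, "group_b": pw.group_b,
                    "z": pw.z, "p_raw": pw.p_raw, "p_adj": pw.p_adj,
                }
            )
    _write_table(pd.DataFrame(rows), out / "comparison.tsv")
    _write_table(pd.DataFrame(pairwise_rows), out / "comparison_pairwise.tsv")
    manifest["stages"]["compare"] = {"genes_compared": len(rows)}


def _stage_simulate(cfg: dict, out: Path, manifest: dict, seed: int | None) -> None:
    kind = cfg.get("kind")
    if kind not in ("summary", "trios", "casecontrol", "expression"):
        raise ConfigError(f"unknown simulate kind: {kind!r}")
    params = dict(cfg.get("params", {}))
    if seed is not None:
        params.setdefault("seed", seed)
    try:
        sim_cfg = simulate.SimulationConfig(**params)
    except TypeError as exc:
        raise ConfigError(f"bad simulation parameter: {exc}") from exc
    paths = simulate.write_outputs(kind, sim_cfg, out)
    manifest["stages"][f"simulate:{kind}"] = {"outputs": paths}


_STAGES = {
    "dimorphism": _stage_dimorphism,
    "assoc": _stage_assoc,
    "tdt": _stage_tdt,
    "corr": _stage_corr,
    "compare": _stage_compare,
}


def run_pipeline(config_path, out_dir, seed: int | None = None) -> Path:
    """Run the configured stages in order; write tables, summaries, manifest.

    The manifest records input digests, the config snapshot, the seed, the
    package version and per-stage row counts. Failures abort with the
    typed error whose ``exit_code`` the CLI propagates; the manifest is
    still written to record partial progress.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ConfigError(f"config file not found: {config_path}")
    try:
        config = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse: {exc}") from exc
    if not isinstance(config, dict) or "stages" not in config:
        raise ConfigError("config must be a mapping with a 'stages' list")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_digest": _digest(config_path),
        "input_digests": {},
        "stages": {},
        "status": "running",
    }

    try:
        for stage_cfg in config["stages"]:
            stage_cfg = dict(stage_cfg)
            name = stage_cfg.pop("stage", None)
            if name is None:
                raise ConfigError("every stage entry needs a 'stage' key")
            for key in ("summary", "counts", "trios", "expr", "meta",
                        "regions_file"):
                if key in stage_cfg and Path(str(stage_cfg[key])).exists():
                    manifest["input_digests"][str(stage_cfg[key])] = _digest(
                        Path(str(stage_cfg[key]))
                    )
            if name == "simulate":
                _stage_simulate(stage_cfg, out, manifest, seed)
            elif name in _STAGES:
                _STAGES[name](stage_cfg, out, manifest)
            else:
                raise ConfigError(f"unknown stage name: {name!r}")
        manifest["status"] = "ok"
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _stars(p_adj: float | None) -> str:
    if p_adj is None:
        return ""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def report(results_dir) -> str:
    """Human-readable markdown summary of a results directory."""
    out = Path(results_dir)
    if not out.exists() or not any(out.iterdir()):
        raise DataFormatError(f"no results found in {out}")
    lines = ["# Analysis report", ""]

    summary_json = out / "dimorphism_summary.json"
    if summary_json.exists():
        lines.append("## Sex-dimorphism screen")
        for s in json.loads(summary_json.read_text()):
            lines.append(
                f"- {s['region']} (chr{s['chrom']}:{s['region_start']:,}-"
                f"{s['region_end']:,}): core {s['core']['n_dimorphic']}/"
                f"{s['core']['n_snps']} dimorphic "
                f"({s['core']['pct_dimorphic']:.2f}%), flank "
                f"{s['flank']['n_dimorphic']}/{s['flank']['n_snps']} "
                f"({s['flank']['pct_dimorphic']:.2f}%)"
            )
        lines.append("")

    assoc_tsv = out / "association.tsv"
    if assoc_tsv.exists():
        lines.append("## Case-control association")
        df = pd.read_csv(assoc_tsv, sep="\t")
        if df.empty:
            lines.append("no variants")
        else:
            for _, r in df.iterrows():
                lines.append(
                    f"- {r['variant']}: p = {r['p']:.2g} ({r['method']}), "
                    f"case MAF {r['case_maf']:.3g}, "
                    f"control MAF {r['control_maf']:.3g}"
                )
        lines.append("")

    tdt_json = out / "tdt.json"
    if tdt_json.exists():
        t = json.loads(tdt_json.read_text())
        lines.append("## Transmission disequilibrium test")
        lines.append(
            f"- b = {t['b']}, c = {t['c']}: transmission rate "
            f"{100 * t['transmission_rate']:.0f}%, chi2 = {t['chi2']:.2f}, "
            f"p = {t['p_chi2']:.2f} (exact binomial p = {t['p_binomial']:.2f})"
        )
        lines.append("")

    corr_tsv = out / "correlations.tsv"
    if corr_tsv.exists():
        lines.append("## Expression correlations")
        df = pd.read_csv(corr_tsv, sep="\t")
        if df.empty:
            lines.append("no correlations")
        else:
            for _, r in df.iterrows():
                lines.append(
                    f"- [{r['depot']}] {r['pair']}: rho = {r['rho']:.2f} "
                    f"(n = {r['n']}, p_adj = {r['p_adj']:.2g}) "
                    f"{_stars(r['p_adj'])}"
                )
        lines.append("")

    cmp_tsv = out / "comparison.tsv"
    if cmp_tsv.exists():
        lines.append("## Group comparisons (Kruskal-Wallis + Dunn)")
        df = pd.read_csv(cmp_tsv, sep="\t")
        if df.empty:
            lines.append("no variants")
        else:
            for _, r in df.iterrows():
                lines.append(
                    f"- {r['gene']}: H = {r['H']:.2f}, p = {r['p']:.2g}, "
                    f"epsilon^2 = {r['epsilon_squared']:.3f}"
                )
        lines.append("")
    return "\n".join(lines)
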