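"""End-to-end orchestration: simulate a scenario, run every analysis stage,
write fixed-format reports.

Stage outputs are plain TSV / BED / bedGraph / FASTA under one output
directory, plus a JSON manifest recording the seed, thresholds (flagging
which were overridden from the study defaults) and files written, and a
human-readable summary.  Given the same config and seed, analysis outputs
are byte-identical across runs.
"""
from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .allelic import (classify_allelic_state, filter_expressed_allelic,
                      pscore_table, select_switched_genes, switch_results_frame)
from .colony import (call_clone, clone_set_methylation, clones_frame,
                     deduplicate_clones, render_lollipop_matrix, AmpliconReference)
from .core import GENOTYPES, SEXES
from .expression import (compute_tpm, differential_frame, differential_genes,
                         filter_quantifiable)
from .io import write_fasta, write_icr_bed, write_tsv
from .methylation import (compare_icr_groups, export_methylation_track,
                          icr_methylation_by_sample, site_methylation_table)
from .presets import demo_scenario
from .scenario import Scenario, load_scenario
from .synthetic import (simulate_allelic_counts, simulate_colony_reads,
                        simulate_cross, simulate_wgbs_calls)

logger = logging.getLogger("imprintkit")

STAGES = ("simulate", "pscore", "expression", "methylation", "colony")

#: The study's analysis thresholds (defaults for every run).
DEFAULT_THRESHOLDS = {
    "delta_pscore": 0.1,
    "alpha": 0.05,
    "fc_threshold": 0.5,
    "fc_threshold_sex": 0.3,
    "min_reads": 10,
    "min_tpm": 1.0,
    "min_site_reads": 3,
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    scenario: Scenario
    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    scenario_source: str = "<python>"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        th = self.thresholds
        for key, default in DEFAULT_THRESHOLDS.items():
            th.setdefault(key, default)
        if not 0 < th["alpha"] < 1:
            raise ValueError(f"alpha must be in (0,1), got {th['alpha']}")
        for key in ("delta_pscore", "fc_threshold", "fc_threshold_sex",
                    "min_reads", "min_tpm", "min_site_reads"):
            if th[key] <= 0:
                raise ValueError(f"threshold {key} must be positive, got {th[key]}")


def load_run_config(path: str | Path, seed: int | None = None,
                    out_dir: str | Path | None = None) -> RunConfig:
    """Read a run config TOML (``[run]`` + optional ``[thresholds]``).

    ``run.scenario`` is either the preset name ``"demo"`` or a path to a
    scenario TOML (relative paths resolve against the config file).
    """
    path = Path(path)
    doc = tomllib.loads(path.read_text())
    run = doc.get("run", {})
    scen_ref = run.get("scenario", "demo")
    cfg_seed = int(run.get("seed", 0)) if seed is None else int(seed)
    if scen_ref == "demo":
        scenario = demo_scenario(seed=cfg_seed)
    else:
        scen_path = Path(scen_ref)
        if not scen_path.is_absolute():
            scen_path = path.parent / scen_path
        scenario = load_scenario(scen_path)
    out = Path(out_dir) if out_dir is not None else Path(run.get("out", "imprintkit_out"))
    stages = tuple(run.get("stages", list(STAGES)))
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(doc.get("thresholds", {}))
    return RunConfig(scenario=scenario, out_dir=out, seed=cfg_seed,
                     stages=stages, thresholds=thresholds,
                     scenario_source=str(scen_ref))


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    """Round float columns for byte-stable TSV output."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(10)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages and return the manifest dictionary.

    Stage order is fixed: simulate -> pscore -> expression -> methylation
    -> colony.  Analysis stages require the simulate outputs of the same
    run; a stage missing its input fails with a named error, leaving any
    outputs already written in place alongside a failure marker in the
    manifest.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    scenario = config.scenario
    seed = config.seed
    manifest: dict = {
        "tool": "imprintkit",
        "version": __version__,
        "seed": seed,
        "scenario": config.scenario_source,
        "stages": list(config.stages),
        "thresholds": th,
        "threshold_overrides": sorted(
            k for k, v in th.items() if DEFAULT_THRESHOLDS.get(k) != v
        ),
        "outputs": [],
        "status": "running",
    }
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)

    state: dict = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        logger.info("wrote %s", path)

    try:
        if "simulate" in config.stages:
            samples = simulate_cross(scenario.design)
            state["samples"] = samples
            emit("samples.tsv", lambda p: write_tsv(samples, p))
            if scenario.genes:
                counts = simulate_allelic_counts(scenario.genes, samples, seed)
                state["counts"] = counts
                emit("counts.tsv", lambda p: write_tsv(counts, p))
                lengths = pd.DataFrame({
                    "gene": [g.gene_id for g in scenario.genes],
                    "length_bp": [g.gene_length for g in scenario.genes],
                })
                state["lengths"] = lengths
                emit("lengths.tsv", lambda p: write_tsv(lengths, p))
            if scenario.icrs:
                calls = pd.concat(
                    [simulate_wgbs_calls(ic, samples, seed) for ic in scenario.icrs],
                    ignore_index=True,
                )
                state["calls"] = calls
                emit("calls.tsv", lambda p: write_tsv(calls, p))
                regions = [ic.icr for ic in scenario.icrs]
                state["icrs"] = regions
                emit("icrs.bed", lambda p: write_icr_bed(regions, p))
            for amp in scenario.amplicons:
                reads = simulate_colony_reads(amp, seed)
                state.setdefault("colony_reads", {})[amp.name] = reads
                emit(f"colonies_{amp.name}.fa", lambda p, r=reads: write_fasta(r, p))

        if "pscore" in config.stages:
            _require(state, "counts", "pscore")
            filtered = filter_expressed_allelic(state["counts"], th["min_reads"])
            scores = pscore_table(filtered)
            emit("pscores.tsv", lambda p: write_tsv(_float_fmt(scores), p))
            samples = state["samples"]
            all_results = []
            geno_of = dict(zip(samples["sample"], samples["genotype"]))
            sex_of = dict(zip(samples["sample"], samples["sex"]))
            for sex in SEXES:
                if not set(GENOTYPES) <= set(
                        samples.loc[samples["sex"] == sex, "genotype"]):
                    continue
                results, heat, intensity = select_switched_genes(
                    scores, samples, sex, ("M+Z+", "M-Z-"),
                    delta_threshold=th["delta_pscore"], alpha=th["alpha"])
                states = {}
                valid = scores.dropna(subset=["pscore"])
                for genotype in GENOTYPES:
                    group_samples = [s for s in samples["sample"]
                                     if geno_of[s] == genotype and sex_of[s] == sex]
                    sub = valid[valid["sample"].isin(group_samples)]
                    states[f"{sex}:{genotype}"] = {
                        gene: classify_allelic_state(g["pscore"])
                        for gene, g in sub.groupby("gene")
                    }
                all_results.append(switch_results_frame(results, states))
                emit(f"pscore_heatmap_{sex}.tsv",
                     lambda p, h=heat: write_tsv(_float_fmt(h.reset_index()), p))
                emit(f"pscore_intensity_diff_{sex}.tsv",
                     lambda p, h=intensity: write_tsv(_float_fmt(h.reset_index()), p))
            if all_results:
                switch_df = pd.concat(all_results, ignore_index=True)
                state["switches"] = switch_df
                emit("switch_results.tsv",
                     lambda p: write_tsv(_float_fmt(switch_df), p))

        if "expression" in config.stages:
            _require(state, "counts", "expression")
            counts = state["counts"].rename(columns={"total_count": "count"})
            tpm = compute_tpm(counts[["gene", "sample", "count"]], state["lengths"])
            tpm = filter_quantifiable(tpm, th["min_reads"], th["min_tpm"])
            emit("tpm.tsv", lambda p: write_tsv(_float_fmt(tpm), p))
            samples = state["samples"]
            diff_frames = []
            for sex in SEXES:
                sub = samples[samples["sex"] == sex]
                ga = list(sub.loc[sub["genotype"] == "M-Z-", "sample"])
                gb = list(sub.loc[sub["genotype"] == "M+Z+", "sample"])
                if len(ga) < 2 or len(gb) < 2:
                    continue
                results, matrix = differential_genes(
                    tpm, samples, ga, gb, comparison=f"{sex}:M-Z- vs M+Z+",
                    fc_threshold=th["fc_threshold"], alpha=th["alpha"])
                diff_frames.append(differential_frame(results))
                emit(f"expression_heatmap_{sex}.tsv",
                     lambda p, m=matrix: write_tsv(_float_fmt(m.reset_index()), p))
            if diff_frames:
                diff_df = pd.concat(diff_frames, ignore_index=True)
                state["differential"] = diff_df
                emit("differential.tsv", lambda p: write_tsv(_float_fmt(diff_df), p))

        if "methylation" in config.stages:
            _require(state, "calls", "methylation")
            calls = state["calls"]
            percents = icr_methylation_by_sample(
                calls, state["icrs"], min_reads=th["min_site_reads"])
            state["icr_percents"] = percents
            emit("icr_methylation.tsv", lambda p: write_tsv(_float_fmt(percents), p))
            samples = state["samples"]
            sizes = samples.groupby(["genotype", "sex"]).size()
            if (len(sizes) == len(GENOTYPES) * len(SEXES)) and (sizes >= 2).all():
                comparisons = compare_icr_groups(percents, samples,
                                                 alpha=th["alpha"])
                state["icr_comparisons"] = comparisons
                emit("icr_comparisons.tsv",
                     lambda p: write_tsv(_float_fmt(comparisons), p))
            levels = site_methylation_table(calls, min_reads=th["min_site_reads"])
            for sample in samples["sample"]:
                track = export_methylation_track(levels, sample)
                emit(f"methylation_{sample}.bedGraph",
                     lambda p, t=track: Path(p).write_text(t))

        if "colony" in config.stages:
            _require(state, "colony_reads", "colony")
            rows = []
            for amp in scenario.amplicons:
                ref = AmpliconReference(name=amp.name,
                                        sequence=amp.amplicon_sequence,
                                        cpg_indices=list(amp.cpg_indices),
                                        non_cpg_c_indices=list(amp.non_cpg_c_indices))
                reads = state["colony_reads"][amp.name]
                clones = [call_clone(rid, seq, ref) for rid, seq in reads]
                unique = deduplicate_clones(clones)
                emit(f"clones_{amp.name}.tsv",
                     lambda p, c=clones: write_tsv(_float_fmt(clones_frame(c)), p))
                emit(f"lollipop_{amp.name}.tsv",
                     lambda p, u=unique: write_tsv(render_lollipop_matrix(u), p))
                rows.append({
                    "amplicon": amp.name,
                    "n_reads": len(reads),
                    "n_unique_clones": len(unique),
                    "percent_methylated": (clone_set_methylation(unique)
                                           if unique else float("nan")),
                })
            colony_df = pd.DataFrame(rows)
            state["colony_summary"] = colony_df
            emit("colony_methylation.tsv",
                 lambda p: write_tsv(_float_fmt(colony_df), p))

        summary = summarize_run(state, th)
        (out / "summary.txt").write_text(summary)
        manifest["outputs"].append("summary.txt")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(manifest, out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    _write_manifest(manifest, out)
    return manifest


def _require(state: dict, key: str, stage: str) -> None:
    if key not in state:
        raise RuntimeError(
            f"stage '{stage}' needs '{key}' from the simulate stage; "
            "run with the simulate stage enabled"
        )


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")


def summarize_run(state: dict, thresholds: dict) -> str:
    """Human-readable run summary: ICR percentages by group, switched and
    differential gene lists, colony methylation.  Stable ordering."""
    lines: list[str] = ["imprintkit run summary", "=" * 30]
    lines.append("thresholds: " + ", ".join(
        f"{k}={v}" for k, v in sorted(thresholds.items())))

    if "icr_percents" in state and "samples" in state:
        lines.append("")
        lines.append("ICR methylation (% mean per genotype x sex):")
        merged = state["icr_percents"].merge(state["samples"], on="sample")
        table = (merged.groupby(["icr", "genotype", "sex"])["percent"]
                       .mean().reset_index())
        for icr in sorted(table["icr"].unique()):
            sub = table[table["icr"] == icr]
            parts = []
            for genotype in GENOTYPES:
                for sex in SEXES:
                    row = sub[(sub["genotype"] == genotype) & (sub["sex"] == sex)]
                    if not row.empty and pd.notna(row["percent"].iloc[0]):
                        parts.append(f"{genotype}/{sex}={row['percent'].iloc[0]:.1f}")
                    else:
                        parts.append(f"{genotype}/{sex}=no-data")
            lines.append(f"  {icr}: " + "  ".join(parts))

    if "switches" in state:
        lines.append("")
        sel = state["switches"].query("selected").sort_values(["comparison", "gene"])
        if sel.empty:
            lines.append("switched genes: none selected")
        else:
            lines.append("switched genes (delta-P >= "
                         f"{thresholds['delta_pscore']}, p < {thresholds['alpha']}):")
            for row in sel.itertuples(index=False):
                lines.append(
                    f"  {row.gene} [{row.comparison}] dP={row.delta_pscore:.3f} "
                    f"p={row.p_value:.3g}"
                )

    if "differential" in state:
        lines.append("")
        sig = state["differential"].query("significant") \
                                   .sort_values(["comparison", "gene"])
        if sig.empty:
            lines.append("differential genes: none selected")
        else:
            lines.append("differential genes (|log2FC| > "
                         f"{thresholds['fc_threshold']}, p < {thresholds['alpha']}):")
            for row in sig.itertuples(index=False):
                lines.append(
                    f"  {row.gene} [{row.comparison}] log2FC={row.log2fc:.3f} "
                    f"p={row.p_value:.3g}"
                )

    if "colony_summary" in state:
        lines.append("")
        lines.append("colony bisulfite methylation:")
        for row in state["colony_summary"].sort_values("amplicon") \
                                          .itertuples(index=False):
            lines.append(
                f"  {row.amplicon}: {row.percent_methylated:.1f}% methylated "
                f"({row.n_unique_clones} unique clones from {row.n_reads} reads)"
            )
    return "\n".join(lines) + "\n"
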