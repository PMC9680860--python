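"""End-to-end orchestration: VCF in, structured report bundle out.

``run_all`` chains the stages — biallelic/complete filtering, diagnostic
site extraction, focal classification, backcross model comparison,
ancestry painting, optional diversity/F_ST, and IUPAC alignment export —
and writes every result as a machine-readable file plus a human-readable
summary.  Each numeric in the summary is traceable to one of the bundle
files; a MANIFEST records the configuration, the stages completed and
any incompleteness, so two runs with equal config and seed produce
byte-identical reports apart from the MANIFEST timestamp field.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from hybridtrace import backcross, diagnostic, painting, popgen, variants_io
from hybridtrace.errors import ConfigurationError, HybridtraceError


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    vcf: str
    panel_config: str
    focal: str
    panelA: str = "parentA"
    panelB: str = "parentB"
    out_dir: str = "hybridtrace_out"
    generations: tuple = (1, 2, 3)
    p_error: "float | None" = None  #: default: plug-in aa-fraction estimate
    window: int = 101
    min_sites: int = 10
    l_bar: "dict[str, float] | None" = None  #: panel -> average mapped sites
    bootstrap_reps: int = 0
    seed: int = 0
    anchored: "list[str] | None" = None


class StageError(HybridtraceError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict of output paths and headline numbers.  On stage
    failure, partial outputs are retained and the MANIFEST notes which
    stage was incomplete before the error propagates as
    :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages_completed": [],
        "complete": False,
    }
    results: dict = {"out_dir": str(out)}

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    stage = "load"
    try:
        panel_map = variants_io.read_panel_config(config.panel_config)
        matrix = variants_io.read_vcf(config.vcf, panel_map)
        for required in (config.panelA, config.panelB):
            if required not in matrix.panels:
                raise ConfigurationError(f"panel {required!r} missing from panel config")
        focal_found = any(
            config.focal in p.sample_ids for p in matrix.panels.values()
        ) or config.focal in matrix.samples
        if not focal_found:
            raise ConfigurationError(f"focal sample {config.focal!r} not in VCF")
        finish_stage(stage)

        stage = "filter"
        core_samples = (
            list(matrix.panels[config.panelA].sample_ids)
            + list(matrix.panels[config.panelB].sample_ids)
            + [config.focal]
        )
        filtered = variants_io.filter_biallelic_complete(matrix, core_samples)
        results["n_sites_filtered"] = filtered.n_sites
        finish_stage(stage)

        stage = "diagnostic"
        siteset = diagnostic.find_discriminatory_sites(
            filtered, config.panelA, config.panelB
        )
        siteset.table[["chrom", "pos", "allele_A", "allele_a"]].to_csv(
            out / "diagnostic_sites.tsv", sep="\t", index=False
        )
        results["n_diagnostic_sites"] = len(siteset)
        finish_stage(stage)

        stage = "classify"
        classes, table = diagnostic.classify_focal_genotypes(
            siteset, filtered, config.focal, anchored=config.anchored
        )
        classes.to_csv(out / "classes.tsv", sep="\t", index=False)
        table.table.to_csv(out / "class_table.tsv", sep="\t")
        diagnostic.per_chromosome_summary(classes).to_csv(
            out / "per_chromosome_heterozygosity.tsv", sep="\t", index=False
        )
        counts = table.counts
        results["counts"] = counts
        finish_stage(stage)

        stage = "fit-backcross"
        comparison = backcross.compare_models(
            counts,
            generations=config.generations,
            p_error=config.p_error,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        with open(out / "model_comparison.json", "w") as fh:
            json.dump(comparison.as_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        results["best_model"] = comparison.best.name
        results["delta_lnL"] = comparison.delta_lnL
        finish_stage(stage)

        stage = "paint"
        tracks = [
            painting.smooth_track(t, window=config.window, min_sites=config.min_sites)
            for t in painting.paint_chromosomes(classes)
        ]
        (out / "segments.bed").write_text(painting.segments_to_bed(tracks))
        seg_counts = painting.count_segments(tracks)
        seg_counts.to_csv(out / "segment_counts.tsv", sep="\t", index=False)
        results["segment_summary"] = seg_counts.attrs["summary"]
        finish_stage(stage)

        stage = "popgen"
        popgen_out: dict = {}
        for pname in (config.panelA, config.panelB):
            panel = matrix.panels[pname]
            if len(panel.sample_ids) >= 2 and config.l_bar and pname in config.l_bar:
                sub = variants_io.filter_biallelic_complete(
                    matrix, list(panel.sample_ids)
                )
                div = popgen.nucleotide_diversity(sub, panel, config.l_bar[pname])
                popgen_out[f"theta_pi_{pname}"] = dataclasses.asdict(div)
        if (
            len(matrix.panels[config.panelA].sample_ids) >= 2
            and len(matrix.panels[config.panelB].sample_ids) >= 2
        ):
            both = list(matrix.panels[config.panelA].sample_ids) + list(
                matrix.panels[config.panelB].sample_ids
            )
            sub = variants_io.filter_biallelic_complete(matrix, both)
            fst = popgen.pairwise_fst(sub, config.panelA, config.panelB)
            popgen_out["fst"] = dataclasses.asdict(fst)
        if popgen_out:
            with open(out / "diversity_fst.json", "w") as fh:
                json.dump(popgen_out, fh, indent=1, sort_keys=True)
                fh.write("\n")
            results["popgen"] = popgen_out
        finish_stage(stage)

        stage = "alignment"
        fasta = variants_io.export_iupac_fasta(filtered)
        (out / "alignment.fasta").write_text(fasta)
        finish_stage(stage)

        stage = "summary"
        (out / "summary.txt").write_text(_summary_text(results, comparison, table))
        manifest["complete"] = True
        finish_stage(stage)
    except HybridtraceError:
        manifest["failed_stage"] = stage
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        raise StageError(stage, exc) from exc
    return results


def _summary_text(results, comparison, table) -> str:
    n_aa, n_het, n_bb = results["counts"]
    total = n_aa + n_het + n_bb
    lines = [
        "hybridtrace run summary",
        "=======================",
        f"filtered biallelic complete sites : {results['n_sites_filtered']}",
        f"diagnostic (fixed-opposite) sites : {results['n_diagnostic_sites']}",
        f"focal genotype classes            : "
        f"AA {n_aa} ({n_aa / total:.2%}), Aa {n_het} ({n_het / total:.2%}), "
        f"aa {n_bb} ({n_bb / total:.2%})  [class_table.tsv]",
        f"best backcross model              : {comparison.best.name} "
        f"(delta lnL vs {comparison.runner_up.name}: {comparison.delta_lnL:.2f}) "
        f"[model_comparison.json]",
        f"segments per chromosome           : {results['segment_summary']} "
        f"[segment_counts.tsv]",
    ]
    if "popgen" in results:
        lines.append(f"diversity / F_ST                  : see diversity_fst.json")
    return "\n".join(lines) + "\n"
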