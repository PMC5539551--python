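"""End-to-end orchestration: filter -> bin -> exclude -> screen -> summarise.

A run is configured by one YAML file naming the input tables, the control
sample, and the output directory, and produces a directory of deterministic
TSVs plus ``manifest.json`` recording the config hash, the seed, and
per-stage record counts (which must shrink monotonically: generated >=
filtered >= screened).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

from . import community
from .abundance_filter import filter_rare_otus
from .binning import apply_screen, assign_bins, compute_relative_abundance
from .errors import ConfigurationError
from .io_tables import (
    OtuTable,
    QuantConfig,
    SampleMetadata,
    ScreenConfig,
    TaxonomyMap,
    load_config,
    read_metadata,
    read_otu_table,
    read_taxonomy,
    write_metadata,
    write_otu_table,
    write_report,
    write_taxonomy,
)
from .quant import quantify_panel, read_qpcr_table, write_quant_results

log = logging.getLogger("crustscreen")

__all__ = ["run_pipeline", "screen_tables", "write_dataset"]


def screen_tables(
    table: OtuTable,
    config: ScreenConfig,
    metadata: Mapping[str, SampleMetadata] | None = None,
):
    """Filter + bin + screen an in-memory table; returns (result, report).

    When the table has no CONTROL-role sample the screen degrades to a
    pass-through and the result is flagged ``unscreened``.
    """
    filtered, report = filter_rare_otus(table, config)
    result = _bin_and_screen(filtered, table.control_id, metadata, config)
    return result, report


def _bin_and_screen(filtered: OtuTable, control_id, metadata, config: ScreenConfig):
    from .binning import BinAssignment

    if control_id is None:
        log.warning("no control sample designated: skipping binning (pass-through)")
        return apply_screen(filtered, None, metadata, config)
    if not filtered.otu_ids:
        return apply_screen(filtered, BinAssignment({}, {}, control_id), metadata, config)
    abund = compute_relative_abundance(filtered)
    bins = assign_bins(abund, control_id, config)
    return apply_screen(filtered, bins, metadata, config)


def run_pipeline(config_path: str | Path, seed: int | None = None) -> Path:
    """Execute a full screening run described by a YAML config file.

    Required config keys: ``otu_table``, ``out``; optional: ``taxonomy``,
    ``metadata``, ``qpcr``, ``control_id``, ``screening_enabled`` (default
    true), ``seed``, plus ``screen:`` / ``quant:`` parameter blocks.
    """
    config_path = Path(config_path)
    screen_cfg, quant_cfg, extras = load_config(config_path)
    stage = "configure"
    try:
        outdir = Path(extras["out"]) if "out" in extras else None
        if outdir is None:
            raise ConfigurationError("config must name an output directory ('out')")
        table_path = extras.get("otu_table")
        if table_path is None:
            raise ConfigurationError("config must name an input table ('otu_table')")
        screening = bool(extras.get("screening_enabled", True))
        control_id = extras.get("control_id")
        if screening and not control_id:
            raise ConfigurationError(
                "screening_enabled requires 'control_id' in the config"
            )
        seed = seed if seed is not None else int(extras.get("seed", 0))
        outdir.mkdir(parents=True, exist_ok=True)

        stage = "read"
        table = read_otu_table(table_path)
        if control_id:
            table = table.with_control(str(control_id))
        taxonomy = read_taxonomy(extras["taxonomy"]) if extras.get("taxonomy") else None
        metadata = read_metadata(extras["metadata"]) if extras.get("metadata") else None

        stage = "filter"
        filtered, filter_report = filter_rare_otus(table, screen_cfg)
        filter_report.to_tsv(outdir / "filter_report.tsv")

        stage = "screen"
        result = _bin_and_screen(
            filtered, str(control_id) if screening else None, metadata, screen_cfg
        )
        write_otu_table(result.screened, outdir / "screened_otu_table.tsv")

        stage = "summarize"
        comp = None
        if taxonomy is not None and result.screened.otu_ids:
            for rank in ("phylum", "class"):
                c = community.aggregate_by_rank(result.screened, taxonomy, rank)
                c.fractions.sort_index().to_csv(
                    outdir / f"composition_{rank}.tsv", sep="\t", float_format="%.6g"
                )
                c.counts.sort_index().to_csv(
                    outdir / f"composition_{rank}_counts.tsv", sep="\t"
                )
                if rank == "class":
                    comp = c
        write_report(result, outdir, comp)

        jac_input = (
            result.screened if screen_cfg.jaccard_input == "POST_SCREEN"
            else filtered.select_samples(filtered.noncontrol_ids)
        )
        if jac_input.sample_ids:
            community.jaccard_matrix(jac_input).to_csv(
                outdir / "jaccard.tsv", sep="\t", float_format="%.6g"
            )
            shared = community.shared_otu_matrix(jac_input)
            shared.index.name = "otu_id"
            shared.to_csv(outdir / "shared_otus.tsv", sep="\t")

        stage = "quantify"
        n_panels = 0
        if extras.get("qpcr"):
            panels = read_qpcr_table(extras["qpcr"], quant_cfg)
            results = [quantify_panel(p) for p in panels]
            write_quant_results(results, outdir / "quant_results.tsv")
            n_panels = len(panels)

        stage = "manifest"
        manifest = {
            "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
            "seed": seed,
            "screening_enabled": screening,
            "control_id": control_id,
            "stages": {
                "input_otus": len(table.otu_ids),
                "filtered_otus": len(filtered.otu_ids),
                "screened_otus": len(result.screened.otu_ids),
                "input_samples": len(table.noncontrol_ids),
                "screened_samples": len(result.screened.sample_ids),
                "excluded_samples": sorted(result.excluded),
                "qpcr_panels": n_panels,
            },
        }
        assert (
            manifest["stages"]["input_otus"]
            >= manifest["stages"]["filtered_otus"]
            >= manifest["stages"]["screened_otus"]
        )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def write_dataset(table, taxonomy: TaxonomyMap, metadata, outdir: str | Path) -> None:
    """Write a (synthetic) dataset in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, outdir / "otu_table.tsv")
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    write_metadata(metadata, outdir / "metadata.tsv")
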