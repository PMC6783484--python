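"""End-to-end orchestration: one config in, the full report bundle out.

``run_all`` executes every stage on a pre-built alignment — site table, SNP
Venn partition, window profile, hotspot and high-deletion BEDs, percent
identity against a reference taxon, p-distance matrix, relative rate tests
(skipped with a warning when no outgroup is configured), and a quadripartite
structure report per annotated genome — writing plain-text outputs (TSV /
JSON / BED) plus a run log with parameters.  Runs are deterministic: the
same config and inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alignment import Alignment, read_alignment, read_genbank_features
from .sites import classify_columns, count_totals, snp_partition, write_site_table
from .windows import (annotate_windows, detect_hotspots, high_deletion_windows,
                      identity_profile, window_profile, write_bed, write_profile)
from .distances import p_distance, rrt_all_pairs, rrt_table
from .structure import summarize_plastome

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Plain-text configuration for a full pipeline run."""

    alignment: str
    output_dir: str
    reference: str | None = None       # reference taxon for identity/annotation
    outgroup: str | None = None        # outgroup taxon for the rate tests
    annotations: dict[str, str] = field(default_factory=dict)  # taxon -> gb file
    window_length: int = 500
    step: int = 250
    hotspot_mode: str = "min_count"
    hotspot_param: float = 20
    deletion_fraction: float = 0.70
    min_ir_length: int = 10_000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_against(self, alignment: Alignment) -> None:
        for role, taxon in (("reference", self.reference),
                            ("outgroup", self.outgroup)):
            if taxon is not None and taxon not in alignment.taxa:
                raise ValueError(
                    f"{role} taxon {taxon!r} not in alignment "
                    f"(taxa: {list(alignment.taxa)})")
        for taxon in self.annotations:
            if taxon not in alignment.taxa:
                raise ValueError(
                    f"annotated taxon {taxon!r} not in alignment")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_all(config: RunConfig,
            alignment: Alignment | None = None) -> dict[str, Path]:
    """Run every analysis stage and write the report bundle.

    Returns a mapping from output name to written path.  Any stage error
    aborts with a stage-named :class:`StageError`; outputs written before
    the failure remain on disk and are listed in the exception message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise StageError(
                    f"stage {name!r} failed: {exc}; partial outputs: "
                    f"{sorted(str(p) for p in outputs.values())}") from exc
        return deco

    if alignment is None:
        @stage("read_alignment")
        def _():
            nonlocal alignment
            alignment = read_alignment(config.alignment)
    config.validate_against(alignment)
    header = (f"plastdiv {__version__} | alignment={config.alignment} | "
              f"L={config.window_length} s={config.step} | "
              f"hotspot={config.hotspot_mode}:{config.hotspot_param} | "
              f"deletion_fraction={config.deletion_fraction} | "
              f"seed={config.seed}")

    records = None

    @stage("classify")
    def _():
        nonlocal records
        records = classify_columns(alignment)
        path = outdir / "sites.tsv"
        write_site_table(records, alignment.taxa, path)
        outputs["sites"] = path

    @stage("venn")
    def _():
        table = snp_partition(records, alignment.taxa)
        path = outdir / "venn.json"
        payload = table.to_json_dict()
        payload["totals"] = count_totals(records)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        outputs["venn"] = path

    profile = None

    @stage("windows")
    def _():
        nonlocal profile
        profile = window_profile(records, config.window_length, config.step)
        if config.reference and config.reference in config.annotations:
            features, _seq = read_genbank_features(
                config.annotations[config.reference])
            profile = annotate_windows(profile, features, alignment,
                                       config.reference)
        path = outdir / "windows.tsv"
        write_profile(profile, path, comment=header)
        outputs["windows"] = path

    @stage("hotspots")
    def _():
        regions = detect_hotspots(profile, records, config.hotspot_mode,
                                  config.hotspot_param)
        path = outdir / "hotspots.bed"
        write_bed(regions, path, name_prefix="hotspot")
        outputs["hotspots"] = path

    @stage("high_deletion")
    def _():
        flagged = high_deletion_windows(alignment, config.window_length,
                                        config.step,
                                        config.deletion_fraction)
        path = outdir / "high_deletion.bed"
        write_bed(flagged, path)
        outputs["high_deletion"] = path

    @stage("identity")
    def _():
        if not config.reference:
            logger.warning("no reference taxon configured; "
                           "identity profile skipped")
            return
        df = identity_profile(alignment, config.reference,
                              config.window_length, config.step)
        path = outdir / "identity.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n# reference={config.reference}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.3f")
        outputs["identity"] = path

    @stage("pdist")
    def _():
        result = p_distance(alignment, deletion="complete")
        path = outdir / "pdist.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n# complete deletion; "
                     f"n_complete={result.n_complete}\n")
            result.to_dataframe().to_csv(fh, sep="\t", float_format="%.6f")
        outputs["pdist"] = path

    @stage("rrt")
    def _():
        if not config.outgroup:
            logger.warning("no outgroup configured; relative rate tests "
                           "skipped")
            return
        ingroup = [t for t in alignment.taxa if t != config.outgroup]
        results = rrt_all_pairs(alignment, ingroup, config.outgroup)
        path = outdir / "rrt.tsv"
        with open(path, "w") as fh:
            fh.write(f"# {header}\n# outgroup={config.outgroup}\n")
            rrt_table(results).to_csv(fh, sep="\t", index=False)
        outputs["rrt"] = path

    @stage("structure")
    def _():
        for taxon, gb_path in sorted(config.annotations.items()):
            features, seq = read_genbank_features(gb_path)
            summary = summarize_plastome(seq, features,
                                         min_ir_length=config.min_ir_length)
            path = outdir / f"structure.{taxon}.json"
            path.write_text(
                json.dumps(summary.to_json_dict(), indent=2) + "\n")
            outputs[f"structure.{taxon}"] = path

    @stage("run_log")
    def _():
        path = outdir / "run_log.txt"
        lines = [header] + [f"{k}\t{v}" for k, v in sorted(outputs.items())]
        path.write_text("\n".join(lines) + "\n")
        outputs["run_log"] = path

    return outputs
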