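"""End-to-end pipeline: simulate → classify/filter → call → map → lineage.

Every stage consumes and produces plain TSV/FASTA files, so stages are
independently re-runnable; a JSON manifest recording the config hash, seed,
package versions and output row counts is written at the end of every run,
including failed ones (with the failing stage recorded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .align import AlignmentScoring
from .calling import (
    DominantMutationCaller,
    Genotype,
    GenotypeProjector,
    build_frequency_table,
    call_aligned_reads,
    call_reads,
    genotypes_to_frame,
)
from .io import (
    DEFAULT_LENGTH_BINS,
    LengthBins,
    classify_reads,
    filter_by_passes,
    read_sequences,
    write_sequences,
)
from .lineage import find_unique_mutations, match_parasite_origin, summary_report
from .references import HOST, ReferenceSet
from .simulate import SimulationConfig, sample_reads, simulate_serial_transfer
from .space import SquaredHammingPCoA, build_distance_matrix, build_edges

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "coevoseq_out"
    reads_path: str | None = None  # None -> simulate
    reads_format: str = "fasta"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dominance_threshold: float = 0.10
    top_n: int = 90
    min_passes_by_class: dict[str, int] | None = None
    length_bins: LengthBins = DEFAULT_LENGTH_BINS
    scoring: AlignmentScoring = AlignmentScoring()
    literal_eigenvalue_scaling: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.dominance_threshold < 1.0:
            raise ValueError(
                f"dominance_threshold must lie in (0, 1), got "
                f"{self.dominance_threshold}"
            )
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        self.simulation.validate()

    def config_hash(self) -> str:
        plain = _as_plain(self)
        plain.pop("out_dir", None)  # identifies the analysis, not its location
        raw = json.dumps(plain, sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            sim = raw.pop("simulation")
            sim_cfg = (SimulationConfig.from_dict(sim)
                       if isinstance(sim, dict) else sim)
        else:
            sim_cfg = SimulationConfig()
        if "length_bins" in raw:
            raw["length_bins"] = LengthBins(
                tuple((l, int(a), int(b)) for l, a, b in raw["length_bins"])
            )
        if "scoring" in raw:
            raw["scoring"] = AlignmentScoring(**raw["scoring"])
        return cls(simulation=sim_cfg, **raw)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def genotypes_from_frame(frame: pd.DataFrame) -> list[Genotype]:
    """Inverse of :func:`coevoseq.calling.genotypes_to_frame`."""
    out = []
    for row in frame.to_dict("records"):
        vec = tuple(-1 if c == "-" else int(c) for c in str(row["vector"]))
        out.append(
            Genotype(vec, row["class"], int(row["round"]),
                     float(row["frequency"]), int(row["rank"]),
                     int(row["count"]))
        )
    return out


def simulate_stage(config: PipelineConfig, out: Path) -> tuple[list, ReferenceSet]:
    """Run the serial-transfer simulation and write reads + truth."""
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    populations, truth = simulate_serial_transfer(sim_cfg)
    references = populations[0].references
    reads = []
    for pop in populations:
        reads.extend(
            sample_reads(
                pop,
                sim_cfg.reads_per_round,
                sim_cfg.seq_error_rate,
                seed=np.random.default_rng((config.seed, pop.round)),
            )
        )
    write_sequences(reads, out / "reads.fasta")
    truth.to_tsv(out / "truth.tsv")
    with open(out / "references.fasta", "w") as fh:
        for label in references.classes:
            fh.write(f">{label}\n{references.sequence(label)}\n")
    return reads, references


def run_pipeline(config: PipelineConfig,
                 references: ReferenceSet | None = None) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": {},
        "status": "running",
    }
    stage = "setup"
    t0 = time.monotonic()

    def record(name: str, frame: pd.DataFrame, path: Path) -> None:
        frame.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = {"path": path.name, "rows": int(len(frame))}

    try:
        if config.reads_path is None:
            stage = "simulate"
            reads, references = simulate_stage(config, out)
        else:
            stage = "read input"
            reads = read_sequences(config.reads_path, config.reads_format)
            if references is None:
                raise ValueError(
                    "run_pipeline needs a ReferenceSet when reads are supplied"
                )

        stage = "classify/filter"
        if config.reads_format != "aligned-fasta":
            reads = classify_reads(reads, config.length_bins)
        if any(r.passes is not None for r in reads):
            reads = filter_by_passes(reads, config.min_passes_by_class)
        logger.info("%d reads after classification and filtering", len(reads))

        stage = "align/call"
        if config.reads_format == "aligned-fasta":
            called = call_aligned_reads(reads, references)
        else:
            called = call_reads(reads, references, config.scoring)
        table = build_frequency_table(called)
        record("frequency_table", table, out / "frequency.tsv")

        stage = "dominant"
        caller = DominantMutationCaller(config.dominance_threshold).fit(table)
        dominant = caller.dominant_set_
        dom_frame = pd.DataFrame(
            [
                {"site": ev.site, "kind": ev.kind, "ref": ev.ref,
                 "alt": ev.alt, "label": ev.label}
                for ev in dominant.events
            ],
            columns=["site", "kind", "ref", "alt", "label"],
        )
        record("dominant_mutations", dom_frame, out / "dominant.tsv")
        manifest["n_dominant_mutations"] = caller.n_events_
        manifest["n_dominant_sites"] = caller.n_sites_

        stage = "genotypes"
        projector = GenotypeProjector(dominant, references, config.top_n)
        genotypes = projector.fit_transform(called)
        record("genotypes", genotypes_to_frame(genotypes),
               out / "genotypes.tsv")

        stage = "distances/embedding/edges"
        dmat = build_distance_matrix(genotypes)
        coords = SquaredHammingPCoA(
            literal_eigenvalue_scaling=config.literal_eigenvalue_scaling
        ).fit_transform(dmat)
        coord_frame = genotypes_to_frame(genotypes).assign(
            x=coords[:, 0], y=coords[:, 1]
        )
        record("coordinates", coord_frame, out / "coordinates.tsv")
        edges = build_edges(genotypes, dmat)
        record("edges", edges.to_frame(), out / "edges.tsv")

        stage = "lineage"
        parasite_classes = [c for c in references.classes if c != HOST]
        reports = [
            find_unique_mutations(table, dominant, pc, references)
            for pc in parasite_classes
            if (table["class"] == pc).any()
        ]
        unique_frame = (
            pd.concat([r.to_frame() for r in reports], ignore_index=True)
            if reports
            else pd.DataFrame(columns=["class", "site", "kind", "label",
                                       "first_round", "last_round"])
        )
        record("unique_mutations", unique_frame, out / "unique_mutations.tsv")
        hosts = [g for g in genotypes if g.class_label == HOST]
        parasites = [g for g in genotypes if g.class_label != HOST]
        origins = match_parasite_origin(parasites, hosts)
        origin_frame = pd.DataFrame(
            [
                {
                    "parasite_round": o.parasite_round,
                    "n_candidates": len(o.candidates),
                    "best_host_round": (o.candidates[0].host_round
                                        if o.candidates else ""),
                }
                for o in origins
            ],
            columns=["parasite_round", "n_candidates", "best_host_round"],
        )
        record("origin_matches", origin_frame, out / "origin_matches.tsv")
        (out / "summary.txt").write_text(
            summary_report(reports, origins=origins) + "\n"
        )

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, manifest)
        raise RuntimeError(f"pipeline failed in stage '{stage}'") from exc
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
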