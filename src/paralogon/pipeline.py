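"""End-to-end driver: candidates -> anchors -> q-scores -> tiers -> families.

`run_pipeline` is the in-memory engine; `run_all` wraps it with file I/O and
writes a run manifest so a rerun with identical inputs and seed reproduces
identical outputs byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .calling import (
    OhnologPair,
    TIER_ORDER,
    build_families,
    classify_pair,
    filter_epoch,
    filter_ssd_load,
    tier_pairs,
)
from .errors import DataError
from .genome_io import (
    GenomeMap,
    HomologySet,
    WgdConfig,
    write_families,
    write_pairs,
)
from .scoring import score_candidates

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int | None
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    pairs: list[OhnologPair]
    families: dict[str, list]
    unsupported: list[tuple[str, str]]
    manifest: RunManifest


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    target: GenomeMap,
    outgroups: Mapping[str, GenomeMap],
    orthologs: Mapping[str, HomologySet],
    paralogs: HomologySet,
    cfg: WgdConfig,
    seed: int | None = None,
) -> PipelineResult:
    """Run detection on in-memory tables and return scored pairs + families.

    Stages: SSD-load filter -> epoch filter -> per-outgroup anchor detection
    and scoring -> self comparison -> weighted combination -> tier
    classification -> per-tier family construction.  Candidates that never
    land in any anchor are returned in ``unsupported`` rather than silently
    dropped.
    """
    if target.n_genes == 0:
        raise DataError(f"target genome {target.species!r} is empty")
    if not cfg.target_epochs:
        raise DataError("cfg.target_epochs is empty: no duplication epochs selected")

    retained = filter_ssd_load(paralogs, cfg.max_paralogs)
    candidates = {
        p
        for p in filter_epoch(paralogs, cfg.target_epochs)
        if p[0] in retained and p[1] in retained
    }
    logger.info("stage=candidates n=%d", len(candidates))

    self_links = sorted(candidates)
    ortholog_sets = {sp: sorted(hs.orthologs) for sp, hs in orthologs.items()}
    scores = score_candidates(
        target, outgroups, ortholog_sets, sorted(candidates), self_links, cfg
    )
    logger.info("stage=scored n=%d", len(scores))

    pairs = [
        OhnologPair(p[0], p[1], s, classify_pair(s, cfg.criteria_thresholds))
        for p, s in sorted(scores.items())
    ]
    unsupported = sorted(candidates - set(scores))

    families = {
        tier: build_families(tier_pairs(pairs, tier), tier) for tier in TIER_ORDER
    }
    manifest = RunManifest(
        config=_config_dict(cfg),
        seed=seed,
        version=__version__,
        row_counts={
            "candidates": len(candidates),
            "scored_pairs": len(scores),
            "unsupported": len(unsupported),
            **{f"families_{t}": len(f) for t, f in families.items()},
            **{
                f"pairs_{t}": len(tier_pairs(pairs, t)) for t in TIER_ORDER
            },
        },
    )
    return PipelineResult(pairs, families, unsupported, manifest)


def _config_dict(cfg: WgdConfig) -> dict:
    d = asdict(cfg)
    d["window_sizes"] = list(cfg.window_sizes)
    d["target_epochs"] = sorted(cfg.target_epochs)
    d["criteria_thresholds"] = {k: list(v) for k, v in cfg.criteria_thresholds.items()}
    return d


def run_all(
    input_dir: str | Path,
    out_dir: str | Path,
    cfg: WgdConfig,
    target_name: str = "target",
    seed: int | None = None,
) -> PipelineResult:
    """File-level pipeline: read an input directory, write all output tables.

    Expects ``<target>.genome.tsv``, ``<target>.paralogs.tsv`` and for each
    outgroup ``<name>.genome.tsv`` + ``<name>.orthologs.tsv`` (the layout
    :func:`paralogon.wgd_sim.write_simulation` produces).
    """
    from .genome_io import read_genome_map, read_homology

    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    target_path = input_dir / f"{target_name}.genome.tsv"
    if not target_path.exists():
        raise DataError(f"missing target genome file {target_path}")
    target = read_genome_map(target_path, species=target_name)

    outgroups: dict[str, GenomeMap] = {}
    orthologs: dict[str, HomologySet] = {}
    inputs = {f"{target_name}.genome.tsv": target_path}
    for opath in sorted(input_dir.glob("*.orthologs.tsv")):
        sp = opath.name[: -len(".orthologs.tsv")]
        gpath = input_dir / f"{sp}.genome.tsv"
        if not gpath.exists():
            raise DataError(f"orthologs for {sp!r} present but genome file {gpath} missing")
        outgroups[sp] = read_genome_map(gpath, species=sp)
        orthologs[sp] = read_homology(
            opath, "ortholog", sp, target_name, genomes=[outgroups[sp], target]
        )
        inputs[gpath.name] = gpath
        inputs[opath.name] = opath
    if not outgroups:
        raise DataError(f"no outgroup ortholog tables found in {input_dir}")

    ppath = input_dir / f"{target_name}.paralogs.tsv"
    if not ppath.exists():
        raise DataError(f"missing paralog table {ppath}")
    paralogs = read_homology(ppath, "paralog", target_name, genomes=[target])
    inputs[ppath.name] = ppath

    result = run_pipeline(target, outgroups, orthologs, paralogs, cfg, seed=seed)
    result.manifest.input_digests = {name: _digest(p) for name, p in sorted(inputs.items())}

    write_pairs(result.pairs, out_dir / "pairs.tsv")
    for tier, fams in result.families.items():
        write_families(fams, out_dir / f"families.{tier}.tsv")
    with open(out_dir / "unsupported.tsv", "w") as fh:
        fh.write("gene_id_1\tgene_id_2\n")
        for a, b in result.unsupported:
            fh.write(f"{a}\t{b}\n")
    (out_dir / "manifest.json").write_text(result.manifest.to_json() + "\n")
    return result
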