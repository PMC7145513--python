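"""Forward simulator of paleo-polyploid genome evolution.

The simulator lays an ancestral gene order on chromosomes, branches off
non-duplicated outgroup lineages (with independent gene loss and
rearrangement), then applies one or more whole-genome duplications to the
target lineage.  Each WGD duplicates every chromosome; for every duplicated
gene pair both copies survive with probability ``retention_prob``, otherwise
one uniformly chosen copy is deleted — so genes are never lost entirely, and
the expected extant gene count is ``n_genes * prod(1 + retention_prob)``.
Lineage-specific inversions and tail translocations scramble gene order, and
small-scale duplications (SSD) insert extra copies either in tandem or at a
random position.

Every extant gene remembers its ancestral gene and its copy path through the
WGD rounds, so ortholog links (by ancestral identity), epoch-labelled paralog
pairs (first path divergence = WGD round; identical paths = SSD), and
ground-truth ohnolog pairs per round fall out exactly.  The output tables
are the same TSV dialects the detection pipeline reads.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import ConfigError, DataError
from .genome_io import (
    Gene,
    GenomeMap,
    HomologySet,
    write_genome_map,
    write_homology,
)

BIOTYPE_CHOICES = ("protein_coding", "miRNA", "misc_RNA", "rRNA", "snRNA", "snoRNA")
BIOTYPE_PROBS = (0.95, 0.02, 0.015, 0.005, 0.005, 0.005)


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters of one simulated paleo-polyploidy history.

    ``wgd_rounds=2`` emulates the two rounds at the base of vertebrates
    (2R-like); ``wgd_rounds=1`` a single teleost-like event (3R-like).
    ``retention_prob`` is the per-pair probability that both copies survive a
    WGD; ``retention_odds_multiplier`` (> 1) multiplies the retention *odds*
    in later rounds for genes already sitting in a retained earlier-round
    pair, reproducing the observed coupling between 2R and 3R retention.
    """

    n_genes: int = 1000
    n_chromosomes: int = 5
    wgd_rounds: int = 2
    retention_prob: float = 0.25
    n_inversions: int = 20
    n_translocations: int = 5
    ssd_rate: float = 0.0
    n_outgroups: int = 2
    outgroup_loss_prob: float = 0.15
    seed: int = 0
    retention_odds_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for p, name in (
            (self.retention_prob, "retention_prob"),
            (self.outgroup_loss_prob, "outgroup_loss_prob"),
        ):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for c, name in (
            (self.n_genes, "n_genes"),
            (self.n_chromosomes, "n_chromosomes"),
            (self.wgd_rounds, "wgd_rounds"),
            (self.n_inversions, "n_inversions"),
            (self.n_translocations, "n_translocations"),
            (self.n_outgroups, "n_outgroups"),
        ):
            if c < 0:
                raise ConfigError(f"{name} must be >= 0, got {c}")
        if self.ssd_rate < 0 or self.retention_odds_multiplier <= 0:
            raise ConfigError("ssd_rate must be >= 0 and retention_odds_multiplier > 0")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ConfigError("need at least one gene and one chromosome")


@dataclass
class SimTruth:
    """A simulated dataset with its ground truth."""

    config: SimConfig
    target: GenomeMap
    outgroups: dict[str, GenomeMap]
    orthologs: dict[str, HomologySet]
    paralogs: HomologySet
    true_pairs: dict[str, set[tuple[str, str]]]  # epoch label -> pairs
    true_families: dict[str, list[frozenset]] = field(default_factory=dict)

    def wgd_epochs(self) -> frozenset[str]:
        return frozenset(self.true_pairs)

    def all_wgd_pairs(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for pairs in self.true_pairs.values():
            out |= pairs
        return out


# internal gene record: (ancestor id, wgd copy path, ssd serial: 0 = original)
_Rec = tuple[int, tuple[int, ...], int]


def _ancestral_chromosomes(cfg: SimConfig) -> list[list[_Rec]]:
    blocks = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    return [[(int(a), (), 0) for a in block] for block in blocks]


def _rearrange(
    chroms: list[list], n_inversions: int, n_translocations: int, rng: np.random.Generator
) -> None:
    """In-place inversions (reverse a rank interval) and tail translocations."""
    for _ in range(n_inversions):
        sizes = np.array([len(c) for c in chroms], dtype=float)
        if sizes.sum() == 0:
            return
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        n = len(chroms[ci])
        if n < 2:
            continue
        i, j = sorted(rng.integers(0, n, size=2))
        chroms[ci][i : j + 1] = chroms[ci][i : j + 1][::-1]
    for _ in range(n_translocations):
        if len(chroms) < 2:
            break
        ci, cj = rng.choice(len(chroms), size=2, replace=False)
        cut_i = int(rng.integers(0, len(chroms[ci]) + 1))
        cut_j = int(rng.integers(0, len(chroms[cj]) + 1))
        tail_i, tail_j = chroms[ci][cut_i:], chroms[cj][cut_j:]
        chroms[ci] = chroms[ci][:cut_i] + tail_j
        chroms[cj] = chroms[cj][:cut_j] + tail_i


def _apply_wgd(
    chroms: list[tuple[str, list[_Rec]]],
    round_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, list[_Rec]]]:
    # ancestors with >=2 extant copies are already members of a retained pair
    counts: dict[int, int] = {}
    for _, genes in chroms:
        for anc, _, _ in genes:
            counts[anc] = counts.get(anc, 0) + 1

    p = cfg.retention_prob
    if cfg.retention_odds_multiplier != 1.0 and 0.0 < p < 1.0:
        odds = p / (1.0 - p) * cfg.retention_odds_multiplier
        p_bias = odds / (1.0 + odds)
    else:
        p_bias = p

    new: list[tuple[str, list[_Rec]]] = []
    for label, genes in chroms:
        copy_a: list[_Rec] = []
        copy_b: list[_Rec] = []
        for anc, path, ssd in genes:
            p_eff = p_bias if (round_index > 0 and counts[anc] >= 2) else p
            rec_a = (anc, path + (0,), ssd)
            rec_b = (anc, path + (1,), ssd)
            if rng.random() < p_eff:
                copy_a.append(rec_a)
                copy_b.append(rec_b)
            elif rng.random() < 0.5:
                copy_a.append(rec_a)
            else:
                copy_b.append(rec_b)
        new.append((label + "a", copy_a))
        new.append((label + "b", copy_b))
    return new


def _apply_ssd(
    chroms: list[tuple[str, list[_Rec]]], cfg: SimConfig, rng: np.random.Generator
) -> int:
    total = sum(len(g) for _, g in chroms)
    n_events = int(rng.poisson(cfg.ssd_rate * total))
    serial = 0
    for _ in range(n_events):
        sizes = np.array([len(g) for _, g in chroms], dtype=float)
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        pos = int(rng.integers(0, len(chroms[ci][1])))
        anc, path, _ = chroms[ci][1][pos]
        serial += 1
        rec = (anc, path, serial)
        if rng.random() < 0.5:  # tandem
            chroms[ci][1].insert(pos + 1, rec)
        else:
            sizes = np.array([len(g) + 1 for _, g in chroms], dtype=float)
            cj = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
            ins = int(rng.integers(0, len(chroms[cj][1]) + 1))
            chroms[cj][1].insert(ins, rec)
    return n_events


def _gene_id(species_tag: str, rec: _Rec) -> str:
    anc, path, ssd = rec
    suffix = "".join("ab"[c] for c in path)
    sid = f"{species_tag}g{anc:05d}"
    if suffix:
        sid += f"_{suffix}"
    if ssd:
        sid += f"_s{ssd}"
    return sid


def _pair_epoch(r1: _Rec, r2: _Rec) -> str:
    _, p1, _ = r1
    _, p2, _ = r2
    for i, (a, b) in enumerate(zip(p1, p2)):
        if a != b:
            return f"WGD_{i + 1}"
    return "SSD"


def simulate(cfg: SimConfig) -> SimTruth:
    """Run the forward simulation and assemble genomes, homologies and truth."""
    rng = np.random.default_rng(cfg.seed)
    biotype_of = rng.choice(BIOTYPE_CHOICES, size=cfg.n_genes, p=BIOTYPE_PROBS)

    ancestral = _ancestral_chromosomes(cfg)

    # outgroup lineages: branch before all WGD rounds
    outgroups: dict[str, GenomeMap] = {}
    ortholog_links: dict[str, list[tuple[str, int]]] = {}
    for i in range(cfg.n_outgroups):
        sp = f"outgroup{i + 1}"
        tag = f"O{i + 1}"
        chroms = [list(c) for c in ancestral]
        kept = [
            [rec for rec in c if rng.random() >= cfg.outgroup_loss_prob] for c in chroms
        ]
        _rearrange(kept, cfg.n_inversions, cfg.n_translocations, rng)
        gmap: dict[str, list[Gene]] = {}
        links: list[tuple[str, int]] = []
        for ci, genes in enumerate(kept):
            label = f"chr{ci + 1}"
            gmap[label] = [
                Gene(_gene_id(tag, rec), label, r, str(biotype_of[rec[0]]))
                for r, rec in enumerate(genes)
            ]
            links.extend((_gene_id(tag, rec), rec[0]) for rec in genes)
        outgroups[sp] = GenomeMap(sp, gmap)
        ortholog_links[sp] = links

    # target lineage: WGD rounds, then rearrangement, then SSD
    target_chroms: list[tuple[str, list[_Rec]]] = [
        (f"chr{i + 1}", list(c)) for i, c in enumerate(ancestral)
    ]
    for r in range(cfg.wgd_rounds):
        target_chroms = _apply_wgd(target_chroms, r, cfg, rng)
    gene_lists = [genes for _, genes in target_chroms]
    _rearrange(gene_lists, cfg.n_inversions, cfg.n_translocations, rng)
    target_chroms = [(label, genes) for (label, _), genes in zip(target_chroms, gene_lists)]
    _apply_ssd(target_chroms, cfg, rng)

    tmap: dict[str, list[Gene]] = {}
    by_ancestor: dict[int, list[_Rec]] = {}
    for label, genes in target_chroms:
        if not genes:
            continue
        tmap[label] = [
            Gene(_gene_id("T", rec), label, r, str(biotype_of[rec[0]]))
            for r, rec in enumerate(genes)
        ]
        for rec in genes:
            by_ancestor.setdefault(rec[0], []).append(rec)
    target = GenomeMap("target", tmap)

    # paralogs within the target, epoch = first copy-path divergence
    paralogs = HomologySet("target", "target")
    true_pairs: dict[str, set[tuple[str, str]]] = {
        f"WGD_{r + 1}": set() for r in range(cfg.wgd_rounds)
    }
    for recs in by_ancestor.values():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                epoch = _pair_epoch(recs[i], recs[j])
                a, b = sorted((_gene_id("T", recs[i]), _gene_id("T", recs[j])))
                paralogs.paralogs.add((a, b, epoch))
                if epoch in true_pairs:
                    true_pairs[epoch].add((a, b))

    orthologs: dict[str, HomologySet] = {}
    for sp, links in ortholog_links.items():
        hs = HomologySet(sp, "target")
        for og_id, anc in links:
            for rec in by_ancestor.get(anc, ()):
                hs.orthologs.add((og_id, _gene_id("T", rec)))
        orthologs[sp] = hs

    true_families = {
        epoch: _components(pairs) for epoch, pairs in true_pairs.items()
    }
    return SimTruth(
        config=cfg,
        target=target,
        outgroups=outgroups,
        orthologs=orthologs,
        paralogs=paralogs,
        true_pairs=true_pairs,
        true_families=true_families,
    )


def _components(pairs: Iterable[tuple[str, str]]) -> list[frozenset]:
    g = nx.Graph()
    g.add_edges_from(pairs)
    return sorted((frozenset(c) for c in nx.connected_components(g)), key=min)


def shuffle_null(genome: GenomeMap, seed: int) -> GenomeMap:
    """Uniformly permute gene order genome-wide, preserving chromosome sizes.

    The per-chromosome gene counts are kept and genes are dealt back in
    shuffled order, which re-draws each gene's chromosome with probability
    proportional to chromosome size.  Homology tables are untouched.
    """
    rng = np.random.default_rng(seed)
    genes = list(genome.genes())
    perm = rng.permutation(len(genes))
    shuffled = [genes[i] for i in perm]
    chroms: dict[str, list[Gene]] = {}
    offset = 0
    for label in sorted(genome.chromosomes):
        size = len(genome.chromosomes[label])
        chroms[label] = [
            replace(g, chromosome=label, rank=r)
            for r, g in enumerate(shuffled[offset : offset + size])
        ]
        offset += size
    return GenomeMap(genome.species, chroms)


@dataclass
class EvalResult:
    """Precision/recall of called pairs against simulated truth."""

    precision: float | None  # None = NA (no calls)
    recall: float | None  # None = NA (empty truth)
    n_calls: int
    n_truth: int
    n_correct: int
    per_tier: dict[str, dict[str, float | None]] = field(default_factory=dict)


def _canon(pairs: Iterable) -> set[tuple[str, str]]:
    out = set()
    for p in pairs:
        a, b = p.pair if hasattr(p, "pair") else tuple(p)
        out.add((a, b) if a < b else (b, a))
    return out


def _pr(calls: set, truth: set) -> tuple[float | None, float | None, int]:
    correct = len(calls & truth)
    precision = correct / len(calls) if calls else None
    recall = correct / len(truth) if truth else None
    return precision, recall, correct


def evaluate(
    calls: Iterable,
    truth: SimTruth,
    epochs: Iterable[str] | None = None,
) -> EvalResult:
    """Compare called pairs with the simulator's true WGD pairs.

    ``calls`` may be ``(gene_id_1, gene_id_2)`` tuples or
    :class:`~paralogon.calling.OhnologPair` objects; when tiers are present a
    per-tier (cumulative) precision/recall table is included.  ``epochs``
    restricts the truth to specific WGD rounds (default: all rounds).
    """
    calls = list(calls)
    call_set = _canon(calls)
    for a, b in call_set:
        if a not in truth.target or b not in truth.target:
            raise DataError(f"called pair ({a}, {b}) not in the simulated genome")
    if epochs is None:
        truth_set = truth.all_wgd_pairs()
    else:
        truth_set = set()
        for e in epochs:
            truth_set |= truth.true_pairs.get(e, set())
    precision, recall, correct = _pr(call_set, truth_set)

    per_tier: dict[str, dict[str, float | None]] = {}
    tiers_present = [p for p in calls if hasattr(p, "criterion")]
    if tiers_present:
        from .calling import TIER_ORDER, tier_pairs

        for tier in TIER_ORDER:
            tset = _canon(tier_pairs(tiers_present, tier))
            tp, tr, tc = _pr(tset, truth_set)
            per_tier[tier] = {
                "n_calls": len(tset),
                "precision": tp,
                "recall": tr,
            }
    return EvalResult(
        precision=precision,
        recall=recall,
        n_calls=len(call_set),
        n_truth=len(truth_set),
        n_correct=correct,
        per_tier=per_tier,
    )


def write_simulation(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the TSV tables the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    p = out / "target.genome.tsv"
    write_genome_map(truth.target, p)
    paths["target"] = p
    for sp, gm in truth.outgroups.items():
        p = out / f"{sp}.genome.tsv"
        write_genome_map(gm, p)
        paths[sp] = p
        p = out / f"{sp}.orthologs.tsv"
        write_homology(truth.orthologs[sp], p, "ortholog")
        paths[f"{sp}_orthologs"] = p
    p = out / "target.paralogs.tsv"
    write_homology(truth.paralogs, p, "paralog")
    paths["paralogs"] = p
    p = out / "truth_pairs.tsv"
    import pandas as pd

    rows = [
        (a, b, epoch)
        for epoch in sorted(truth.true_pairs)
        for a, b in sorted(truth.true_pairs[epoch])
    ]
    pd.DataFrame(rows, columns=["gene_id_1", "gene_id_2", "epoch"]).to_csv(
        p, sep="\t", index=False
    )
    paths["truth"] = p
    return paths
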