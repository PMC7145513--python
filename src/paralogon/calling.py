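"""Candidate filtering, confidence-tier classification and family building.

Candidates are paralog pairs dated to a WGD epoch.  Genes carrying an
excessive small-scale-duplication load are removed first (their inflated
paralogy distorts the synteny statistics), the duplication epoch may be
resolved by majority vote across annotation snapshots, and scored pairs are
assigned the most stringent confidence tier whose outgroup/self q-score
thresholds they satisfy.  Tiers are nested by construction:
``strict`` pairs are also ``intermediate`` and ``relaxed`` pairs.

Families are the connected components of the pair graph at one tier.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import DataError
from .genome_io import GenomeMap, HomologySet
from .scoring import PairScore

logger = logging.getLogger(__name__)

#: sentinel returned when annotation snapshots disagree without a majority
UNRESOLVED = "UNRESOLVED"

TIER_ORDER = ("strict", "intermediate", "relaxed")


@dataclass(frozen=True)
class OhnologPair:
    """A scored candidate pair with the best confidence tier it attains."""

    gene_id_1: str
    gene_id_2: str
    scores: PairScore
    criterion: str  # strict | intermediate | relaxed | none

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_id_1, self.gene_id_2)


@dataclass(frozen=True)
class OhnologFamily:
    """Connected component of ohnolog pairs at one confidence tier."""

    family_id: str
    criterion: str
    members: frozenset


def filter_epoch(
    paralogs: HomologySet | Iterable[tuple[str, str, str]],
    target_epochs: Iterable[str],
) -> set[tuple[str, str]]:
    """Pairs whose duplication-epoch label is in ``target_epochs``, exactly.

    Unknown labels are never remapped: a pair is retained iff its label is
    explicitly listed.
    """
    triples = paralogs.paralogs if isinstance(paralogs, HomologySet) else paralogs
    epochs = set(target_epochs)
    return {(a, b) for a, b, e in triples if e in epochs}


def consensus_epoch(labels: Sequence[str]) -> str:
    """Strict-majority epoch across annotation snapshots, else ``UNRESOLVED``."""
    if not labels:
        raise DataError("consensus_epoch needs at least one label")
    label, count = Counter(labels).most_common(1)[0]
    return label if count * 2 > len(labels) else UNRESOLVED


def filter_ssd_load(
    paralogs: HomologySet | Iterable[tuple[str, str, str]],
    max_paralogs: int = 30,
) -> set[str]:
    """Genes whose total paralog count (any epoch) does not exceed the cap.

    Returns the retained gene set; a gene with ``> max_paralogs`` paralogs is
    excluded, and callers must drop every pair touching an excluded gene.
    """
    triples = paralogs.paralogs if isinstance(paralogs, HomologySet) else paralogs
    counts: Counter = Counter()
    for a, b, _ in triples:
        counts[a] += 1
        counts[b] += 1
    return {g for g, c in counts.items() if c <= max_paralogs}


def classify_pair(scores: PairScore, criteria_thresholds: Mapping[str, tuple[float, float]]) -> str:
    """Most stringent tier whose q thresholds the pair passes, else ``"none"``.

    Both the combined outgroup q and the self q must pass.  A missing q
    (no supporting anchors in that comparison) fails every tier and is
    logged.
    """
    if scores.q_outgroup is None or scores.q_self is None:
        logger.debug(
            "pair (%s, %s): missing %s q-score, classified as none",
            scores.gene_id_1,
            scores.gene_id_2,
            "outgroup" if scores.q_outgroup is None else "self",
        )
        return "none"
    for tier in TIER_ORDER:
        qo_max, qs_max = criteria_thresholds[tier]
        if scores.q_outgroup <= qo_max and scores.q_self <= qs_max:
            return tier
    return "none"


def tier_pairs(pairs: Iterable[OhnologPair], criterion: str) -> list[OhnologPair]:
    """Pairs belonging to ``criterion``'s (cumulative, nested) set."""
    rank = {t: i for i, t in enumerate(TIER_ORDER)}
    if criterion not in rank:
        raise DataError(f"unknown criterion {criterion!r}")
    return [p for p in pairs if p.criterion in rank and rank[p.criterion] <= rank[criterion]]


def build_families(pairs: Iterable[OhnologPair | tuple[str, str]], criterion: str = "relaxed") -> list[OhnologFamily]:
    """Connected components of the pair graph, with deterministic ids.

    Components are sorted by their smallest member id and numbered in that
    order; output is independent of input pair order.
    """
    g = nx.Graph()
    for p in pairs:
        a, b = (p.pair if isinstance(p, OhnologPair) else tuple(p))
        g.add_edge(a, b)
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [
        OhnologFamily(f"{criterion}_{i + 1:05d}", criterion, frozenset(c))
        for i, c in enumerate(comps)
    ]


def family_size_distribution(families: Iterable[OhnologFamily]) -> dict[int, int]:
    """Mapping family size -> number of families of that size."""
    return dict(Counter(len(f.members) for f in families))


@dataclass
class EnrichmentResult:
    """2x2 association between 2R-ohnolog status and 3R-ohnolog retention."""

    table: np.ndarray  # rows: is 2R-ohnolog yes/no; cols: has 3R-ohnolog yes/no
    chi_square: float
    odds_ratio: float
    valid: bool


def cross_wgd_enrichment(
    families_2r: Iterable[OhnologFamily],
    families_3r: Iterable[OhnologFamily],
    all_genes: Iterable[str],
) -> EnrichmentResult:
    """Test whether 2R-ohnologs preferentially retain 3R-ohnologs.

    Builds the gene-level 2x2 contingency table over ``all_genes`` and
    reports the Pearson chi-square statistic (no continuity correction) and
    the odds ratio.  A table with a zero margin is flagged invalid and the
    statistics are NaN.
    """
    def _members(f):
        return f.members if hasattr(f, "members") else f

    set_2r = {g for f in families_2r for g in _members(f)}
    set_3r = {g for f in families_3r for g in _members(f)}
    genes = list(all_genes)
    a = sum(1 for g in genes if g in set_2r and g in set_3r)
    b = sum(1 for g in genes if g in set_2r and g not in set_3r)
    c = sum(1 for g in genes if g not in set_2r and g in set_3r)
    d = len(genes) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("cross-WGD table has a zero margin; statistic undefined")
        return EnrichmentResult(table, float("nan"), float("nan"), False)
    from scipy.stats import chi2_contingency

    chi2 = float(chi2_contingency(table, correction=False)[0])
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(table, chi2, odds, True)


def biotype_pair_summary(
    pairs: Iterable[OhnologPair | tuple[str, str]],
    biotypes: Mapping[str, str] | GenomeMap,
) -> dict[str, dict[str, float]]:
    """Per-biotype bookkeeping of a pair table.

    A pair is counted under a biotype class when both members share that
    biotype, under ``"mixed"`` otherwise.  Returns
    ``{class: {"count": ..., "percent": ...}}`` with percentages of the total
    pair count.
    """
    if isinstance(biotypes, GenomeMap):
        biotypes = biotypes.biotypes()
    counts: Counter = Counter()
    total = 0
    for p in pairs:
        a, b = (p.pair if isinstance(p, OhnologPair) else tuple(p))
        total += 1
        ba, bb = biotypes.get(a), biotypes.get(b)
        counts[ba if ba == bb else "mixed"] += 1
    return {
        cls: {"count": float(n), "percent": 100.0 * n / total if total else float("nan")}
        for cls, n in sorted(counts.items())
    }
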