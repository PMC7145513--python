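"""q-scores: the probability that an ohnolog pair's synteny support is chance.

The null model is hypergeometric: if the ``n`` genes of an outgroup window
that have orthologs in the target genome were scattered uniformly among the
target's ``G`` anchored gene slots, the number landing inside one target
window of ``K`` genes follows ``Hypergeometric(G, K, n)``.  The raw score of
a window pair is the upper tail ``P(X >= k)`` of that distribution,
Bonferroni-adjusted for the number of target windows examined.

For a candidate pair the raw scores of its two supporting windows are
multiplied, minimized over supporting anchors, geometric-averaged over window
sizes, and finally combined across outgroup species with a weighted geometric
mean.  The species weights ``w_i = 1 / sum_j s_ij`` (with ``s`` the pairwise
ortholog-sharing similarity) correct for phylogenetically biased sampling:
adding a second copy of an already-sampled genome splits that genome's weight
rather than doubling its vote.

All combination arithmetic is carried out in log space; every emitted q lies
in ``(0, 1]``.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ConfigError, DataError
from .genome_io import GenomeMap, WgdConfig
from .synteny import (
    SyntenyAnchor,
    Window,
    detect_anchors,
    detect_self_anchors,
)


@dataclass
class PairScore:
    """Scores of one candidate pair: per-outgroup, combined, and self q."""

    gene_id_1: str
    gene_id_2: str
    per_outgroup_q: dict[str, float] = field(default_factory=dict)
    q_outgroup: float | None = None
    q_self: float | None = None


@dataclass
class SpeciesWeights:
    """Phylogeny-bias-correcting weights with the similarity they came from."""

    weights: dict[str, float]
    similarity: pd.DataFrame


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

def _check_hypergeom_args(G: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= G):
        raise DataError(f"need 0 <= K <= G, got K={K}, G={G}")
    if not (0 <= k <= n <= G):
        raise DataError(f"need 0 <= k <= n <= G, got k={k}, n={n}, G={G}")
    if k > K:
        raise DataError(f"observed k={k} exceeds window size K={K}")


def log_hypergeom_tail(G: int, K: int, n: int, k: int) -> float:
    """``log P(X >= k)`` for ``X ~ Hypergeometric(G, K, n)`` (natural log)."""
    _check_hypergeom_args(G, K, n, k)
    if k == 0:
        return 0.0
    # scipy parametrization: hypergeom(M=population, n=successes, N=draws)
    return float(hypergeom.logsf(k - 1, G, K, n))


def hypergeom_tail(G: int, K: int, n: int, k: int) -> float:
    """Upper tail ``P(X >= k)`` of the hypergeometric null, in ``(0, 1]``.

    ``G``: anchored genes in the target genome; ``K``: genes in the target
    window; ``n``: outgroup-window genes with >=1 ortholog in the target;
    ``k``: of those, the number hitting the target window.
    """
    _check_hypergeom_args(G, K, n, k)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, G, K, n))


# ---------------------------------------------------------------------------
# species weighting
# ---------------------------------------------------------------------------

def ortholog_similarity(ortholog_sets: Mapping[str, Iterable[tuple[str, str]]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of the target genes each species covers.

    ``ortholog_sets`` maps outgroup species name to its ``(outgroup gene,
    target gene)`` links; similarity between two species is the Jaccard index
    of the sets of target genes they supply orthologs for.
    """
    species = sorted(ortholog_sets)
    covered = {sp: {b for _, b in ortholog_sets[sp]} for sp in species}
    s = pd.DataFrame(np.eye(len(species)), index=species, columns=species)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            union = covered[a] | covered[b]
            sim = len(covered[a] & covered[b]) / len(union) if union else 0.0
            s.loc[a, b] = s.loc[b, a] = sim
    return s


def species_weights(similarity: pd.DataFrame) -> SpeciesWeights:
    """Effective-number weights solving ``sum_j s_ij w_j = 1`` for every i.

    Each species should carry one unit of *independent* evidence; a species
    whose homology is shared with others has part of that unit already
    accounted for, so its weight shrinks.  The defining property is clone
    invariance: adding an exact duplicate of a sampled genome splits that
    genome's weight between the two copies (min-norm solution of the then
    singular system) and leaves every other weight unchanged, so oversampled
    lineages can never increase their effective vote.  An isolated species
    gets weight 1; for mutually independent panels all weights are 1.

    Should the linear system return a non-positive weight (possible only for
    similarity structures far from anything a Jaccard index produces), the
    reciprocal row-sum form ``w_i = 1 / sum_j s_ij`` is used instead.
    """
    s = similarity.astype(float)
    if list(s.index) != list(s.columns):
        raise ConfigError("similarity matrix must have identical row/column labels")
    arr = s.to_numpy()
    if not np.allclose(arr, arr.T):
        raise ConfigError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(arr), 1.0):
        raise ConfigError("similarity diagonal must be 1")
    if arr.min() < 0 or arr.max() > 1 + 1e-12:
        raise ConfigError("similarity entries must lie in [0, 1]")
    w, *_ = np.linalg.lstsq(arr, np.ones(len(arr)), rcond=None)
    if w.min() <= 0:
        w = 1.0 / arr.sum(axis=1)
    weights = {sp: float(w[i]) for i, sp in enumerate(s.index)}
    return SpeciesWeights(weights=weights, similarity=s)


def combine_weighted(per_species_q: Mapping[str, float], weights: SpeciesWeights) -> float:
    """Weighted geometric mean of per-species q over the species that scored."""
    logq = combine_weighted_log(
        {sp: math.log(q) for sp, q in per_species_q.items()}, weights
    )
    return math.exp(logq)


def combine_weighted_log(per_species_logq: Mapping[str, float], weights: SpeciesWeights) -> float:
    if not per_species_logq:
        raise DataError("cannot combine an empty set of per-species scores")
    missing = set(per_species_logq) - set(weights.weights)
    if missing:
        raise DataError(f"no weight for species {sorted(missing)}")
    num = sum(weights.weights[sp] * lq for sp, lq in per_species_logq.items())
    den = sum(weights.weights[sp] for sp in per_species_logq)
    return min(0.0, num / den)


# ---------------------------------------------------------------------------
# pair scoring against anchors
# ---------------------------------------------------------------------------

_window_gene_sets: dict[Window, frozenset] = {}


def _gene_set(w: Window) -> frozenset:
    s = _window_gene_sets.get(w)
    if s is None:
        s = frozenset(w.gene_ids)
        _window_gene_sets[w] = s
    return s


def _log_raw_outgroup(
    anchor: SyntenyAnchor, g1: str, g2: str, G: int
) -> float | None:
    """min over window combos of log(p1 * p2 * m), capped at log 1 = 0."""
    best = None
    wins = anchor.target_windows
    log_m = math.log(max(anchor.n_tested, 1))
    for i, (w1, k1, n) in enumerate(wins):
        if g1 not in _gene_set(w1):
            continue
        lt1 = log_hypergeom_tail(G, len(w1.gene_ids), n, min(k1, len(w1.gene_ids)))
        for j, (w2, k2, _) in enumerate(wins):
            if i == j or g2 not in _gene_set(w2):
                continue
            lt2 = log_hypergeom_tail(G, len(w2.gene_ids), n, min(k2, len(w2.gene_ids)))
            val = min(0.0, lt1 + lt2 + log_m)
            if best is None or val < best:
                best = val
    return best


def _aggregate_sizes(per_size_best: Mapping[int, float]) -> float:
    """Geometric mean over window sizes of the per-size minimum (log scale)."""
    return sum(per_size_best.values()) / len(per_size_best)


def score_pair_one_outgroup(
    pair: tuple[str, str],
    anchors: Sequence[SyntenyAnchor],
    target_size: int,
    cfg: WgdConfig | None = None,
) -> float | None:
    """q of one pair against one outgroup's anchors; ``None`` if unsupported.

    Per supporting anchor the raw score is the product of the two windows'
    hypergeometric tails times the Bonferroni multiplicity, capped at 1; per
    window size the minimum over anchors is taken; sizes are combined by
    geometric mean.
    """
    g1, g2 = pair
    per_size: dict[int, float] = {}
    for a in anchors:
        lr = _log_raw_outgroup(a, g1, g2, target_size)
        lr2 = _log_raw_outgroup(a, g2, g1, target_size)
        for v in (lr, lr2):
            if v is None:
                continue
            if a.window_size not in per_size or v < per_size[a.window_size]:
                per_size[a.window_size] = v
    if not per_size:
        return None
    return math.exp(_aggregate_sizes(per_size))


def score_pair_self(
    pair: tuple[str, str],
    self_anchors: Sequence[SyntenyAnchor],
    target_size: int,
    cfg: WgdConfig | None = None,
) -> float | None:
    """Self-comparison q of one pair; ``None`` if no self anchor supports it.

    Each self anchor links a query window to partner windows; a pair is
    supported when its genes fall one in the query and one in a partner.  The
    raw score is that window pair's tail times the Bonferroni multiplicity.
    """
    g1, g2 = pair
    per_size: dict[int, float] = {}
    for a in self_anchors:
        qset = _gene_set(a.outgroup_window)
        log_m = math.log(max(a.n_tested, 1))
        for w, k, n in a.target_windows:
            pset = _gene_set(w)
            if (g1 in qset and g2 in pset) or (g2 in qset and g1 in pset):
                K = len(w.gene_ids)
                lt = log_hypergeom_tail(target_size, K, n, min(k, K, n))
                val = min(0.0, lt + log_m)
                if a.window_size not in per_size or val < per_size[a.window_size]:
                    per_size[a.window_size] = val
    if not per_size:
        return None
    return math.exp(_aggregate_sizes(per_size))


# ---------------------------------------------------------------------------
# batch driver
# ---------------------------------------------------------------------------

def _anchor_index(anchors: Sequence[SyntenyAnchor]) -> dict[str, list[int]]:
    """gene id -> indices of anchors whose target windows contain it."""
    idx: dict[str, list[int]] = defaultdict(list)
    for i, a in enumerate(anchors):
        seen: set[str] = set()
        for w, _, _ in a.target_windows:
            seen.update(w.gene_ids)
        for g in seen:
            idx[g].append(i)
    return idx


def _self_anchor_index(anchors: Sequence[SyntenyAnchor]) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i, a in enumerate(anchors):
        seen = set(a.outgroup_window.gene_ids)
        for w, _, _ in a.target_windows:
            seen.update(w.gene_ids)
        for g in seen:
            idx[g].append(i)
    return idx


def score_candidates(
    target: GenomeMap,
    outgroups: Mapping[str, GenomeMap],
    ortholog_sets: Mapping[str, Iterable[tuple[str, str]]],
    candidates: Iterable[tuple[str, str]],
    self_links: Iterable[tuple[str, str]],
    cfg: WgdConfig,
    weights: SpeciesWeights | None = None,
) -> dict[tuple[str, str], PairScore]:
    """Score candidate pairs against every outgroup and the self comparison.

    Returns scores for every candidate supported by >=1 outgroup anchor;
    unsupported candidates are absent from the result (callers may report
    them separately as diagnostics).
    """
    candidates = [tuple(sorted(p)) for p in candidates]
    G = target.n_genes
    ortholog_sets = {sp: list(links) for sp, links in ortholog_sets.items()}
    if weights is None:
        weights = species_weights(ortholog_similarity(ortholog_sets))

    per_species_logq: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for sp in sorted(outgroups):
        anchors = detect_anchors(outgroups[sp], target, ortholog_sets[sp], cfg)
        gidx = _anchor_index(anchors)
        for pair in candidates:
            g1, g2 = pair
            hit_ids = set(gidx.get(g1, ())) & set(gidx.get(g2, ()))
            if not hit_ids:
                continue
            per_size: dict[int, float] = {}
            for ai in hit_ids:
                a = anchors[ai]
                v = _log_raw_outgroup(a, g1, g2, G)
                if v is None:
                    continue
                if a.window_size not in per_size or v < per_size[a.window_size]:
                    per_size[a.window_size] = v
            if per_size:
                per_species_logq[pair][sp] = _aggregate_sizes(per_size)

    self_anchors = detect_self_anchors(target, self_links, cfg)
    sidx = _self_anchor_index(self_anchors)

    result: dict[tuple[str, str], PairScore] = {}
    for pair in candidates:
        logqs = per_species_logq.get(pair)
        if not logqs:
            continue
        g1, g2 = pair
        q_self = None
        hit_ids = set(sidx.get(g1, ())) & set(sidx.get(g2, ()))
        if hit_ids:
            q_self = score_pair_self(pair, [self_anchors[i] for i in sorted(hit_ids)], G, cfg)
        result[pair] = PairScore(
            gene_id_1=g1,
            gene_id_2=g2,
            per_outgroup_q={sp: math.exp(lq) for sp, lq in logqs.items()},
            q_outgroup=math.exp(combine_weighted_log(logqs, weights)),
            q_self=q_self,
        )
    return result


# ---------------------------------------------------------------------------
# null-calibration helper
# ---------------------------------------------------------------------------

def window_pair_tails(
    outgroup: GenomeMap,
    target: GenomeMap,
    orthologs: Iterable[tuple[str, str]],
    cfg: WgdConfig,
    sizes: Sequence[int] | None = None,
) -> list[tuple[float, int, int, int, int]]:
    """Raw tails of every examined window pair, for calibration studies.

    Returns ``(tail, G, K, n, k)`` for each (outgroup window, target window)
    pair with at least one hit, over the configured window sizes.
    """
    from .synteny import WindowIndex, _adjacency, _hits_for_window, build_windows

    adj = _adjacency(list(orthologs), target.locations())
    G = target.n_genes
    out: list[tuple[float, int, int, int, int]] = []
    for size in sizes if sizes is not None else cfg.window_sizes:
        step = cfg.step_for(size)
        out_wins = build_windows(outgroup, size, step)
        index = WindowIndex(build_windows(target, size, step))
        for w_out in out_wins:
            hits, n = _hits_for_window(w_out, index, adj)
            for wi, k in hits.items():
                K = len(index.windows[wi].gene_ids)
                kk = min(k, K, n)
                out.append((hypergeom_tail(G, K, n, kk), G, K, n, kk))
    return out
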