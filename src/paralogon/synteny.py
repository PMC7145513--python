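"""Sliding macro-synteny windows and doubly-conserved-synteny anchors.

A whole-genome duplication leaves a characteristic footprint: one region of a
non-duplicated outgroup genome shares orthology with *two or more* regions of
the paleo-polyploid genome (doubly conserved synteny, DCS).  This module
tiles gene orders with sliding windows, counts ortholog hits between an
outgroup window and all target windows, and emits :class:`SyntenyAnchor`
records wherever the DCS pattern holds.  The same machinery run on one genome
against itself (with WGD-epoch paralog links in place of orthologs) yields
self-comparison anchors linking the two retained copies of a duplicated
segment.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .genome_io import GenomeMap, WgdConfig


@dataclass(frozen=True)
class Window:
    """A half-open rank interval ``[start_rank, start_rank + len(gene_ids))``.

    ``size`` records the nominal window size; truncated tail windows (and
    whole short chromosomes) carry fewer genes than ``size``.
    """

    species: str
    chromosome: str
    start_rank: int
    size: int
    gene_ids: tuple[str, ...]

    @property
    def stop_rank(self) -> int:
        return self.start_rank + len(self.gene_ids)

    def overlaps(self, other: "Window") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start_rank < other.stop_rank
            and other.start_rank < self.stop_rank
        )


@dataclass(frozen=True)
class SyntenyAnchor:
    """One outgroup (or query) window linked to supported target windows.

    ``target_windows`` holds ``(window, k, n)`` triples sorted by descending
    hit count ``k``; ``n`` is the number of outgroup-window genes with at
    least one homolog in the target; ``n_tested`` is the number of target
    windows with any hit, used as the Bonferroni multiplicity when scoring.
    """

    outgroup_window: Window
    target_windows: tuple[tuple[Window, int, int], ...]
    window_size: int
    n_tested: int


def build_windows(genome: GenomeMap, size: int, step: int) -> list[Window]:
    """Tile every chromosome with windows of ``size`` genes every ``step`` ranks.

    A chromosome shorter than ``size`` yields a single window covering it
    entirely.  The final window may be truncated, but a tail shorter than
    ``size / 2`` is merged into the previous window instead of standing alone.
    """
    if size < 2:
        raise ConfigError(f"window size must be >= 2, got {size}")
    if step < 1:
        raise ConfigError(f"window step must be >= 1, got {step}")
    windows: list[Window] = []
    for chrom in sorted(genome.chromosomes):
        genes = genome.chromosomes[chrom]
        n = len(genes)
        ids = [g.gene_id for g in genes]
        chrom_wins: list[tuple[int, int]] = []  # (start, stop)
        for start in range(0, max(n - size, 0) + 1, step) if n >= size else [0]:
            chrom_wins.append((start, min(start + size, n)))
        # windows whose natural stop passed the end were clipped; also cover a
        # remaining tail beyond the last full window
        last_stop = chrom_wins[-1][1]
        if last_stop < n:
            chrom_wins.append((chrom_wins[-1][0] + step, n))
        # merge a too-short tail into the previous window
        while len(chrom_wins) > 1 and chrom_wins[-1][1] - chrom_wins[-1][0] < size / 2:
            start, _ = chrom_wins.pop()
            pstart, _ = chrom_wins.pop()
            chrom_wins.append((pstart, n))
        for start, stop in chrom_wins:
            windows.append(Window(genome.species, chrom, start, size, tuple(ids[start:stop])))
    return windows


class WindowIndex:
    """Fast rank-position -> window lookup over one window tiling."""

    def __init__(self, windows: Sequence[Window]):
        self.windows = list(windows)
        self._by_pos: dict[tuple[str, int], tuple[int, ...]] = {}
        tmp: dict[tuple[str, int], list[int]] = defaultdict(list)
        for i, w in enumerate(self.windows):
            for r in range(w.start_rank, w.stop_rank):
                tmp[(w.chromosome, r)].append(i)
        self._by_pos = {k: tuple(v) for k, v in tmp.items()}

    def windows_at(self, chromosome: str, rank: int) -> tuple[int, ...]:
        return self._by_pos.get((chromosome, rank), ())


def _adjacency(
    links: Iterable[tuple[str, str]], target_loc: Mapping[str, tuple[str, int]]
) -> dict[str, list[tuple[str, int]]]:
    """source gene -> list of target (chromosome, rank) positions."""
    adj: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for a, b in links:
        pos = target_loc.get(b)
        if pos is not None:
            adj[a].append(pos)
    return dict(adj)


def _hits_for_window(
    w_out: Window, index: WindowIndex, adj: Mapping[str, list[tuple[str, int]]]
) -> tuple[dict[int, int], int]:
    """Return ``(window_index -> k, n)`` for one outgroup window.

    ``n`` counts outgroup-window genes with >=1 homolog anywhere in the
    target; each such gene contributes at most one hit per target window,
    however many homologs it has there.
    """
    k: dict[int, int] = defaultdict(int)
    n = 0
    for g in w_out.gene_ids:
        positions = adj.get(g)
        if not positions:
            continue
        n += 1
        hit_windows: set[int] = set()
        for chrom, rank in positions:
            hit_windows.update(index.windows_at(chrom, rank))
        for wi in hit_windows:
            k[wi] += 1
    return dict(k), n


def window_hits(
    w_out: Window,
    target: GenomeMap,
    orthologs: Iterable[tuple[str, str]],
    target_windows: Sequence[Window],
) -> tuple[dict[Window, tuple[int, int]], int]:
    """Ortholog hit counts of one outgroup window against prebuilt target windows.

    Returns ``(mapping target Window -> (k, n), n)``; windows with zero hits
    are omitted from the mapping.
    """
    index = WindowIndex(target_windows)
    adj = _adjacency(orthologs, target.locations())
    k, n = _hits_for_window(w_out, index, adj)
    return {index.windows[i]: (c, n) for i, c in k.items()}, n


def _select_nonoverlapping(
    candidates: list[tuple[int, int]], windows: Sequence[Window]
) -> list[tuple[int, int]]:
    """Greedy selection of pairwise non-overlapping windows by descending k."""
    chosen: list[tuple[int, int]] = []
    for wi, k in sorted(candidates, key=lambda t: (-t[1], windows[t[0]].chromosome, windows[t[0]].start_rank)):
        if all(not windows[wi].overlaps(windows[cj]) for cj, _ in chosen):
            chosen.append((wi, k))
    return chosen


def detect_anchors(
    outgroup: GenomeMap,
    target: GenomeMap,
    orthologs: Iterable[tuple[str, str]],
    cfg: WgdConfig,
    sizes: Sequence[int] | None = None,
) -> list[SyntenyAnchor]:
    """Detect doubly-conserved-synteny anchors of ``outgroup`` against ``target``.

    For every window size and outgroup window, an anchor is emitted iff at
    least two pairwise non-overlapping target windows each receive
    ``k >= cfg.scaled_min_hits(size)`` ortholog hits.  Unless
    ``cfg.allow_same_chromosome`` the target windows must additionally lie on
    distinct chromosomes.
    """
    orthologs = list(orthologs)
    target_loc = target.locations()
    adj = _adjacency(orthologs, target_loc)
    anchors: list[SyntenyAnchor] = []
    for size in sizes if sizes is not None else cfg.window_sizes:
        step = cfg.step_for(size)
        out_wins = build_windows(outgroup, size, step)
        index = WindowIndex(build_windows(target, size, step))
        min_k = cfg.scaled_min_hits(size)
        for w_out in out_wins:
            hits, n = _hits_for_window(w_out, index, adj)
            if not hits:
                continue
            candidates = [(wi, k) for wi, k in hits.items() if k >= min_k]
            chosen = _select_nonoverlapping(candidates, index.windows)
            if not cfg.allow_same_chromosome:
                seen_chrom: set[str] = set()
                distinct = []
                for wi, k in chosen:
                    c = index.windows[wi].chromosome
                    if c not in seen_chrom:
                        seen_chrom.add(c)
                        distinct.append((wi, k))
                chosen = distinct
            if len(chosen) >= 2:
                anchors.append(
                    SyntenyAnchor(
                        outgroup_window=w_out,
                        target_windows=tuple(
                            (index.windows[wi], k, n) for wi, k in chosen
                        ),
                        window_size=size,
                        n_tested=len(hits),
                    )
                )
    return anchors


def detect_self_anchors(
    genome: GenomeMap,
    paralogs: Iterable[tuple[str, str]],
    cfg: WgdConfig,
    sizes: Sequence[int] | None = None,
) -> list[SyntenyAnchor]:
    """Self-comparison anchors: window pairs of one genome linked by paralogs.

    Each anchor pairs a query window with >=1 partner window carrying
    ``k >= scaled_min_hits`` paralog hits; window pairs that overlap in rank
    space (e.g. tandem clusters within one window) are excluded, and each
    unordered window pair is reported once, with the lexicographically
    smaller window as the query.
    """
    links = set()
    for a, b in paralogs:
        links.add((a, b))
        links.add((b, a))
    loc = genome.locations()
    adj = _adjacency(links, loc)
    anchors: list[SyntenyAnchor] = []
    for size in sizes if sizes is not None else cfg.window_sizes:
        step = cfg.step_for(size)
        wins = build_windows(genome, size, step)
        index = WindowIndex(wins)
        min_k = cfg.scaled_min_hits(size)
        order = {i: (w.chromosome, w.start_rank, w.stop_rank) for i, w in enumerate(wins)}
        for qi, w_q in enumerate(wins):
            hits, _ = _hits_for_window(w_q, index, adj)
            # genes of the query whose partners land outside the query window
            # define the draw count n; overlapping windows are not partners
            hits = {wi: k for wi, k in hits.items() if not wins[wi].overlaps(w_q)}
            if not hits:
                continue
            n = 0
            for g in w_q.gene_ids:
                positions = adj.get(g, ())
                if any(
                    chrom != w_q.chromosome
                    or not (w_q.start_rank <= r < w_q.stop_rank)
                    for chrom, r in positions
                ):
                    n += 1
            candidates = [
                (wi, k)
                for wi, k in hits.items()
                if k >= min_k and order[wi] > order[qi]
            ]
            chosen = _select_nonoverlapping(candidates, wins)
            if chosen:
                anchors.append(
                    SyntenyAnchor(
                        outgroup_window=w_q,
                        target_windows=tuple((wins[wi], k, n) for wi, k in chosen),
                        window_size=size,
                        n_tested=len(hits),
                    )
                )
    return anchors


def write_anchors(anchors: Sequence[SyntenyAnchor], path) -> None:
    """Serialize anchors to TSV for diagnostics."""
    import pandas as pd

    rows = []
    for a in anchors:
        for w, k, n in a.target_windows:
            rows.append(
                (
                    a.window_size,
                    a.outgroup_window.species,
                    a.outgroup_window.chromosome,
                    a.outgroup_window.start_rank,
                    a.outgroup_window.stop_rank,
                    w.species,
                    w.chromosome,
                    w.start_rank,
                    w.stop_rank,
                    k,
                    n,
                    a.n_tested,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "window_size", "query_species", "query_chrom", "query_start", "query_stop",
            "target_species", "target_chrom", "target_start", "target_stop",
            "k", "n", "n_tested",
        ],
    ).to_csv(path, sep="\t", index=False)
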