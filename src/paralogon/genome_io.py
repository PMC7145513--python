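"""Domain types and TSV readers/writers for gene order and homology tables.

The synteny machinery works on *gene order*, not physical coordinates: every
gene carries a 0-based ``rank`` along its chromosome, and macro-synteny
windows are half-open rank intervals ``[i, i + size)``.  Strand is ignored
throughout, and genes that are not anchored on a named chromosome (scaffolds,
contigs, unplaced sequence) are excluded at load time.

All tables are plain UTF-8 TSV with a header row; lines starting with ``#``
are treated as comments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Gene classes with ortholog/paralog annotation; anything else is rejected.
VALID_BIOTYPES = frozenset(
    {"protein_coding", "miRNA", "misc_RNA", "rRNA", "snRNA", "snoRNA"}
)

#: Chromosome-label prefixes treated as unanchored sequence (case-insensitive).
UNANCHORED_PREFIXES = ("scaffold", "contig", "ctg", "chrun", "un_", "gl", "ki", "jh")


@dataclass(frozen=True)
class Gene:
    """A gene anchored on a chromosome at an order rank."""

    gene_id: str
    chromosome: str
    rank: int
    biotype: str = "protein_coding"


class GenomeMap:
    """Ordered genes per chromosome for one species.

    Invariants (checked at construction): gene ids are unique within the
    genome and ranks on each chromosome form a contiguous ``0..n-1`` sequence.
    """

    def __init__(self, species: str, chromosomes: Mapping[str, Sequence[Gene]]):
        self.species = species
        self.chromosomes: dict[str, list[Gene]] = {
            c: list(genes) for c, genes in chromosomes.items()
        }
        self._validate()
        self._locations: dict[str, tuple[str, int]] = {
            g.gene_id: (c, g.rank) for c, genes in self.chromosomes.items() for g in genes
        }

    def _validate(self) -> None:
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            ranks = [g.rank for g in genes]
            if ranks != list(range(len(genes))):
                raise DataError(
                    f"ranks on chromosome {chrom!r} are not contiguous 0..{len(genes) - 1}"
                )
            for g in genes:
                if g.chromosome != chrom:
                    raise DataError(
                        f"gene {g.gene_id!r} filed under {chrom!r} but labelled {g.chromosome!r}"
                    )
                if g.gene_id in seen:
                    raise DataError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def genes(self) -> Iterator[Gene]:
        for chrom in self.chromosomes:
            yield from self.chromosomes[chrom]

    def locations(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (chromosome, rank) for every gene in the genome."""
        return self._locations

    def biotypes(self) -> dict[str, str]:
        return {g.gene_id: g.biotype for g in self.genes()}

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._locations

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeMap):
            return NotImplemented
        return self.species == other.species and self.chromosomes == other.chromosomes

    def __repr__(self) -> str:
        return (
            f"GenomeMap({self.species!r}, {len(self.chromosomes)} chromosomes, "
            f"{self.n_genes} genes)"
        )


@dataclass
class HomologySet:
    """Ortholog links between two genomes and/or epoch-labelled paralog pairs.

    Orthologs are directed ``(gene_in_a, gene_in_b)`` links; paralogs are
    unordered pairs stored canonically with ``gene_id_1 < gene_id_2`` plus an
    opaque duplication-epoch label (e.g. ``"Vertebrata"``, ``"WGD_1"``,
    ``"SSD"``).
    """

    species_a: str
    species_b: str
    orthologs: set[tuple[str, str]] = field(default_factory=set)
    paralogs: set[tuple[str, str, str]] = field(default_factory=set)

    def paralog_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.paralogs}


@dataclass
class WgdConfig:
    """Tunable thresholds of the detection pipeline.

    ``min_hits`` is the minimum shared homologs per window pair at the base
    window size of 100 genes; it is scaled proportionally for larger windows.
    ``criteria_thresholds`` maps each confidence tier to a pair
    ``(outgroup_q_max, self_q_max)``; tiers must be nested from strict to
    relaxed.
    """

    window_sizes: tuple[int, ...] = (100, 200, 300, 400, 500)
    window_step: int | None = None  # None -> size // 2 (50% overlap)
    min_hits: int = 6
    target_epochs: frozenset[str] = frozenset()
    max_paralogs: int = 30
    criteria_thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "strict": (0.01, 0.01),
            "intermediate": (0.05, 0.30),
            "relaxed": (0.30, 0.30),
        }
    )
    allow_same_chromosome: bool = True

    #: tier order from most to least stringent
    TIERS = ("strict", "intermediate", "relaxed")

    def __post_init__(self) -> None:
        self.window_sizes = tuple(sorted(int(s) for s in self.window_sizes))
        self.target_epochs = frozenset(self.target_epochs)
        if any(s < 2 for s in self.window_sizes):
            raise ConfigError("window sizes must all be >= 2")
        if self.window_step is not None and self.window_step < 1:
            raise ConfigError("window_step must be >= 1")
        if self.min_hits < 1:
            raise ConfigError("min_hits must be >= 1")
        prev = (0.0, 0.0)
        for tier in self.TIERS:
            if tier not in self.criteria_thresholds:
                raise ConfigError(f"missing thresholds for tier {tier!r}")
            qo, qs = self.criteria_thresholds[tier]
            for v in (qo, qs):
                if not (0.0 < v <= 1.0):
                    raise ConfigError(f"threshold {v} for tier {tier!r} not in (0, 1]")
            if qo < prev[0] or qs < prev[1]:
                raise ConfigError("criteria thresholds must be nested strict <= intermediate <= relaxed")
            prev = (qo, qs)

    def step_for(self, size: int) -> int:
        return self.window_step if self.window_step is not None else max(1, size // 2)

    def scaled_min_hits(self, size: int) -> int:
        return max(2, round(self.min_hits * size / 100))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str], optional_groups: Sequence[Sequence[str]] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    for group in optional_groups:
        if not any(c in df.columns for c in group):
            raise DataError(f"{path}: need one of columns {list(group)}")
    return df


def _is_unanchored(chrom: str) -> bool:
    low = chrom.lower()
    return any(low.startswith(p) for p in UNANCHORED_PREFIXES)


def read_genome_map(path: str | Path, species: str | None = None) -> GenomeMap:
    """Read a gene-order table into a :class:`GenomeMap`.

    Expected columns: ``gene_id``, ``chromosome``, ``biotype`` and either
    physical ``start`` (``end`` optional) or a precomputed ``rank``.  Genes on
    unanchored sequence are dropped with a logged count.  Ties on ``start``
    are broken by lexicographic ``gene_id``.
    """
    path = Path(path)
    df = _read_tsv(path, ["gene_id", "chromosome", "biotype"], [("start", "rank")])
    if species is None:
        species = path.stem

    bad_bio = sorted(set(df["biotype"]) - VALID_BIOTYPES)
    if bad_bio:
        raise DataError(f"{path}: unknown biotype(s) {bad_bio}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")

    anchored = ~df["chromosome"].map(_is_unanchored)
    n_dropped = int((~anchored).sum())
    if n_dropped:
        logger.info("%s: dropped %d genes on unanchored sequence", path.name, n_dropped)
    df = df[anchored]

    order_col = "rank" if "rank" in df.columns else "start"
    df = df.assign(_order=df[order_col].astype(float))

    chromosomes: dict[str, list[Gene]] = {}
    for chrom, sub in df.groupby("chromosome", sort=True):
        sub = sub.sort_values(["_order", "gene_id"], kind="mergesort")
        chromosomes[str(chrom)] = [
            Gene(str(r.gene_id), str(chrom), i, str(r.biotype))
            for i, r in enumerate(sub.itertuples())
        ]
    return GenomeMap(species, chromosomes)


def read_homology(
    path: str | Path,
    kind: str,
    species_a: str = "A",
    species_b: str = "B",
    genomes: Sequence[GenomeMap] | None = None,
    strict: bool = False,
) -> HomologySet:
    """Read an ortholog or paralog TSV into a :class:`HomologySet`.

    Ortholog tables need columns ``gene_id_1``/``gene_id_2``; paralog tables
    additionally need ``epoch``.  Paralog pairs are canonicalized (smaller id
    first); self pairs ``(g, g)`` are dropped with a warning.  If ``genomes``
    is given, links referencing unknown genes are dropped with a warning, or
    raise :class:`DataError` when ``strict`` is true.
    """
    if kind not in ("ortholog", "paralog"):
        raise ConfigError(f"kind must be 'ortholog' or 'paralog', got {kind!r}")
    cols = ["gene_id_1", "gene_id_2"] + (["epoch"] if kind == "paralog" else [])
    df = _read_tsv(path, cols)

    known_a = known_b = None
    if genomes:
        known_a = genomes[0].locations()
        known_b = genomes[-1].locations()

    hs = HomologySet(species_a, species_b if kind == "ortholog" else species_a)
    n_self = n_unknown = 0
    for row in df.itertuples(index=False):
        g1, g2 = str(row.gene_id_1), str(row.gene_id_2)
        if g1 == g2:
            n_self += 1
            continue
        if known_a is not None:
            ok = (g1 in known_a) and (g2 in (known_b if kind == "ortholog" else known_a))
            if not ok:
                if strict:
                    raise DataError(f"{path}: link ({g1}, {g2}) references unknown gene")
                n_unknown += 1
                continue
        if kind == "ortholog":
            hs.orthologs.add((g1, g2))
        else:
            a, b = sorted((g1, g2))
            hs.paralogs.add((a, b, str(row.epoch)))
    if n_self:
        logger.warning("%s: dropped %d self pair(s)", Path(path).name, n_self)
    if n_unknown:
        logger.warning("%s: dropped %d link(s) to unknown genes", Path(path).name, n_unknown)
    return hs


# ---------------------------------------------------------------------------
# writers (and their round-trip readers)
# ---------------------------------------------------------------------------

def write_genome_map(genome: GenomeMap, path: str | Path) -> None:
    rows = [
        (g.gene_id, g.chromosome, g.rank, g.biotype)
        for chrom in sorted(genome.chromosomes)
        for g in genome.chromosomes[chrom]
    ]
    pd.DataFrame(rows, columns=["gene_id", "chromosome", "rank", "biotype"]).to_csv(
        path, sep="\t", index=False
    )


def write_homology(hs: HomologySet, path: str | Path, kind: str) -> None:
    if kind == "ortholog":
        rows = sorted(hs.orthologs)
        cols = ["gene_id_1", "gene_id_2"]
    else:
        rows = sorted(hs.paralogs)
        cols = ["gene_id_1", "gene_id_2", "epoch"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _fmt_q(q: float | None) -> str:
    return "NA" if q is None else repr(float(q))


def _parse_q(s: str) -> float | None:
    return None if s == "NA" else float(s)


def write_pairs(pairs: Iterable, path: str | Path) -> None:
    """Write ohnolog pairs with their scores and best confidence tier.

    Columns: ``gene_id_1``, ``gene_id_2``, per-outgroup q columns
    (``q__<species>``), ``q_outgroup``, ``q_self``, ``criterion``.  Floats are
    written with full precision so a round-trip read reproduces them exactly.
    """
    pairs = list(pairs)
    outgroup_names = sorted({sp for p in pairs for sp in p.scores.per_outgroup_q})
    header = (
        ["gene_id_1", "gene_id_2"]
        + [f"q__{sp}" for sp in outgroup_names]
        + ["q_outgroup", "q_self", "criterion"]
    )
    rows = []
    for p in sorted(pairs, key=lambda p: (p.gene_id_1, p.gene_id_2)):
        rows.append(
            [p.gene_id_1, p.gene_id_2]
            + [_fmt_q(p.scores.per_outgroup_q.get(sp)) for sp in outgroup_names]
            + [_fmt_q(p.scores.q_outgroup), _fmt_q(p.scores.q_self), p.criterion]
        )
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list:
    from .calling import OhnologPair
    from .scoring import PairScore

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    qcols = [c for c in df.columns if c.startswith("q__")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        per = {}
        for c in qcols:
            v = _parse_q(d[c])
            if v is not None:
                per[c[3:]] = v
        score = PairScore(
            gene_id_1=d["gene_id_1"],
            gene_id_2=d["gene_id_2"],
            per_outgroup_q=per,
            q_outgroup=_parse_q(d["q_outgroup"]),
            q_self=_parse_q(d["q_self"]),
        )
        out.append(
            OhnologPair(d["gene_id_1"], d["gene_id_2"], score, d["criterion"])
        )
    return out


def write_families(families: Iterable, path: str | Path) -> None:
    """Write ohnolog families: ``family_id``, ``criterion``, comma-joined members."""
    rows = [
        (f.family_id, f.criterion, ",".join(sorted(f.members)))
        for f in sorted(families, key=lambda f: f.family_id)
    ]
    pd.DataFrame(rows, columns=["family_id", "criterion", "members"]).to_csv(
        path, sep="\t", index=False
    )


def read_families(path: str | Path) -> list:
    from .calling import OhnologFamily

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    return [
        OhnologFamily(r.family_id, r.criterion, frozenset(r.members.split(",")))
        for r in df.itertuples(index=False)
    ]
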