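"""Read-pair preprocessing: valid-pair selection, deduplication, the 1 kb
short/long split, and AND/XOR/NOT bin-pair classification.

A proximity-ligation read pair is "valid" when, after mapping-quality
filtering, its read id carries exactly two alignments, or three alignments
that can be disambiguated (one read spanning the ligation junction). Valid
pairs are deduplicated on the (chrom, pos, strand) of both ends, split into
short-range (<= 1 kb, used for ChIP-enrichment estimation) and long-range
(> 1 kb, the actual contacts), and long-range pairs are accumulated into
intra-chromosomal bin-pair counts classified against a peak list:

* AND — both bins overlap a protein-binding peak,
* XOR — exactly one bin does,
* NOT — neither does (emitted, but never modeled downstream).
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid

#: Intra-chromosomal pairs separated by at most this many bp are short-range.
SHORT_RANGE_MAX = 1000

#: Default maximum genomic distance (bp) for tested bin pairs.
DEFAULT_D_MAX = 1_000_000

#: Default minimum mapping quality.
DEFAULT_MAPQ_MIN = 30

BIN_PAIR_COLUMNS = ["chrom", "bin1", "bin2", "x", "d", "set"]


@dataclass(frozen=True, order=True)
class PairEnd:
    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    chrom: str
    pos: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")

    @property
    def end(self) -> PairEnd:
        return PairEnd(self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class ValidPair:
    """An ordered read pair: ``end1 <= end2`` in genome order."""

    end1: PairEnd
    end2: PairEnd

    @classmethod
    def from_ends(cls, a: PairEnd, b: PairEnd) -> "ValidPair":
        return cls(*sorted((a, b)))

    @property
    def is_intra(self) -> bool:
        return self.end1.chrom == self.end2.chrom

    @property
    def distance(self) -> int | None:
        if not self.is_intra:
            return None
        return abs(self.end2.pos - self.end1.pos)

    @property
    def range_class(self) -> str:
        d = self.distance
        return "short" if d is not None and d <= SHORT_RANGE_MAX else "long"

    @property
    def key(self) -> tuple:
        e1, e2 = self.end1, self.end2
        return (e1.chrom, e1.pos, e1.strand, e2.chrom, e2.pos, e2.strand)


def select_valid_pair(
    group: Sequence[AlignmentRecord],
    rng: np.random.Generator | None = None,
) -> ValidPair | None:
    """Pick the valid alignment pair for one read id, or ``None`` to discard.

    Groups of other than 2 or 3 alignments are discarded. Two alignments
    form the pair directly. Three alignments on one chromosome suggest one
    read spans the ligation junction: the alignment pair with the second
    largest linear distance is kept (on a distance tie, the candidate with
    the smaller leftmost coordinate). Three alignments on two chromosomes
    keep the lone alignment paired with one of the two same-chromosome
    alignments chosen at random (``rng``); on three chromosomes the group is
    discarded as a spurious double ligation.
    """
    group = list(group)
    if len(group) not in (2, 3):
        return None
    if len(group) == 2:
        return ValidPair.from_ends(group[0].end, group[1].end)

    chroms = {a.chrom for a in group}
    if len(chroms) == 3:
        return None
    if len(chroms) == 1:
        candidates = []
        for a, b in combinations(group, 2):
            dist = abs(a.pos - b.pos)
            candidates.append((dist, min(a.pos, b.pos), a, b))
        dists = sorted((c[0] for c in candidates), reverse=True)
        target = dists[1]
        tied = [c for c in candidates if c[0] == target]
        _, _, a, b = min(tied, key=lambda c: c[1])
        return ValidPair.from_ends(a.end, b.end)

    # two chromosomes: pair the lone alignment with a random same-chromosome one
    if rng is None:
        raise ValueError("rng is required to resolve two-chromosome triples")
    counts = Counter(a.chrom for a in group)
    lone_chrom = next(c for c, n in counts.items() if n == 1)
    lone = next(a for a in group if a.chrom == lone_chrom)
    same = sorted(
        (a for a in group if a.chrom != lone_chrom), key=lambda a: (a.pos, a.strand)
    )
    chosen = same[int(rng.integers(2))]
    return ValidPair.from_ends(lone.end, chosen.end)


def pair_reads(
    records: Iterable[AlignmentRecord],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    seed: int = 0,
) -> list[ValidPair]:
    """Group alignments by read id, filter by mapq, and select valid pairs."""
    rng = np.random.default_rng(seed)
    groups: "OrderedDict[str, list[AlignmentRecord]]" = OrderedDict()
    for rec in records:
        if rec.mapq < mapq_min:
            continue
        groups.setdefault(rec.read_id, []).append(rec)
    pairs = []
    for group in groups.values():
        pair = select_valid_pair(group, rng)
        if pair is not None:
            pairs.append(pair)
    return pairs


def deduplicate(pairs: Iterable[ValidPair]) -> list[ValidPair]:
    """Remove PCR duplicates: pairs sharing (chrom, pos, strand) on both ends.

    The first occurrence of each duplicate class is kept; the operation is
    idempotent.
    """
    seen = set()
    unique = []
    for pair in pairs:
        if pair.key not in seen:
            seen.add(pair.key)
            unique.append(pair)
    return unique


def split_and_filter(
    pairs: Iterable[ValidPair],
) -> tuple[list[ValidPair], list[ValidPair]]:
    """Split pairs at 1 kb and drop short-range ligation artifacts.

    Returns ``(short, long)``. Intra-chromosomal pairs at distance <= 1 kb
    are short-range; those with both ends on the same strand are removed as
    re-ligation/dangling-end artifacts. Remaining intra-chromosomal pairs
    are long-range. Inter-chromosomal pairs are dropped entirely (only
    intra-chromosomal contacts are modeled).
    """
    short, long_ = [], []
    for pair in pairs:
        if not pair.is_intra:
            continue
        if pair.distance <= SHORT_RANGE_MAX:
            if pair.end1.strand != pair.end2.strand:
                short.append(pair)
        else:
            long_.append(pair)
    return short, long_


def peak_bins(peaks: pd.DataFrame, grid: BinGrid) -> dict[str, set[int]]:
    """Bins overlapping at least one peak interval, per chromosome."""
    out: dict[str, set[int]] = {chrom: set() for chrom in grid.chroms}
    res = grid.resolution
    for chrom, start, end in zip(peaks["chrom"], peaks["start"], peaks["end"]):
        if chrom not in out or end <= start:
            continue
        n = grid.n_bins(chrom)
        first = max(0, start // res)
        last = min(n - 1, (end - 1) // res)
        out[chrom].update(range(first, last + 1))
    return out


def classify_bin_pairs(
    long_pairs: Iterable[ValidPair],
    peaks: pd.DataFrame,
    grid: BinGrid,
    d_min: int | None = None,
    d_max: int = DEFAULT_D_MAX,
) -> pd.DataFrame:
    """Bin long-range pairs and classify them into AND/XOR/NOT sets.

    Each read-pair end is assigned to the bin containing its 5' position.
    Only bin pairs with genomic distance ``d = (j - i) * resolution`` in
    ``[d_min, d_max]`` are emitted (``d_min`` defaults to twice the
    resolution, which also excludes adjacent bins); zero-count bin pairs are
    not emitted. Columns: chrom, bin1, bin2, x, d, set.
    """
    res = grid.resolution
    if d_min is None:
        d_min = 2 * res
    pbins = peak_bins(peaks, grid)

    counts: Counter = Counter()
    for pair in long_pairs:
        if not pair.is_intra:
            continue
        chrom = pair.end1.chrom
        i = grid.bin_index(chrom, pair.end1.pos)
        j = grid.bin_index(chrom, pair.end2.pos)
        if i > j:
            i, j = j, i
        d = (j - i) * res
        if d < d_min or d > d_max:
            continue
        counts[(chrom, i, j)] += 1

    rows = []
    for (chrom, i, j), x in counts.items():
        in_peaks = (i in pbins[chrom]) + (j in pbins[chrom])
        label = ("NOT", "XOR", "AND")[in_peaks]
        rows.append((chrom, i, j, x, (j - i) * res, label))
    df = pd.DataFrame(rows, columns=BIN_PAIR_COLUMNS)
    return df.sort_values(["chrom", "bin1", "bin2"], ignore_index=True)


def short_pairs_frame(short: Sequence[ValidPair]) -> pd.DataFrame:
    """Tabulate short-range pairs (chrom, pos1, pos2, strand1, strand2)."""
    return pd.DataFrame(
        {
            "chrom": [p.end1.chrom for p in short],
            "pos1": [p.end1.pos for p in short],
            "pos2": [p.end2.pos for p in short],
            "strand1": [p.end1.strand for p in short],
            "strand2": [p.end2.strand for p in short],
        }
    )


def preprocess_pairs(
    records: Iterable[AlignmentRecord],
    peaks: pd.DataFrame,
    grid: BinGrid,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    seed: int = 0,
    d_min: int | None = None,
    d_max: int = DEFAULT_D_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing: alignments -> (short-pair table, bin-pair table)."""
    pairs = deduplicate(pair_reads(records, mapq_min=mapq_min, seed=seed))
    short, long_ = split_and_filter(pairs)
    return short_pairs_frame(short), classify_bin_pairs(
        long_, peaks, grid, d_min=d_min, d_max=d_max
    )
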