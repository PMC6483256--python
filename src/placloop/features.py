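"""Per-bin covariates for contact-count normalization.

The background model corrects four systematic biases, each summarized per
genomic bin:

* ``f`` — effective fragment length: total length of restriction-fragment
  ends (each end truncated to 500 bp) falling inside the bin,
* ``gc`` — mean GC fraction of the fragment ends anchored in the bin,
* ``m`` — mean mappability of those fragment ends,
* ``IP`` — ChIP enrichment, measured as the number of short-range
  (<= 1 kb) intra-chromosomal read pairs whose midpoint falls in the bin.

Fragment ends are anchored at their outermost coordinate: the fragment
start for the left end, ``end - 1`` for the right end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import BinGrid

logger = logging.getLogger(__name__)

#: Fragment ends are truncated to this many bp before accumulating ``f``.
FRAGMENT_END_TRUNCATION = 500

_VALID_BASES = frozenset("ACGTN")

FEATURE_COLUMNS = ["chrom", "start", "end", "f", "gc", "m", "IP"]


@dataclass(frozen=True)
class RestrictionFragment:
    """A restriction fragment in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(
                f"invalid fragment [{self.start}, {self.end}) on {self.chrom!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def digest_genome(
    sequences: Mapping[str, str], motif: str
) -> list[RestrictionFragment]:
    """In-silico restriction digest: cut at every motif occurrence start.

    The cut is placed at the first base of the motif (MboI-style ``^GATC``),
    so the motif stays on the downstream fragment. Chromosomes without any
    motif occurrence yield a single full-length fragment. Overlapping motif
    occurrences are all honoured.
    """
    if not motif:
        raise ValueError("restriction motif must be non-empty")
    motif = motif.upper()
    if not set(motif) <= _VALID_BASES:
        raise ValueError(f"motif contains non-ACGTN characters: {motif!r}")

    fragments: list[RestrictionFragment] = []
    for chrom, seq in sequences.items():
        seq = str(seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {chrom!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        cuts = [0]
        idx = seq.find(motif)
        while idx != -1:
            if idx != 0:
                cuts.append(idx)
            idx = seq.find(motif, idx + 1)
        cuts.append(len(seq))
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                fragments.append(RestrictionFragment(chrom, a, b))
    return fragments


def _end_cover_intervals(
    frag: RestrictionFragment, truncation: int
) -> list[tuple[int, int]]:
    """Base intervals covered by the two truncated fragment ends.

    When the fragment is shorter than twice the truncation the two end
    windows overlap; the union is returned so no base is counted twice.
    """
    left_end = min(frag.start + truncation, frag.end)
    right_start = max(frag.end - truncation, frag.start)
    if right_start <= left_end:
        return [(frag.start, frag.end)]
    return [(frag.start, left_end), (right_start, frag.end)]


def fragment_end_anchors(
    fragments: Iterable[RestrictionFragment],
) -> list[tuple[str, int]]:
    """``(chrom, position)`` anchor of every fragment end (left start, right end-1)."""
    anchors = []
    for frag in fragments:
        anchors.append((frag.chrom, frag.start))
        anchors.append((frag.chrom, frag.end - 1))
    return anchors


def gc_of_fragment_ends(
    sequences: Mapping[str, str],
    fragments: Iterable[RestrictionFragment],
    end_truncation: int = FRAGMENT_END_TRUNCATION,
) -> dict[tuple[str, int], float]:
    """GC fraction of each truncated fragment-end window, keyed by its anchor.

    N bases are ignored in the denominator; a window of only Ns gets NaN.
    """
    out: dict[tuple[str, int], float] = {}
    upper: dict[str, str] = {}
    for frag in fragments:
        seq = upper.get(frag.chrom)
        if seq is None:
            seq = upper[frag.chrom] = str(sequences[frag.chrom]).upper()
        left = seq[frag.start : min(frag.start + end_truncation, frag.end)]
        right = seq[max(frag.end - end_truncation, frag.start) : frag.end]
        out[(frag.chrom, frag.start)] = _gc_fraction(left)
        out[(frag.chrom, frag.end - 1)] = _gc_fraction(right)
    return out


def _gc_fraction(window: str) -> float:
    n_valid = len(window) - window.count("N")
    if n_valid == 0:
        return float("nan")
    return (window.count("G") + window.count("C")) / n_valid


def mappability_of_ends_from_track(
    fragments: Iterable[RestrictionFragment],
    track: pd.DataFrame,
) -> dict[tuple[str, int], float]:
    """Look up a per-interval mappability track at every fragment-end anchor.

    ``track`` needs columns chrom, start, end, value (BED4-like). Anchors not
    covered by any interval get mappability 0.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["value"].to_numpy(float),
        )
    out: dict[tuple[str, int], float] = {}
    for chrom, pos in fragment_end_anchors(fragments):
        if chrom not in by_chrom:
            out[(chrom, pos)] = 0.0
            continue
        starts, ends, values = by_chrom[chrom]
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k >= 0 and pos < ends[k]:
            out[(chrom, pos)] = float(values[k])
        else:
            out[(chrom, pos)] = 0.0
    return out


def compute_bin_features(
    fragments: Iterable[RestrictionFragment],
    grid: BinGrid,
    per_end_gc: Mapping[tuple[str, int], float] | None = None,
    per_end_map: Mapping[tuple[str, int], float] | None = None,
    end_truncation: int = FRAGMENT_END_TRUNCATION,
) -> pd.DataFrame:
    """Accumulate effective fragment length, GC and mappability per bin.

    Returns a frame with one row per bin of the grid (columns chrom, start,
    end, f, gc, m). Bins without any fragment end have ``f`` 0 and ``gc``/
    ``m`` NaN; such bins are invisible to the assay and are excluded from
    regression downstream.
    """
    if end_truncation <= 0:
        raise ValueError("end_truncation must be positive")
    if per_end_map is None:
        logger.warning(
            "no mappability supplied; assuming mappability 1 for all fragment ends"
        )
    fragments = list(fragments)
    res = grid.resolution
    f_arr: dict[str, np.ndarray] = {}
    gc_sum: dict[str, np.ndarray] = {}
    m_sum: dict[str, np.ndarray] = {}
    n_ends: dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        f_arr[chrom] = np.zeros(n)
        gc_sum[chrom] = np.zeros(n)
        m_sum[chrom] = np.zeros(n)
        n_ends[chrom] = np.zeros(n, dtype=int)

    for frag in fragments:
        if frag.chrom not in grid.chrom_sizes:
            raise ValueError(f"fragment on unknown chromosome {frag.chrom!r}")
        if frag.end > grid.chrom_sizes[frag.chrom]:
            raise ValueError(
                f"fragment [{frag.start}, {frag.end}) exceeds length of {frag.chrom!r}"
            )
        f = f_arr[frag.chrom]
        for a, b in _end_cover_intervals(frag, end_truncation):
            for k in range(a // res, (b - 1) // res + 1):
                f[k] += min(b, (k + 1) * res) - max(a, k * res)
        for chrom, pos in fragment_end_anchors([frag]):
            k = pos // res
            gc = float("nan") if per_end_gc is None else per_end_gc[(chrom, pos)]
            m = 1.0 if per_end_map is None else per_end_map[(chrom, pos)]
            if not np.isnan(gc):
                gc_sum[chrom][k] += gc
            m_sum[chrom][k] += m
            n_ends[chrom][k] += 1

    rows = []
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        cnt = n_ends[chrom]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.where(cnt > 0, gc_sum[chrom] / np.maximum(cnt, 1), np.nan)
            m = np.where(cnt > 0, m_sum[chrom] / np.maximum(cnt, 1), np.nan)
        if per_end_gc is None:
            gc = np.full(n, np.nan)
        starts = np.arange(n) * res
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + res, grid.chrom_sizes[chrom]),
                    "f": f_arr[chrom],
                    "gc": gc,
                    "m": m,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def compute_ip_enrichment(short_pairs, grid: BinGrid) -> pd.DataFrame:
    """Count short-range read pairs per bin (ChIP enrichment, ``IP``).

    Each pair increments exactly one bin: the bin containing the midpoint of
    its two end positions, so the total over bins equals the number of input
    pairs. Accepts a DataFrame with columns chrom, pos1, pos2 or an iterable
    of :class:`placloop.pairs.ValidPair`.
    """
    if isinstance(short_pairs, pd.DataFrame):
        chroms = short_pairs["chrom"].to_numpy()
        pos1 = short_pairs["pos1"].to_numpy()
        pos2 = short_pairs["pos2"].to_numpy()
    else:
        chroms, pos1, pos2 = [], [], []
        for pair in short_pairs:
            if pair.end1.chrom != pair.end2.chrom:
                raise ValueError("inter-chromosomal pair in short-range input")
            chroms.append(pair.end1.chrom)
            pos1.append(pair.end1.pos)
            pos2.append(pair.end2.pos)
        chroms = np.asarray(chroms)
        pos1 = np.asarray(pos1, dtype=int)
        pos2 = np.asarray(pos2, dtype=int)
    if len(pos1) and np.abs(pos2 - pos1).max() > 1000:
        raise ValueError("short-range input contains a pair separated by > 1 kb")

    counts = {chrom: np.zeros(grid.n_bins(chrom), dtype=int) for chrom in grid.chroms}
    mid = (np.asarray(pos1) + np.asarray(pos2)) // 2
    for chrom in np.unique(chroms) if len(chroms) else []:
        sel = chroms == chrom
        idx = mid[sel] // grid.resolution
        np.add.at(counts[str(chrom)], idx, 1)

    rows = []
    for chrom in grid.chroms:
        starts = np.arange(grid.n_bins(chrom)) * grid.resolution
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "IP": counts[chrom]})
        )
    return pd.concat(rows, ignore_index=True)


def build_feature_table(
    fragments: Iterable[RestrictionFragment],
    grid: BinGrid,
    per_end_gc: Mapping[tuple[str, int], float] | None = None,
    per_end_map: Mapping[tuple[str, int], float] | None = None,
    short_pairs=None,
    end_truncation: int = FRAGMENT_END_TRUNCATION,
) -> pd.DataFrame:
    """Full per-bin feature table: chrom, start, end, f, gc, m, IP."""
    feats = compute_bin_features(
        fragments, grid, per_end_gc, per_end_map, end_truncation
    )
    if short_pairs is None:
        feats["IP"] = 0
    else:
        ip = compute_ip_enrichment(short_pairs, grid)
        feats = feats.merge(ip, on=["chrom", "start"], how="left")
        feats["IP"] = feats["IP"].fillna(0).astype(int)
    return feats[FEATURE_COLUMNS]
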