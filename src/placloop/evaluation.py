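"""Evaluation statistics for called interaction sets.

Covers the standard downstream checks on loop calls from proximity-ligation
data: overlap between loop sets with a 15 kb slack (reproducibility between
replicates, sensitivity against a deeply sequenced reference), CTCF motif
orientation of loop anchors (convergent / tandem / divergent), enrichment
of cis-regulatory features in the non-anchor bins of XOR interactions
against distance-matched controls, and a rank statistic against an
orthogonal coarse-resolution contact matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError
from .grid import BinGrid

#: Two bin pairs overlap when both anchor offsets are at most this (bp).
DEFAULT_OVERLAP_GAP = 15_000


def _overlap_mask(a: pd.DataFrame, b: pd.DataFrame, gap: int) -> np.ndarray:
    """Boolean per row of ``a``: does any pair of ``b`` lie within ``gap``?

    Loop-set frames carry columns chrom, start1, start2 (bin starts in bp);
    anchors are compared left-with-left and right-with-right.
    """
    out = np.zeros(len(a), dtype=bool)
    for chrom, sub_b in b.groupby("chrom"):
        sel = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        b1 = sub_b["start1"].to_numpy()
        b2 = sub_b["start2"].to_numpy()
        a1 = a["start1"].to_numpy()[sel]
        a2 = a["start2"].to_numpy()[sel]
        hit = (
            (np.abs(a1[:, None] - b1[None, :]) <= gap)
            & (np.abs(a2[:, None] - b2[None, :]) <= gap)
        ).any(axis=1)
        out[sel] = hit
    return out


def pair_overlap(
    pair: tuple[str, int, int],
    loops: pd.DataFrame,
    gap: int = DEFAULT_OVERLAP_GAP,
) -> bool:
    """Does ``(chrom, start1, start2)`` overlap any pair in ``loops``?"""
    chrom, s1, s2 = pair
    a = pd.DataFrame({"chrom": [chrom], "start1": [s1], "start2": [s2]})
    return bool(_overlap_mask(a, loops, gap)[0])


def reproducibility(
    a: pd.DataFrame, b: pd.DataFrame, gap: int = DEFAULT_OVERLAP_GAP
) -> tuple[float, float]:
    """Directional overlap fractions between two loop sets.

    Returns ``(fraction of a found in b, fraction of b found in a)``; each
    is NaN for an empty query set.
    """
    fa = float(_overlap_mask(a, b, gap).mean()) if len(a) else float("nan")
    fb = float(_overlap_mask(b, a, gap).mean()) if len(b) else float("nan")
    return fa, fb


def sensitivity(
    calls: pd.DataFrame,
    reference: pd.DataFrame,
    gap: int = DEFAULT_OVERLAP_GAP,
) -> float:
    """Fraction of (pre-filtered, detectable) reference loops re-discovered."""
    if len(reference) == 0:
        raise UndefinedScoreError("empty reference loop set")
    if len(calls) == 0:
        return 0.0
    return float(_overlap_mask(reference, calls, gap).mean())


@dataclass(frozen=True)
class MotifAnnotation:
    """Per-bin CTCF motif orientation summary.

    ``orientation`` maps (chrom, bin index) to '+', '-' or 'mixed'; absent
    bins have no motif. A bin is testable only when all its motifs point
    one way ('+' or '-').
    """

    orientation: Mapping[tuple[str, int], str]

    @classmethod
    def from_motifs(cls, motifs: pd.DataFrame, grid: BinGrid) -> "MotifAnnotation":
        """Summarize a stranded motif BED (chrom, start, end, strand) per bin.

        A motif is assigned to the bin containing its midpoint.
        """
        strands: dict[tuple[str, int], set] = {}
        for row in motifs.itertuples(index=False):
            if row.chrom not in grid.chrom_sizes:
                continue
            mid = (int(row.start) + int(row.end)) // 2
            key = (row.chrom, mid // grid.resolution)
            strands.setdefault(key, set()).add(row.strand)
        orientation = {
            key: next(iter(s)) if len(s) == 1 else "mixed"
            for key, s in strands.items()
        }
        return cls(orientation)

    def bin_orientation(self, chrom: str, index: int) -> str:
        return self.orientation.get((chrom, index), "none")


def classify_motif_orientation(
    pair: tuple[str, int, int], motifs: MotifAnnotation
) -> str:
    """Orientation class of a bin pair: convergent, tandem, divergent, untestable.

    With left-bin orientation L and right-bin orientation R in genome
    order: (+, -) is convergent (motifs face each other), (-, +) divergent,
    equal strands tandem. Any bin with mixed-direction or no motifs makes
    the pair untestable.
    """
    chrom, i, j = pair
    left = motifs.bin_orientation(chrom, i)
    right = motifs.bin_orientation(chrom, j)
    if left not in ("+", "-") or right not in ("+", "-"):
        return "untestable"
    if left == right:
        return "tandem"
    return "convergent" if left == "+" else "divergent"


def motif_orientation_proportions(
    pairs: pd.DataFrame, motifs: MotifAnnotation
) -> dict[str, float]:
    """Convergent/tandem/divergent proportions among testable bin pairs."""
    counts = {"convergent": 0, "tandem": 0, "divergent": 0}
    for row in pairs.itertuples(index=False):
        cls = classify_motif_orientation((row.chrom, row.bin1, row.bin2), motifs)
        if cls != "untestable":
            counts[cls] += 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedScoreError("no testable bin pairs")
    return {k: v / total for k, v in counts.items()}


def cre_enrichment(
    xor_calls: pd.DataFrame,
    all_calls: pd.DataFrame,
    protein_peaks: pd.DataFrame,
    feature_peaks: pd.DataFrame,
    grid: BinGrid,
    gap: int = DEFAULT_OVERLAP_GAP,
    exclude_interacting_controls: bool = False,
) -> tuple[float, float, float]:
    """Cis-regulatory feature enrichment in XOR target bins vs controls.

    For each XOR call the anchor is its protein-peak bin and the target the
    other bin; the control is the bin at the same distance on the opposite
    side of the anchor. Controls falling off the chromosome or on a
    protein-bound bin are dropped; with ``exclude_interacting_controls``
    the control is also dropped when the (anchor, control) pair overlaps
    any identified interaction. Returns ``(%target, %control, score)``
    where the score is their ratio.
    """
    from .pairs import peak_bins  # local import to avoid a cycle

    protein_bins = peak_bins(protein_peaks, grid)
    feature_bins = peak_bins(feature_peaks, grid)
    res = grid.resolution

    call_loops = pd.DataFrame(
        {
            "chrom": all_calls["chrom"],
            "start1": all_calls["bin1"] * res,
            "start2": all_calls["bin2"] * res,
        }
    )

    n_target_hit = 0
    n_target = 0
    control_hits = []
    for row in xor_calls.itertuples(index=False):
        chrom, i, j = row.chrom, int(row.bin1), int(row.bin2)
        i_peak = i in protein_bins[chrom]
        j_peak = j in protein_bins[chrom]
        if i_peak == j_peak:
            raise ValueError(
                f"bin pair ({chrom}, {i}, {j}) is not an XOR pair under these peaks"
            )
        anchor, target = (i, j) if i_peak else (j, i)
        n_target += 1
        n_target_hit += target in feature_bins[chrom]

        control = 2 * anchor - target
        if control < 0 or control >= grid.n_bins(chrom):
            continue
        if control in protein_bins[chrom]:
            continue
        if exclude_interacting_controls:
            lo, hi = sorted((anchor, control))
            if pair_overlap((chrom, lo * res, hi * res), call_loops, gap):
                continue
        control_hits.append(control in feature_bins[chrom])

    if n_target == 0:
        raise UndefinedScoreError("no XOR calls supplied")
    if not control_hits:
        raise UndefinedScoreError("no usable control bins")
    pct_target = n_target_hit / n_target
    pct_control = float(np.mean(control_hits))
    score = pct_target / pct_control if pct_control > 0 else float("inf")
    return pct_target, pct_control, score


@dataclass(frozen=True)
class SpriteMatrix:
    """A coarse-resolution normalized contact matrix with per-bin peak flags.

    ``matrices[chrom]`` is a dense symmetric-by-construction array indexed
    by bin; ``peak_flags[chrom]`` marks bins containing a ChIP-seq peak.
    """

    matrices: Mapping[str, np.ndarray]
    peak_flags: Mapping[str, np.ndarray]
    resolution: int

    def value(self, chrom: str, i: int, j: int) -> float:
        mat = self.matrices[chrom]
        return float(mat[min(i, j), max(i, j)])

    @classmethod
    def from_triplets(
        cls,
        triplets: pd.DataFrame,
        n_bins: Mapping[str, int],
        peak_bins: Mapping[str, set],
        resolution: int,
    ) -> "SpriteMatrix":
        """Build from a (chrom, bin1, bin2, value) triplet table."""
        matrices = {}
        flags = {}
        for chrom, n in n_bins.items():
            mat = np.zeros((n, n))
            sub = triplets[triplets["chrom"] == chrom]
            for row in sub.itertuples(index=False):
                i, j = int(row.bin1), int(row.bin2)
                mat[min(i, j), max(i, j)] = row.value
            flag = np.zeros(n, dtype=bool)
            flag[list(peak_bins.get(chrom, ()))] = True
            matrices[chrom] = mat
            flags[chrom] = flag
        return cls(matrices, flags, resolution)


def sprite_rank(query: tuple[str, int, int], sprite: SpriteMatrix) -> int:
    """Rank of a bin pair among same-distance, peak-anchored pairs.

    Counts the bin pairs (m, n) on the same chromosome with identical index
    separation ``|m - n|``, at least one peak-flagged bin, and a strictly
    larger matrix value than the query (rank 0 means the query has the
    highest frequency at its distance).
    """
    chrom, i, j = query
    mat = sprite.matrices[chrom]
    flags = sprite.peak_flags[chrom]
    i, j = min(i, j), max(i, j)
    n = mat.shape[0]
    if i < 0 or j >= n:
        raise ValueError(f"query pair ({chrom}, {i}, {j}) outside the matrix")
    s_query = mat[i, j]
    if not np.isfinite(s_query):
        raise ValueError("query bin pair has no matrix value")
    d = j - i
    m = np.arange(n - d)
    vals = mat[m, m + d]
    anchored = flags[m] | flags[m + d]
    return int(np.sum(anchored & (vals > s_query)))


def coarsen_pair(
    pair: tuple[str, int, int], fine_resolution: int, coarse_resolution: int
) -> tuple[str, int, int]:
    """Map a fine-resolution bin pair to the coarse bins containing the
    fine bins' center positions (half-open convention on boundaries)."""
    chrom, i, j = pair
    ci = (i * fine_resolution + fine_resolution // 2) // coarse_resolution
    cj = (j * fine_resolution + fine_resolution // 2) // coarse_resolution
    return chrom, ci, cj
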