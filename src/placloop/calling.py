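"""Significant-interaction calling, clustering, summits, and BEDPE output.

A normalized bin pair is called significant when it simultaneously has a
raw count of at least 12, an observed/expected fold change of at least 2,
and FDR below 0.01 (all user-configurable). Significant bin pairs are then
grouped into clusters: two pairs (i, j) and (m, n) on the same chromosome
are adjacent when both anchor offsets, left-with-left and right-with-right,
are at most 15 kb, and clusters are the connected components of that
adjacency (transitive closure). Components of size one are singletons and
are kept only below a stricter FDR of 1e-4, since isolated significant bin
pairs are more often false positives. Within each cluster, every bin pair
attaining the minimum FDR is flagged as a summit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidRecordError

CALL_COLUMNS = [
    "chrom", "bin1", "bin2", "x", "e_tilde", "q",
    "set", "call_type", "cluster_id", "is_summit",
]

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "count", "expected", "fdr", "call_type", "is_summit",
]


@dataclass(frozen=True)
class CallingThresholds:
    """Significance and clustering thresholds for interaction calling."""

    fdr_max: float = 0.01
    fold_min: float = 2.0
    count_min: int = 12
    singleton_fdr_max: float = 1e-4
    cluster_gap: int = 15_000

    def __post_init__(self) -> None:
        for name in ("fdr_max", "fold_min", "count_min", "singleton_fdr_max",
                     "cluster_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.singleton_fdr_max > self.fdr_max:
            raise ValueError("singleton_fdr_max must not exceed fdr_max")


def flag_significant(
    normalized: pd.DataFrame, thresholds: CallingThresholds | None = None
) -> pd.DataFrame:
    """Subset of normalized bin pairs passing all three significance criteria."""
    t = thresholds or CallingThresholds()
    keep = (
        (normalized["x"] >= t.count_min)
        & (normalized["x"] / normalized["e_tilde"] >= t.fold_min)
        & (normalized["q"] < t.fdr_max)
    )
    if "set" in normalized:
        keep &= normalized["set"] != "NOT"
    return normalized.loc[keep].reset_index(drop=True)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_significant(
    significant: pd.DataFrame,
    resolution: int,
    gap: int = 15_000,
) -> np.ndarray:
    """Connected-component cluster labels for significant bin pairs.

    Pairs (i, j) and (m, n) are adjacent iff they share a chromosome and
    ``max(|start_i - start_m|, |start_j - start_n|) <= gap``; anchors are
    matched left-with-left and right-with-right, never crossed. Labels are
    arbitrary but consistent integers, one per component.
    """
    n = len(significant)
    labels = np.full(n, -1, dtype=int)
    uf = _UnionFind(n)
    s1 = significant["bin1"].to_numpy() * resolution
    s2 = significant["bin2"].to_numpy() * resolution
    chroms = significant["chrom"].to_numpy()
    order = np.lexsort((s2, s1, chroms))
    for a_idx in range(n):
        a = order[a_idx]
        for b_idx in range(a_idx + 1, n):
            b = order[b_idx]
            if chroms[b] != chroms[a] or s1[b] - s1[a] > gap:
                break
            if abs(s2[b] - s2[a]) <= gap:
                uf.union(a, b)
    roots = {}
    for i in range(n):
        root = uf.find(i)
        labels[i] = roots.setdefault(root, len(roots))
    return labels


def finalize_calls(
    significant: pd.DataFrame,
    labels: np.ndarray,
    thresholds: CallingThresholds | None = None,
) -> pd.DataFrame:
    """Apply the singleton filter and flag cluster summits.

    All cluster members are kept. Singletons survive only with FDR below
    ``singleton_fdr_max`` and never carry a summit flag. Within a cluster
    every member achieving the minimum FDR is a summit (ties give multiple
    summits). Cluster ids are renumbered consecutively in genome order.
    """
    t = thresholds or CallingThresholds()
    df = significant.copy()
    df["_label"] = labels
    sizes = df["_label"].map(df["_label"].value_counts())

    singletons = df[(sizes == 1) & (df["q"] < t.singleton_fdr_max)].copy()
    singletons["call_type"] = "singleton"
    singletons["cluster_id"] = pd.NA
    singletons["is_summit"] = 0

    clusters = df[sizes > 1].copy()
    if len(clusters):
        min_q = clusters.groupby("_label")["q"].transform("min")
        clusters["call_type"] = "cluster"
        clusters["is_summit"] = (clusters["q"] == min_q).astype(int)
        ordering = clusters.sort_values(["chrom", "bin1", "bin2"]).drop_duplicates(
            "_label"
        )["_label"]
        renumber = {lab: k for k, lab in enumerate(ordering)}
        clusters["cluster_id"] = clusters["_label"].map(renumber)
    else:
        clusters["call_type"] = pd.Series(dtype=str)
        clusters["cluster_id"] = pd.Series(dtype="Int64")
        clusters["is_summit"] = pd.Series(dtype=int)

    out = pd.concat([clusters, singletons], ignore_index=True)
    out = out.sort_values(["chrom", "bin1", "bin2"], ignore_index=True)
    return out.reindex(columns=CALL_COLUMNS)


def call_interactions(
    normalized: pd.DataFrame,
    resolution: int,
    thresholds: CallingThresholds | None = None,
) -> pd.DataFrame:
    """End-to-end calling: significance filter, clustering, singleton filter."""
    t = thresholds or CallingThresholds()
    sig = flag_significant(normalized, t)
    labels = cluster_significant(sig, resolution, gap=t.cluster_gap)
    return finalize_calls(sig, labels, t)


def write_bedpe(calls: pd.DataFrame, resolution: int, path) -> None:
    """Write calls as 11-field BEDPE.

    Fields: chrom1, start1, end1, chrom2, start2, end2, raw count, expected
    count, FDR (scientific notation, 4 significant digits), interaction
    type (singleton or cluster), and a 0/1 summit flag (0 for every
    singleton). Input is sorted internally by chromosome and bin starts.
    """
    calls = calls.sort_values(["chrom", "bin1", "bin2"])
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            s1 = row.bin1 * resolution
            s2 = row.bin2 * resolution
            if s1 + resolution > s2:
                raise InvalidRecordError(
                    f"overlapping anchor bins {row.bin1}, {row.bin2} on {row.chrom}"
                )
            fields = [
                row.chrom, s1, s1 + resolution,
                row.chrom, s2, s2 + resolution,
                int(row.x), f"{row.e_tilde:.6g}", f"{row.q:.3e}",
                row.call_type, int(row.is_summit),
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


def read_bedpe(path) -> pd.DataFrame:
    """Read the 11-field BEDPE dialect written by :func:`write_bedpe`."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=BEDPE_COLUMNS,
        dtype={
            "chrom1": str, "start1": int, "end1": int,
            "chrom2": str, "start2": int, "end2": int,
            "count": int, "expected": float, "fdr": float,
            "call_type": str, "is_summit": int,
        },
    )
    return df


def loops_from_calls(calls: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Collapse a call table to a loop set (chrom, start1, start2 in bp)."""
    return pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start1": calls["bin1"] * resolution,
            "start2": calls["bin2"] * resolution,
        }
    )
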