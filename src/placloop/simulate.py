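"""Synthetic proximity-ligation fixtures with known ground truth.

The generator emulates a desk-scale PLAC-seq/HiChIP study: a random genome
with block-varying GC composition (which also modulates restriction-site
density and hence effective fragment length), protein-binding peaks on a
random subset of bins, simulated per-fragment-end mappability, ChIP
enrichment expressed as short-range read pairs concentrated at peak bins,
and bin-pair contact counts drawn from the same log-linear Poisson-rate
model the normalization fits, with multiplicative high-fold loops planted
on bin pairs of typical background intensity. Counts are drawn as plain
Poisson and zeros dropped, which is exactly zero-truncated Poisson
sampling conditioned on observing the pair at all.

Per-bin features are computed by running the :mod:`placloop.features`
pipeline on the synthetic genome and short pairs rather than drawn
independently, so the feature code paths are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import features as ft
from .grid import BinGrid
from .pairs import AlignmentRecord, BIN_PAIR_COLUMNS

_BASES = np.frombuffer(b"ATGC", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    ``beta`` is the true coefficient vector (intercept, effective fragment
    length, GC, mappability, ChIP enrichment, distance); an intercept of
    ``None`` is calibrated so the mean background rate over AND/XOR
    candidate pairs equals ``mean_count``. Loops are planted as
    ``loop_span`` x ``loop_span`` blocks of bin pairs, on candidates whose
    background rate lies within ``loop_rate_band`` (multiples of
    ``mean_count``), so the planted fold is the controlled signal.
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_length_bp: int = 10_000_000
    resolution: int = 5_000
    motif: str = "GACGTT"
    n_peaks: int = 300
    beta: tuple = (None, 0.5, 1.0, 1.0, 1.0, -1.0)
    mean_count: float = 4.0
    n_planted_loops: int = 40
    loop_fold: float = 6.0
    loop_span: int = 2
    loop_rate_band: tuple = (0.75, 1.5)
    loop_min_separation: int = 50_000
    d_min: int | None = None
    d_max: int = 1_000_000
    ip_peak_rate: float = 200.0
    ip_background_rate: float = 20.0
    ip_lognorm_sigma: float = 0.8
    gc_range: tuple = (0.30, 0.65)
    mappability_beta: tuple = (2.0, 0.5)

    def __post_init__(self) -> None:
        if self.loop_fold <= 1:
            raise ValueError("loop_fold must exceed 1")
        if len(self.beta) != 6:
            raise ValueError("beta must have 6 entries")

    @property
    def d_min_effective(self) -> int:
        return 2 * self.resolution if self.d_min is None else self.d_min

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What the generator actually used: coefficients, loops, features."""

    beta: np.ndarray
    planted_loops: pd.DataFrame  # loop_id, chrom, bin1, bin2, lam_background
    features: pd.DataFrame

    @property
    def loop_pairs(self) -> pd.DataFrame:
        return self.planted_loops[["chrom", "bin1", "bin2"]]


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    sequences: dict
    peaks: pd.DataFrame
    grid: BinGrid
    features: pd.DataFrame
    bin_pairs: pd.DataFrame
    truth: GroundTruth


def _random_genome(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Random DNA with per-bin GC levels drawn from ``gc_range``."""
    sequences = {}
    lo, hi = cfg.gc_range
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        length = cfg.chrom_length_bp
        n_bins = -(-length // cfg.resolution)
        gc_levels = rng.uniform(lo, hi, n_bins)
        gc = np.repeat(gc_levels, cfg.resolution)[:length]
        r = rng.random(length)
        # cumulative thresholds A | T | G | C with P(G)=P(C)=gc/2
        t1 = (1 - gc) / 2
        t2 = 1 - gc
        t3 = 1 - gc / 2
        idx = (r >= t1).astype(np.int8) + (r >= t2) + (r >= t3)
        sequences[chrom] = _BASES[idx].tobytes().decode()
    return sequences


def simulate_genome_peaks_features(
    cfg: SimulationConfig,
) -> tuple[dict, pd.DataFrame, pd.DataFrame, BinGrid]:
    """Generate genome, peaks and the per-bin feature table.

    Returns ``(sequences, peaks, features, grid)``. Features are produced
    by in-silico digestion of the generated genome plus simulated per-end
    mappability and ChIP short-range pairs, all routed through the feature
    pipeline.
    """
    rng = cfg.rng(1)
    sequences = _random_genome(cfg, rng)
    grid = BinGrid({c: len(s) for c, s in sequences.items()}, cfg.resolution)

    # peaks: n_peaks distinct bins per genome, a 1 kb interval centered in the bin
    peak_rows = []
    all_bins = [(chrom, k) for chrom in grid.chroms for k in range(grid.n_bins(chrom))]
    n_peaks = min(cfg.n_peaks, len(all_bins))
    chosen = rng.choice(len(all_bins), size=n_peaks, replace=False)
    for idx in sorted(chosen):
        chrom, k = all_bins[idx]
        start = k * cfg.resolution
        center = start + cfg.resolution // 2
        half = min(500, cfg.resolution // 2)
        peak_rows.append((chrom, center - half, center + half))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])

    fragments = ft.digest_genome(sequences, cfg.motif)
    per_end_gc = ft.gc_of_fragment_ends(sequences, fragments)
    a, b = cfg.mappability_beta
    per_end_map = {
        anchor: float(v)
        for anchor, v in zip(
            ft.fragment_end_anchors(fragments),
            rng.beta(a, b, size=2 * len(fragments)),
        )
    }

    short_pairs = _simulate_short_pairs(cfg, peaks, grid, rng)
    feats = ft.build_feature_table(
        fragments, grid, per_end_gc, per_end_map, short_pairs=short_pairs
    )
    return sequences, peaks, feats, grid


def _simulate_short_pairs(
    cfg: SimulationConfig,
    peaks: pd.DataFrame,
    grid: BinGrid,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """ChIP short-range pairs: heavy at peak bins, light elsewhere."""
    from .pairs import peak_bins

    pbins = peak_bins(peaks, grid)
    chroms, pos1, pos2 = [], [], []
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        is_peak = np.zeros(n, dtype=bool)
        is_peak[list(pbins[chrom])] = True
        base = np.where(is_peak, cfg.ip_peak_rate, cfg.ip_background_rate)
        rates = base * rng.lognormal(0.0, cfg.ip_lognorm_sigma, n)
        counts = rng.poisson(rates)
        for k in np.flatnonzero(counts):
            c = int(counts[k])
            start = k * cfg.resolution
            lo = max(start, 500)
            hi = max(start + cfg.resolution, lo + 1)
            mid = rng.integers(lo, hi, c)
            d = rng.integers(100, 901, c)
            chroms.extend([chrom] * c)
            pos1.extend((mid - d // 2).tolist())
            pos2.extend((mid + (d - d // 2)).tolist())
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos1": pos1,
            "pos2": pos2,
            "strand1": "+",
            "strand2": "-",
        }
    )


def simulate_bin_pair_counts(
    cfg: SimulationConfig,
    features: pd.DataFrame,
    peaks: pd.DataFrame,
    grid: BinGrid,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw bin-pair counts from the log-linear model with planted loops.

    Candidate pairs are all intra-chromosomal bin pairs with distance in
    ``[d_min, d_max]`` whose two bins have strictly positive covariates.
    The rate of every bin pair belonging to a planted loop block is
    multiplied by ``loop_fold``. Zero counts are dropped.
    """
    from .pairs import peak_bins

    rng = cfg.rng(2)
    res = cfg.resolution
    kmin = -(-cfg.d_min_effective // res)
    kmax = cfg.d_max // res
    pbins = peak_bins(peaks, grid)

    b0, bf, bgc, bm, bip, bd = cfg.beta

    chrom_arr, i_arr, j_arr, eta_arr, npk_arr = [], [], [], [], []
    for chrom in grid.chroms:
        sub = features[features["chrom"] == chrom].sort_values("start")
        f = sub["f"].to_numpy(float)
        gc = sub["gc"].to_numpy(float)
        m = sub["m"].to_numpy(float)
        ip = sub["IP"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            lf, lg, lm, lip = np.log(f), np.log(gc), np.log(m), np.log(ip)
        valid = np.isfinite(lf) & np.isfinite(lg) & np.isfinite(lm) & np.isfinite(lip)
        n = len(sub)
        is_peak = np.zeros(n, dtype=bool)
        is_peak[list(pbins[chrom])] = True
        for k in range(kmin, min(kmax, n - 1) + 1):
            i = np.arange(n - k)
            ok = valid[i] & valid[i + k]
            i = i[ok]
            if i.size == 0:
                continue
            j = i + k
            eta = (
                bf * (lf[i] + lf[j])
                + bgc * (lg[i] + lg[j])
                + bm * (lm[i] + lm[j])
                + bip * (lip[i] + lip[j])
                + bd * np.log(k * res)
            )
            chrom_arr.append(np.full(i.size, chrom, dtype=object))
            i_arr.append(i)
            j_arr.append(j)
            eta_arr.append(eta)
            npk_arr.append(is_peak[i].astype(int) + is_peak[j].astype(int))

    if not i_arr:
        empty = pd.DataFrame(columns=BIN_PAIR_COLUMNS)
        truth = GroundTruth(
            beta=np.asarray([0.0 if b0 is None else b0, bf, bgc, bm, bip, bd]),
            planted_loops=pd.DataFrame(
                columns=["loop_id", "chrom", "bin1", "bin2", "lam_background"]
            ),
            features=features,
        )
        return empty, truth

    chrom_all = np.concatenate(chrom_arr)
    i_all = np.concatenate(i_arr)
    j_all = np.concatenate(j_arr)
    eta_all = np.concatenate(eta_arr)
    npk_all = np.concatenate(npk_arr)
    labels = np.array(["NOT", "XOR", "AND"], dtype=object)[npk_all]
    and_xor = npk_all > 0

    if b0 is None:
        if not and_xor.any():
            raise ValueError("cannot calibrate the intercept: no AND/XOR candidates")
        b0 = float(
            np.log(cfg.mean_count)
            - (logsumexp(eta_all[and_xor]) - np.log(and_xor.sum()))
        )
    lam = np.exp(b0 + eta_all)

    planted = _plant_loops(cfg, chrom_all, i_all, j_all, lam, and_xor, rng)
    if len(planted):
        lam = lam.copy()
        lam[planted["row"].to_numpy()] *= cfg.loop_fold

    x = rng.poisson(lam)
    keep = x >= 1
    bin_pairs = pd.DataFrame(
        {
            "chrom": chrom_all[keep],
            "bin1": i_all[keep],
            "bin2": j_all[keep],
            "x": x[keep],
            "d": (j_all[keep] - i_all[keep]) * res,
            "set": labels[keep],
        }
    ).sort_values(["chrom", "bin1", "bin2"], ignore_index=True)

    truth = GroundTruth(
        beta=np.asarray([b0, bf, bgc, bm, bip, bd], dtype=float),
        planted_loops=planted.drop(columns=["row"]) if len(planted) else
        pd.DataFrame(columns=["loop_id", "chrom", "bin1", "bin2", "lam_background"]),
        features=features,
    )
    return bin_pairs, truth


def _plant_loops(
    cfg: SimulationConfig,
    chrom_all: np.ndarray,
    i_all: np.ndarray,
    j_all: np.ndarray,
    lam: np.ndarray,
    and_xor: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose loop blocks on typical-intensity AND/XOR candidates."""
    if cfg.n_planted_loops == 0:
        return pd.DataFrame(columns=["loop_id", "chrom", "bin1", "bin2",
                                     "lam_background", "row"])
    index = {
        (c, int(a), int(b)): r
        for r, (c, a, b) in enumerate(zip(chrom_all, i_all, j_all))
    }
    lo = cfg.loop_rate_band[0] * cfg.mean_count
    hi = cfg.loop_rate_band[1] * cfg.mean_count
    span = cfg.loop_span
    eligible = np.flatnonzero(and_xor & (lam >= lo) & (lam <= hi))

    chosen: list[int] = []
    members: list[tuple] = []
    min_sep_bins = -(-cfg.loop_min_separation // cfg.resolution)
    for r in rng.permutation(eligible):
        c, i, j = chrom_all[r], int(i_all[r]), int(j_all[r])
        block = [(c, i + a, j + b) for a in range(span) for b in range(span)]
        rows = [index.get(key) for key in block]
        if any(rr is None for rr in rows):
            continue
        if not all(and_xor[rr] for rr in rows):
            continue
        too_close = any(
            chrom_all[cr] == c
            and max(abs(int(i_all[cr]) - i), abs(int(j_all[cr]) - j)) < min_sep_bins
            for cr in chosen
        )
        if too_close:
            continue
        loop_id = len(chosen)
        chosen.append(r)
        for (bc, bi, bj), rr in zip(block, rows):
            members.append((loop_id, bc, bi, bj, float(lam[rr]), int(rr)))
        if len(chosen) == cfg.n_planted_loops:
            break
    return pd.DataFrame(
        members,
        columns=["loop_id", "chrom", "bin1", "bin2", "lam_background", "row"],
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the whole generator: genome, peaks, features, counts, truth."""
    sequences, peaks, feats, grid = simulate_genome_peaks_features(cfg)
    bin_pairs, truth = simulate_bin_pair_counts(cfg, feats, peaks, grid)
    return SimulatedStudy(
        config=cfg,
        sequences=sequences,
        peaks=peaks,
        grid=grid,
        features=feats,
        bin_pairs=bin_pairs,
        truth=truth,
    )


def simulate_alignment_groups(
    seed: int = 0,
    n_two_long: int = 100,
    n_two_short: int = 20,
    n_same_strand_short: int = 5,
    n_single: int = 10,
    n_three_same: int = 10,
    n_three_two: int = 10,
    n_three_three: int = 5,
    n_four: int = 5,
    n_duplicates: int = 10,
) -> tuple[list[AlignmentRecord], dict]:
    """Alignment-record stream with a controlled group-size mixture.

    Emits read groups of 1-4 alignments (including same-chromosome,
    two-chromosome and three-chromosome triples), exact PCR duplicates of
    some valid pairs, and same-strand short-range artifact pairs, at the
    requested counts. Positions are allocated from disjoint blocks so every
    non-duplicate pair is unique. Returns the shuffled records together
    with closed-form expected survivor counts for each preprocessing stage.
    """
    if n_duplicates > n_two_long:
        raise ValueError("cannot duplicate more pairs than n_two_long")
    rng = np.random.default_rng(seed)
    chrom_names = ("chr1", "chr2", "chr3")
    cursors = {c: 1_000 for c in chrom_names}
    records: list[AlignmentRecord] = []
    read_no = 0

    def alloc(chrom: str, width: int = 120_000) -> int:
        pos = cursors[chrom]
        cursors[chrom] += width
        return pos

    def add(read_id: str, chrom: str, pos: int, strand: str = "+") -> None:
        records.append(AlignmentRecord(read_id, chrom, pos, strand, mapq=60))

    def new_id() -> str:
        nonlocal read_no
        read_no += 1
        return f"read{read_no:06d}"

    two_long_groups = []
    for _ in range(n_two_long):
        rid = new_id()
        p = alloc("chr1")
        d = int(rng.integers(1_500, 80_000))
        s1, s2 = rng.choice(["+", "-"], 2)
        add(rid, "chr1", p, s1)
        add(rid, "chr1", p + d, s2)
        two_long_groups.append(("chr1", p, s1, p + d, s2))
    for _ in range(n_two_short):
        rid = new_id()
        p = alloc("chr2")
        add(rid, "chr2", p, "+")
        add(rid, "chr2", p + int(rng.integers(100, 900)), "-")
    for _ in range(n_same_strand_short):
        rid = new_id()
        p = alloc("chr2")
        add(rid, "chr2", p, "+")
        add(rid, "chr2", p + int(rng.integers(100, 900)), "+")
    for _ in range(n_single):
        add(new_id(), "chr3", alloc("chr3"))
    for _ in range(n_three_same):
        rid = new_id()
        p = alloc("chr1")
        add(rid, "chr1", p)
        add(rid, "chr1", p + 1_200, "-")
        add(rid, "chr1", p + 50_000)
    for _ in range(n_three_two):
        rid = new_id()
        p = alloc("chr1")
        add(rid, "chr1", p)
        add(rid, "chr1", p + 300, "-")
        add(rid, "chr2", alloc("chr2"))
    for _ in range(n_three_three):
        rid = new_id()
        for chrom in chrom_names:
            add(rid, chrom, alloc(chrom))
    for _ in range(n_four):
        rid = new_id()
        for _k in range(4):
            add(rid, "chr3", alloc("chr3"))
    dup_of = rng.choice(n_two_long, size=n_duplicates, replace=False)
    for g in dup_of:
        rid = new_id()
        chrom, p1, s1, p2, s2 = two_long_groups[g]
        add(rid, chrom, p1, s1)
        add(rid, chrom, p2, s2)

    expected = {
        "valid_pairs": n_two_long + n_two_short + n_same_strand_short
        + n_three_same + n_three_two + n_duplicates,
        "unique_pairs": n_two_long + n_two_short + n_same_strand_short
        + n_three_same + n_three_two,
        "short_pairs": n_two_short,
        "long_pairs": n_two_long + n_three_same,
        "discarded_groups": n_single + n_three_three + n_four,
    }
    order = rng.permutation(len(records))
    return [records[k] for k in order], expected
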