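"""Distance-constrained TF-pair cooperativity scoring.

Two binding sites of different factors co-occur when the edge-to-edge gap
between their intervals lies inside a distance window (default 5–20 bp, the
spacing range compatible with direct protein–protein contact between DNA-bound
factors).  Pair co-occurrence frequencies across a promoter set yield a
pointwise mutual information score per unordered TF pair,

    PMI(a;b) = log2( p_ab / (p_a * p_b) ),

with p_ab the pair's share of all co-occurrence events and p_a, p_b the
factors' shares of all binding sites.  Sequence composition alone (GC content,
dinucleotide skew) produces background co-occurrence, so each promoter is
dinucleotide-preserving shuffled and rescanned; the mean background PMI over
shuffle replicates is subtracted with a scaling factor alpha:

    PMIcor(a;b) = PMI(a;b) - (1 + alpha) * AVG(PMI(a;b)),    alpha in [-1, 1].

PMIcor values are z-transformed over all scored pairs and a pair is called
significant at z >= 3.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif_library import PWM
from .promoters import PromoterSequence
from .site_scanner import BindingSite, ScanProfile, scan_corpus
from .synthetic_data import dinucleotide_shuffle

__all__ = [
    "PairKey",
    "PairStatistics",
    "ScoringConfig",
    "enumerate_pairs",
    "count_sites_per_tf",
    "pmi",
    "background_avg_pmi",
    "pmi_cor",
    "zscore_transform",
    "significant_pairs",
    "score_corpus",
    "write_pairs_tsv",
    "read_pairs_tsv",
]


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonicalized unordered TF pair (tf_a <= tf_b lexicographically).

    Homotypic keys (tf_a == tf_b) are representable but excluded from scoring
    by default; ``ScoringConfig.allow_homotypic`` restores them.
    """

    tf_a: str
    tf_b: str

    def __post_init__(self) -> None:
        if self.tf_a > self.tf_b:
            a, b = self.tf_b, self.tf_a
            object.__setattr__(self, "tf_a", a)
            object.__setattr__(self, "tf_b", b)

    @property
    def homotypic(self) -> bool:
        return self.tf_a == self.tf_b

    def __str__(self) -> str:
        return f"{self.tf_a}-{self.tf_b}"


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the pair-scoring stage.

    ``d_min``/``d_max`` bound the edge-to-edge gap in bp; ``alpha`` scales the
    background subtraction; ``n_shuffles`` sets the number of shuffled-corpus
    replicates for the background estimate; ``log_base`` fixes the PMI
    logarithm.  ``distance_mode`` may be ``edge`` (gap between intervals,
    default) or ``center`` (center-to-center).
    """

    d_min: int = 5
    d_max: int = 20
    alpha: float = 0.2
    z_threshold: float = 3.0
    n_shuffles: int = 10
    log_base: float = 2.0
    seed: int = 0
    allow_homotypic: bool = False
    distance_mode: str = "edge"

    def __post_init__(self) -> None:
        if not 0 <= self.d_min <= self.d_max:
            raise ValueError(f"need 0 <= d_min <= d_max, got [{self.d_min}, {self.d_max}]")
        if not -1.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [-1, +1], got {self.alpha}")
        if self.n_shuffles < 0:
            raise ValueError("n_shuffles must be >= 0")
        if self.log_base <= 1.0:
            raise ValueError("log_base must be > 1")
        if self.distance_mode not in ("edge", "center"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass(frozen=True)
class PairStatistics:
    """Full per-pair record: counts, PMI, background, PMIcor, z."""

    key: PairKey
    f_ab: int
    f_a: int
    f_b: int
    pmi: float
    avg_background_pmi: float
    pmi_cor: float
    z: float = math.nan


def site_distance(s: BindingSite, t: BindingSite, mode: str = "edge") -> float:
    """Distance between two sites in the same promoter.

    ``edge``: ``max(start) - min(end)`` — the gap between the intervals,
    negative when they overlap.  ``center``: distance between midpoints.
    """
    if mode == "edge":
        return max(s.start, t.start) - min(s.end, t.end)
    return abs((s.start + s.end) / 2 - (t.start + t.end) / 2)


def enumerate_pairs(
    sites: Sequence[BindingSite],
    config: ScoringConfig = ScoringConfig(),
) -> list[tuple[PairKey, str, float]]:
    """Emit every heterotypic site pair whose distance falls in [d_min, d_max].

    Sites are grouped by promoter; within a promoter every unordered pair of
    sites with different tf_name is tested.  Homotypic pairs (same tf_name,
    any matrix) are skipped unless ``allow_homotypic``; those are keyed by the
    shared name and excluded from PairKey canonicalization, so the default
    path never constructs them.

    Returns (pair key, promoter_id, distance) tuples; the same pair may be
    emitted many times (once per qualifying site pair).
    """
    by_promoter: dict[str, list[BindingSite]] = {}
    for s in sites:
        by_promoter.setdefault(s.promoter_id, []).append(s)

    out: list[tuple[PairKey, str, float]] = []
    for promoter_id, plist in by_promoter.items():
        if config.distance_mode == "edge" and not config.allow_homotypic:
            out.extend(_enumerate_edge_fast(plist, promoter_id, config))
            continue
        for i in range(len(plist)):
            for j in range(i + 1, len(plist)):
                s, t = plist[i], plist[j]
                if s.tf_name == t.tf_name and not config.allow_homotypic:
                    continue
                d = site_distance(s, t, config.distance_mode)
                if config.d_min <= d <= config.d_max:
                    out.append((PairKey(s.tf_name, t.tf_name), promoter_id, d))
    return out


def _enumerate_edge_fast(
    plist: list[BindingSite], promoter_id: str, config: ScoringConfig
) -> list[tuple[PairKey, str, float]]:
    """Sorted-sweep equivalent of the double loop for the edge-gap metric.

    With sites ordered by start, a qualifying pair (gap >= d_min >= 0) always
    has the later site's start in [earlier.end + d_min, earlier.end + d_max],
    and the gap formula max(start) - min(end) reduces to that difference.
    """
    order = sorted(range(len(plist)), key=lambda i: plist[i].start)
    starts = np.array([plist[i].start for i in order])
    out: list[tuple[PairKey, str, float]] = []
    for pos, i in enumerate(order):
        s = plist[i]
        lo = np.searchsorted(starts, s.end + config.d_min, side="left")
        hi = np.searchsorted(starts, s.end + config.d_max, side="right")
        for pos2 in range(max(lo, pos + 1), hi):
            t = plist[order[pos2]]
            if t.tf_name == s.tf_name:
                continue
            out.append((PairKey(s.tf_name, t.tf_name), promoter_id, float(t.start - s.end)))
    return out


def count_sites_per_tf(sites: Iterable[BindingSite]) -> Counter:
    """Total binding-site count per TF over the promoter set."""
    return Counter(s.tf_name for s in sites)


def pmi(
    pair_occurrences: Iterable[tuple[PairKey, str, float]] | Mapping[PairKey, int],
    site_counts: Mapping[str, int],
    log_base: float = 2.0,
) -> dict[PairKey, float]:
    """Pointwise mutual information per pair.

    p_ab normalizes a pair's co-occurrence count by the total number of
    co-occurrence events; p_a normalizes a factor's site count by the total
    site count.  Pairs never observed get no PMI entry (they are excluded,
    not assigned -inf).
    """
    if isinstance(pair_occurrences, Mapping):
        pair_counts = Counter(pair_occurrences)
    else:
        pair_counts = Counter(key for key, _, _ in pair_occurrences)
    f_pairs = sum(pair_counts.values())
    if f_pairs == 0:
        raise ValueError("no co-occurrences under distance constraints")
    f_sites = sum(site_counts.values())
    log = math.log(log_base)
    out: dict[PairKey, float] = {}
    for key, f_ab in pair_counts.items():
        p_ab = f_ab / f_pairs
        p_a = site_counts[key.tf_a] / f_sites
        p_b = site_counts[key.tf_b] / f_sites
        out[key] = math.log(p_ab / (p_a * p_b)) / log
    return out


def background_avg_pmi(
    promoters: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    profile: ScanProfile,
    config: ScoringConfig,
    rng: np.random.Generator | None = None,
) -> dict[PairKey, float]:
    """AVG(PMI) per pair from dinucleotide-preserving shuffled promoters.

    Each of ``n_shuffles`` replicates shuffles every promoter, rescans and
    rescores it; a pair absent from a replicate (or from every replicate)
    contributes PMI = 0 there — no background co-occurrence means zero
    background cooperation, leaving PMIcor = PMI for such pairs.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sums: dict[PairKey, float] = {}
    n = max(config.n_shuffles, 1)
    for _ in range(config.n_shuffles):
        shuffled = [
            PromoterSequence(
                gene_id=p.gene_id,
                chrom=p.chrom,
                start=p.start,
                end=p.end,
                strand=p.strand,
                sequence=dinucleotide_shuffle(p.sequence, rng),
            )
            for p in promoters
        ]
        sites = scan_corpus(shuffled, pwms, profile)
        occ = enumerate_pairs(sites, config)
        if not occ:
            continue
        rep_pmi = pmi(occ, count_sites_per_tf(sites), config.log_base)
        for key, value in rep_pmi.items():
            sums[key] = sums.get(key, 0.0) + value
    return {key: total / n for key, total in sums.items()}


def pmi_cor(pmi_value: float, avg_value: float, alpha: float) -> float:
    """Background-corrected PMI: pmi − (1 + alpha)·avg."""
    if not -1.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [-1, +1], got {alpha}")
    return pmi_value - (1.0 + alpha) * avg_value


def zscore_transform(values: Mapping[PairKey, float]) -> dict[PairKey, float]:
    """Population z-scores of PMIcor over all scored pairs.

    If every value is identical (sd = 0) all z are 0.
    """
    if len(values) < 2:
        raise ValueError(f"need >= 2 scored pairs for a z-transform, got {len(values)}")
    keys = list(values)
    x = np.array([values[k] for k in keys], dtype=float)
    sd = x.std()  # population (ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):  # all values identical
        return {k: 0.0 for k in keys}
    mean = x.mean()
    return {k: float((values[k] - mean) / sd) for k in keys}


def significant_pairs(
    stats: Sequence[PairStatistics],
    config: ScoringConfig = ScoringConfig(),
) -> list[PairStatistics]:
    """Pairs with z >= threshold (inclusive), sorted by descending z then key."""
    hits = [s for s in stats if s.z >= config.z_threshold]
    hits.sort(key=lambda s: (-s.z, s.key))
    return hits


def score_corpus(
    promoters: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    profile: ScanProfile = ScanProfile(),
    config: ScoringConfig = ScoringConfig(),
    sites: Sequence[BindingSite] | None = None,
    rng: np.random.Generator | None = None,
) -> list[PairStatistics]:
    """Full scoring pipeline for one promoter set.

    Scans (unless ``sites`` is supplied), enumerates distance-constrained
    co-occurrences, computes PMI, estimates the shuffled background, applies
    the PMIcor correction and the z-transform.  Returns one record per scored
    pair, sorted by descending z then pair key.
    """
    if sites is None:
        sites = scan_corpus(promoters, pwms, profile)
    occurrences = enumerate_pairs(sites, config)
    site_counts = count_sites_per_tf(sites)
    fg_pmi = pmi(occurrences, site_counts, config.log_base)
    bg_avg = background_avg_pmi(promoters, pwms, profile, config, rng=rng)
    pair_counts = Counter(key for key, _, _ in occurrences)
    corrected = {
        key: pmi_cor(fg_pmi[key], bg_avg.get(key, 0.0), config.alpha) for key in fg_pmi
    }
    if len(corrected) >= 2:
        z = zscore_transform(corrected)
    else:
        z = {key: math.nan for key in corrected}
    stats = [
        PairStatistics(
            key=key,
            f_ab=pair_counts[key],
            f_a=site_counts[key.tf_a],
            f_b=site_counts[key.tf_b],
            pmi=fg_pmi[key],
            avg_background_pmi=bg_avg.get(key, 0.0),
            pmi_cor=corrected[key],
            z=z[key],
        )
        for key in fg_pmi
    ]
    stats.sort(key=lambda s: (-(s.z if not math.isnan(s.z) else -math.inf), s.key))
    return stats


_PAIR_COLUMNS = [
    "tf_a", "tf_b", "f_ab", "f_a", "f_b",
    "pmi", "avg_pmi", "pmi_cor", "z", "significant",
]


def write_pairs_tsv(
    stats: Iterable[PairStatistics],
    path: str | Path,
    z_threshold: float = 3.0,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PAIR_COLUMNS)
        for s in stats:
            w.writerow(
                [s.key.tf_a, s.key.tf_b, s.f_ab, s.f_a, s.f_b,
                 repr(s.pmi), repr(s.avg_background_pmi), repr(s.pmi_cor),
                 repr(s.z), int(s.z >= z_threshold)]
            )


def read_pairs_tsv(path: str | Path) -> list[PairStatistics]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                PairStatistics(
                    key=PairKey(row["tf_a"], row["tf_b"]),
                    f_ab=int(row["f_ab"]),
                    f_a=int(row["f_a"]),
                    f_b=int(row["f_b"]),
                    pmi=float(row["pmi"]),
                    avg_background_pmi=float(row["avg_pmi"]),
                    pmi_cor=float(row["pmi_cor"]),
                    z=float(row["z"]),
                )
            )
    return out
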