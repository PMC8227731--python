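"""Synthetic promoter corpora with known ground truth.

A corpus emulates the statistical structure the cooperativity statistic
assumes: a set of ~600 bp promoter windows of controlled background
composition, a subset of which carries a planted cooperative motif pair —
one site sampled from each of two PWMs, separated by a gap drawn uniformly
from the scoring distance window (default 5–20 bp) — plus decoy motifs placed
independently of one another so their pairwise cooperation is a true null.

The module also provides the Eulerian-path dinucleotide-preserving shuffle
used by the background correction: a uniformly sampled permutation of the
sequence that conserves every adjacent-base (dinucleotide) count exactly,
hence mono- and dinucleotide composition, GC content and GC skew.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motif_library import PWM
from .promoters import PromoterSequence
from .site_scanner import revcomp

__all__ = [
    "SyntheticSpec",
    "PlantedPair",
    "Decoy",
    "generate_corpus",
    "dinucleotide_shuffle",
    "evaluate_recovery",
]

_BASES = "ACGT"
#: AT-rich default reflecting a vertebrate (e.g. teleost) promoter neighbourhood
DEFAULT_BACKGROUND = {"A": 0.315, "C": 0.185, "G": 0.185, "T": 0.315}


@dataclass(frozen=True)
class PlantedPair:
    """A cooperative motif pair planted into a fraction of promoters.

    ``penetrance`` is the fraction of promoters that receive one site of each
    PWM, separated by a gap drawn uniformly from ``gap_range`` (inclusive).
    Site bases are sampled from the PWM frequencies, not the consensus, so
    scan scores vary realistically; each site lands on a random strand.
    """

    pwm_a: PWM
    pwm_b: PWM
    penetrance: float
    gap_range: tuple[int, int] = (5, 20)

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if self.gap_range[0] > self.gap_range[1] or self.gap_range[0] < 0:
            raise ValueError(f"bad gap_range {self.gap_range}")
        if self.pwm_a.tf_name == self.pwm_b.tf_name:
            raise ValueError("planted pair must be heterotypic")


@dataclass(frozen=True)
class Decoy:
    """An independently placed motif; ``rate`` is the Poisson mean number of
    sites per promoter."""

    pwm: PWM
    rate: float = 0.5

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("decoy rate must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Geometry and composition of a synthetic corpus.

    Defaults (200 promoters x 600 bp) mirror the −500/+100 promoter window and
    a study-scale candidate gene count.
    """

    n_promoters: int = 200
    length: int = 600
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    planted_pairs: tuple[PlantedPair, ...] = ()
    decoys: tuple[Decoy, ...] = ()
    seed: int = 0
    retry_cap: int = 200

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.length < 1:
            raise ValueError("need n_promoters >= 1 and length >= 1")
        keys = list(self.background)
        if all(len(k) == 1 for k in keys):
            total = sum(self.background.get(b, 0.0) for b in _BASES)
        elif all(len(k) == 2 for k in keys):
            total = sum(self.background.values())
        else:
            raise ValueError("background keys must be all mono- or all dinucleotides")
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"background frequencies sum to {total}, not 1")


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw a binding-site realization from the PWM's positional frequencies."""
    cum = pwm.frequencies.cumsum(axis=1)
    u = rng.random(pwm.length)
    idx = (u[:, None] > cum).sum(axis=1)
    return "".join(_BASES[i] for i in idx)


def _place(
    occupied: list[tuple[int, int]], span: int, length: int, rng: np.random.Generator,
    retry_cap: int,
) -> int | None:
    """Uniform random feasible offset for a span avoiding occupied intervals."""
    if span > length:
        return None
    for _ in range(retry_cap):
        start = int(rng.integers(0, length - span + 1))
        end = start + span
        if all(end <= s or start >= e for s, e in occupied):
            return start
    return None


def _markov_background(
    dinuc: dict, n: int, L: int, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov sampler matching a target dinucleotide table."""
    joint = np.zeros((4, 4))
    for k, v in dinuc.items():
        joint[_BASES.index(k[0]), _BASES.index(k[1])] = v
    marginal = joint.sum(axis=1)
    marginal = marginal / marginal.sum()
    with np.errstate(invalid="ignore"):
        trans = np.where(
            joint.sum(axis=1, keepdims=True) > 0,
            joint / np.maximum(joint.sum(axis=1, keepdims=True), 1e-300),
            0.25,
        )
    out = np.empty((n, L), dtype=np.int64)
    out[:, 0] = rng.choice(4, size=n, p=marginal)
    for j in range(1, L):
        u = rng.random(n)
        cum = trans[out[:, j - 1]].cumsum(axis=1)
        out[:, j] = (u[:, None] > cum).sum(axis=1)
    return out


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[PromoterSequence], pd.DataFrame]:
    """Generate promoters plus a truth table of every planted site.

    The truth table has one row per planted site with columns promoter_id,
    tf_name, pwm_id, start, end, strand, role ("pair" or "decoy"), pair_id
    (index into ``spec.planted_pairs``, -1 for decoys) and gap (the planted
    pair's gap, repeated on both members; NaN for decoys).  Placements never
    overwrite previously planted sites; an infeasible placement after the
    retry cap raises, naming the promoter.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_promoters, spec.length
    ids = [f"synth{i + 1:03d}" for i in range(n)]

    if all(len(k) == 1 for k in spec.background):
        probs = np.array([spec.background[b] for b in _BASES])
        base_idx = rng.choice(4, size=(n, L), p=probs)
    else:
        base_idx = _markov_background(spec.background, n, L, rng)
    seqs = [list("".join(_BASES[j] for j in row)) for row in base_idx]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    rows: list[dict] = []

    for pair_id, pair in enumerate(spec.planted_pairs):
        n_carriers = int(round(pair.penetrance * n))
        carriers = rng.choice(n, size=n_carriers, replace=False)
        for pi in sorted(carriers):
            gap = int(rng.integers(pair.gap_range[0], pair.gap_range[1] + 1))
            la, lb = pair.pwm_a.length, pair.pwm_b.length
            span = la + gap + lb
            start = _place(occupied[pi], span, L, rng, spec.retry_cap)
            if start is None:
                raise RuntimeError(
                    f"promoter {ids[pi]}: no feasible placement for planted pair "
                    f"{pair.pwm_a.tf_name}-{pair.pwm_b.tf_name} (span {span})"
                )
            for pwm, s0 in ((pair.pwm_a, start), (pair.pwm_b, start + la + gap)):
                word = _sample_site(pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = word if strand == "+" else revcomp(word)
                seqs[pi][s0 : s0 + pwm.length] = inserted
                occupied[pi].append((s0, s0 + pwm.length))
                rows.append(
                    dict(
                        promoter_id=ids[pi], tf_name=pwm.tf_name, pwm_id=pwm.id,
                        start=s0, end=s0 + pwm.length, strand=strand,
                        role="pair", pair_id=pair_id, gap=gap,
                    )
                )

    for decoy in spec.decoys:
        counts = rng.poisson(decoy.rate, size=n)
        for pi in range(n):
            for _ in range(counts[pi]):
                start = _place(occupied[pi], decoy.pwm.length, L, rng, spec.retry_cap)
                if start is None:
                    raise RuntimeError(
                        f"promoter {ids[pi]}: no feasible placement for decoy "
                        f"{decoy.pwm.tf_name}"
                    )
                word = _sample_site(decoy.pwm, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                inserted = word if strand == "+" else revcomp(word)
                seqs[pi][start : start + decoy.pwm.length] = inserted
                occupied[pi].append((start, start + decoy.pwm.length))
                rows.append(
                    dict(
                        promoter_id=ids[pi], tf_name=decoy.pwm.tf_name,
                        pwm_id=decoy.pwm.id, start=start,
                        end=start + decoy.pwm.length, strand=strand,
                        role="decoy", pair_id=-1, gap=np.nan,
                    )
                )

    promoters = [
        PromoterSequence(
            gene_id=ids[i], chrom=f"synthetic_{ids[i]}", start=0, end=L,
            strand="+", sequence="".join(seqs[i]),
        )
        for i in range(n)
    ]
    columns = ["promoter_id", "tf_name", "pwm_id", "start", "end", "strand",
               "role", "pair_id", "gap"]
    truth = pd.DataFrame(rows, columns=columns)
    return promoters, truth


def dinucleotide_shuffle(seq: str, rng: np.random.Generator | int) -> str:
    """Uniform dinucleotide-preserving shuffle (Eulerian-path construction).

    The sequence is viewed as an Eulerian path in the multigraph whose edges
    are its dinucleotides.  A random last-exit edge per vertex is drawn and
    accepted only if the last-exit edges form an arborescence into the final
    vertex (rejection sampling — uniform over arborescences, hence uniform
    over dinucleotide-preserving arrangements); remaining out-edges are then
    permuted freely and the path is walked.  First and last characters are
    preserved, as the construction requires.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if len(seq) < 2:
        return seq
    seq = seq.upper()
    vertices = sorted(set(seq))
    out_edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(seq, seq[1:]):
        out_edges[a].append(b)
    last = seq[-1]

    non_sink = [v for v in vertices if v != last and out_edges[v]]
    while True:
        last_exit = {v: out_edges[v][rng.integers(len(out_edges[v]))] for v in non_sink}
        ok = True
        for v in non_sink:
            # follow last-exit pointers; must reach the sink
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out_edges[v])
        if v in last_exit:
            edges.remove(last_exit[v])
        perm = rng.permutation(len(edges))
        edges = [edges[i] for i in perm]
        if v in last_exit:
            edges.append(last_exit[v])
        shuffled[v] = edges

    next_idx = {v: 0 for v in vertices}
    path = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][next_idx[cur]]
        next_idx[cur] += 1
        path.append(nxt)
        cur = nxt
    return "".join(path)


def evaluate_recovery(
    pairs_table: Sequence, truth: pd.DataFrame, z_threshold: float = 3.0
) -> dict:
    """Score a pair-statistics table against the planted ground truth.

    Returns a dict with ``planted`` (per planted pair: the two TF names, z,
    rank by z among all scored pairs, significance flag, or None values when
    the pair was not scored) and ``false_positives`` — significant pairs that
    are neither planted nor share a TF with any planted pair.
    """
    from .coop_score import PairKey  # local import to avoid a cycle

    ranked = sorted(
        pairs_table,
        key=lambda s: (-(s.z if s.z == s.z else float("-inf")), s.key),
    )
    rank_of = {s.key: r + 1 for r, s in enumerate(ranked)}
    by_key = {s.key: s for s in pairs_table}

    planted_keys: list[PairKey] = []
    planted_tfs: set[str] = set()
    if len(truth):
        pair_rows = truth[truth["role"] == "pair"]
        for pair_id, grp in pair_rows.groupby("pair_id"):
            tfs = sorted(grp["tf_name"].unique())
            if len(tfs) == 2:
                planted_keys.append(PairKey(tfs[0], tfs[1]))
                planted_tfs.update(tfs)

    planted_report = []
    for key in planted_keys:
        stat = by_key.get(key)
        planted_report.append(
            dict(
                tf_a=key.tf_a,
                tf_b=key.tf_b,
                z=(stat.z if stat else None),
                rank=rank_of.get(key),
                significant=(stat is not None and stat.z >= z_threshold),
            )
        )

    false_positives = [
        s for s in pairs_table
        if s.z >= z_threshold
        and s.key not in planted_keys
        and s.key.tf_a not in planted_tfs
        and s.key.tf_b not in planted_tfs
    ]
    return dict(
        planted=planted_report,
        false_positives=[str(s.key) for s in false_positives],
        n_scored=len(by_key),
        n_significant=sum(1 for s in pairs_table if s.z >= z_threshold),
    )
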