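"""MATCH-style prediction of transcription factor binding sites (TFBSs).

Every PWM is slid over each promoter and its reverse complement.  A window is
scored by information-weighted, min–max-normalized similarity

    score = (Current − Min) / (Max − Min)

with Current = Σ_i I(i)·f(i, base_i), where I is the per-position information
vector and f the PWM frequencies; Max and Min substitute the per-position
best and worst base.  Two scores gate a hit: the matrix score over the full
matrix and the core score over the 5 most conserved consecutive positions.
An N base contributes the position's minimum frequency, so Ns penalize and
never create sites.

Scanning is vectorized over all window offsets of a promoter at once; the
per-window arithmetic is deliberately simple so a brute-force reimplementation
can serve as an exact oracle in tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .motif_library import PWM, core_positions, information_vector
from .promoters import PromoterSequence

__all__ = [
    "BindingSite",
    "ScanProfile",
    "matrix_similarity",
    "core_similarity",
    "scan_promoter",
    "scan_corpus",
    "write_sites_tsv",
    "read_sites_tsv",
    "write_sites_bed",
]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, anything else → 4 (N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


@dataclass(frozen=True)
class ScanProfile:
    """Cut-off profile gating site calls.

    Defaults (core 0.75, matrix 0.80) are conventional conservative values;
    both may be overridden per matrix via ``per_matrix`` keyed by PWM id.
    """

    core_cutoff: float = 0.75
    matrix_cutoff: float = 0.80
    per_matrix: dict | None = None

    def __post_init__(self) -> None:
        for name in ("core_cutoff", "matrix_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def cutoffs_for(self, pwm_id: str) -> tuple[float, float]:
        if self.per_matrix and pwm_id in self.per_matrix:
            return self.per_matrix[pwm_id]
        return (self.core_cutoff, self.matrix_cutoff)


@dataclass(frozen=True)
class BindingSite:
    """One predicted TFBS in forward-strand promoter coordinates."""

    tf_name: str
    pwm_id: str
    promoter_id: str
    start: int
    end: int
    strand: str
    core_score: float
    matrix_score: float


class _ScanMatrix:
    """Precomputed score tables for one PWM (shared across promoters).

    Column 4 of ``weights`` holds the N contribution (the per-position
    minimum), which equals the Min term, so an N adds nothing above Min.
    """

    def __init__(self, pwm: PWM):
        self.pwm = pwm
        f = pwm.frequencies
        info = information_vector(pwm)
        w = info[:, None] * f
        self.weights = np.column_stack([w, w.min(axis=1)])
        self.core = core_positions(pwm)
        self.max_terms = w.max(axis=1)
        self.min_terms = w.min(axis=1)

    def scores(self, codes: np.ndarray, lo: int, hi: int) -> np.ndarray:
        """Min–max-normalized scores restricted to matrix positions [lo, hi)
        for every window offset in ``codes`` (shape n_offsets x L)."""
        cur = np.take_along_axis(
            self.weights[lo:hi], codes[:, lo:hi].T.astype(np.intp), axis=1
        ).sum(axis=0)
        max_s = self.max_terms[lo:hi].sum()
        min_s = self.min_terms[lo:hi].sum()
        if max_s - min_s <= 0.0:
            return np.zeros(codes.shape[0])
        return (cur - min_s) / (max_s - min_s)


def _window_scores(pwm: PWM, codes2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sm = _ScanMatrix(pwm)
    matrix = sm.scores(codes2d, 0, pwm.length)
    lo, hi = sm.core
    core = sm.scores(codes2d, lo, hi)
    return core, matrix


def matrix_similarity(pwm: PWM, window: str) -> float:
    """MATCH matrix similarity of one window (in [0, 1])."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    codes = _encode(window)[None, :]
    return float(_window_scores(pwm, codes)[1][0])


def core_similarity(pwm: PWM, window: str) -> float:
    """Matrix similarity restricted to the 5-bp core positions."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    codes = _encode(window)[None, :]
    return float(_window_scores(pwm, codes)[0][0])


def _sliding(codes: np.ndarray, L: int) -> np.ndarray:
    if len(codes) < L:
        return np.empty((0, L), dtype=codes.dtype)
    return np.lib.stride_tricks.sliding_window_view(codes, L)


def scan_promoter(
    promoter: PromoterSequence,
    pwms: Sequence[PWM],
    profile: ScanProfile = ScanProfile(),
) -> list[BindingSite]:
    """Predict sites for every PWM on both strands of one promoter.

    Minus-strand hits are reported in forward coordinates (a hit at offset j
    of the reverse complement maps to ``[n - j - L, n - j)``).  Output is
    sorted by (start, end, tf_name, strand) for reproducibility.
    """
    seq = promoter.sequence
    n = len(seq)
    fwd = _encode(seq)
    rev = _encode(revcomp(seq))
    sites: list[BindingSite] = []
    for pwm in pwms:
        L = pwm.length
        core_cut, mat_cut = profile.cutoffs_for(pwm.id)
        sm = _ScanMatrix(pwm)
        for strand, codes in (("+", fwd), ("-", rev)):
            windows = _sliding(codes, L)
            if windows.shape[0] == 0:
                continue
            mat = sm.scores(windows, 0, L)
            lo, hi = sm.core
            core = sm.scores(windows, lo, hi)
            hits = np.nonzero((core >= core_cut) & (mat >= mat_cut))[0]
            for j in hits:
                start = int(j) if strand == "+" else n - int(j) - L
                sites.append(
                    BindingSite(
                        tf_name=pwm.tf_name,
                        pwm_id=pwm.id,
                        promoter_id=promoter.gene_id,
                        start=start,
                        end=start + L,
                        strand=strand,
                        core_score=round(float(core[j]), 6),
                        matrix_score=round(float(mat[j]), 6),
                    )
                )
    sites.sort(key=lambda s: (s.start, s.end, s.tf_name, s.strand))
    return sites


def scan_corpus(
    promoters: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    profile: ScanProfile = ScanProfile(),
) -> list[BindingSite]:
    """Scan every promoter; concatenated site lists in promoter order."""
    out: list[BindingSite] = []
    for p in promoters:
        out.extend(scan_promoter(p, pwms, profile))
    return out


_SITE_COLUMNS = [
    "promoter_id",
    "tf_name",
    "pwm_id",
    "start",
    "end",
    "strand",
    "core_score",
    "matrix_score",
]


def write_sites_tsv(sites: Iterable[BindingSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SITE_COLUMNS)
        for s in sites:
            w.writerow(
                [s.promoter_id, s.tf_name, s.pwm_id, s.start, s.end, s.strand,
                 f"{s.core_score:.6f}", f"{s.matrix_score:.6f}"]
            )


def read_sites_tsv(path: str | Path) -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sites.append(
                BindingSite(
                    tf_name=row["tf_name"],
                    pwm_id=row["pwm_id"],
                    promoter_id=row["promoter_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    core_score=float(row["core_score"]),
                    matrix_score=float(row["matrix_score"]),
                )
            )
    return sites


def write_sites_bed(sites: Iterable[BindingSite], path: str | Path) -> None:
    """BED6 export: name = tf_name, score = round(1000 * matrix_score)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.promoter_id}\t{s.start}\t{s.end}\t{s.tf_name}\t"
                f"{round(1000 * s.matrix_score)}\t{s.strand}\n"
            )
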