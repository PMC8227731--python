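"""Position weight matrix (PWM) parsing, validation, and characterization.

A PWM models a transcription factor's binding preference as per-position base
frequencies over the alphabet A, C, G, T.  Matrices are read from the TRANSFAC
flat-file dialect or the JASPAR PFM format, regularized with a pseudocount so
every frequency is strictly positive, and characterized by a per-position
information vector (natural-log units) from which the 5-bp "core" — the most
conserved consecutive window, used by the MATCH-style scanner — is derived.

Matrix accessions are collapsed to TF names (e.g. ``V$STAT6_01`` → ``STAT6``)
because cooperation is scored at the level of factors, not matrices: all
matrices sharing a TF name are scanned and their sites pooled.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs

ALPHABET = "ACGT"
#: pseudocount added to every count cell before normalization
PSEUDOCOUNT = 1e-3

__all__ = [
    "PWM",
    "MotifParseError",
    "read_transfac",
    "write_transfac",
    "read_jaspar",
    "information_vector",
    "core_positions",
    "normalize_tf_name",
]


class MotifParseError(ValueError):
    """Raised when a motif file violates its format contract."""


# site-type prefix such as "V$" or "F$"; quality/version suffixes such as
# "_01", "_Q3", "_Q6_01", "_B" — stripped iteratively from the right.
_PREFIX_RE = re.compile(r"^[A-Za-z]+\$")
_SUFFIX_RE = re.compile(r"_(?:\d+|[A-Za-z]\d*)$")


def normalize_tf_name(matrix_id: str) -> str:
    """Collapse a matrix accession/identifier to its factor name.

    Strips the TRANSFAC site-type prefix (``V$``, ``F$``, ...) and any chain of
    version/quality suffixes (``_01``, ``_Q3``, ``_C``), then uppercases.
    ``V$GATA4_Q3`` → ``GATA4``; ``V$CEBP_Q2_01`` → ``CEBP``.
    """
    name = _PREFIX_RE.sub("", matrix_id.strip())
    while True:
        stripped = _SUFFIX_RE.sub("", name)
        if stripped == name or not stripped:
            break
        name = stripped
    return name.upper()


@dataclass(frozen=True)
class PWM:
    """A positional base-frequency model for one matrix accession.

    ``counts`` holds the raw (non-negative) observation counts as parsed;
    ``frequencies`` is derived by adding :data:`PSEUDOCOUNT` to every cell and
    normalizing each row, so every frequency is strictly positive and each row
    sums to 1.
    """

    id: str
    tf_name: str
    counts: np.ndarray
    frequencies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"PWM {self.id}: counts must be L x 4, got {counts.shape}")
        if counts.shape[0] < 4:
            raise ValueError(f"PWM {self.id}: length {counts.shape[0]} < 4")
        if (counts < 0).any():
            raise ValueError(f"PWM {self.id}: negative counts")
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        reg = counts + PSEUDOCOUNT
        freqs = reg / reg.sum(axis=1, keepdims=True)
        freqs.setflags(write=False)
        object.__setattr__(self, "frequencies", freqs)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        """Per-position argmax base (leftmost base on frequency ties)."""
        return "".join(ALPHABET[i] for i in self.frequencies.argmax(axis=1))


def information_vector(pwm: PWM) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Natural-log units; 0 for a uniform position, ln 4 in the degenerate
    single-base limit.  This is the weighting the MATCH similarity score uses.
    """
    f = pwm.frequencies
    return np.einsum("ij,ij->i", f, np.log(4.0 * f))


def core_positions(pwm: PWM, width: int = 5) -> tuple[int, int]:
    """Half-open interval of the ``width`` consecutive positions maximizing
    summed information content; leftmost window on ties.

    For matrices shorter than ``width`` the whole matrix is the core.
    """
    info = information_vector(pwm)
    if pwm.length <= width:
        return (0, pwm.length)
    window_sums = np.lib.stride_tricks.sliding_window_view(info, width).sum(axis=1)
    # leftmost window within float tolerance of the maximum (deterministic
    # tie-break robust to summation-order noise)
    start = int(np.argmax(window_sums >= window_sums.max() - 1e-9))
    return (start, start + width)


# ---------------------------------------------------------------------------
# TRANSFAC flat-file dialect
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _validate_transfac_text(text: str) -> None:
    """Pre-validate count blocks: every numbered row must carry exactly four
    numeric fields (an optional trailing consensus letter is allowed)."""
    accession = "?"
    in_block = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        tag = line[:2]
        if tag == "AC":
            accession = line[2:].strip() or "?"
            in_block = False
        elif tag == "P0" or tag == "PO":
            in_block = True
        elif tag == "//" or tag == "XX":
            in_block = False
        elif in_block and re.match(r"^\d\d", line):
            fields = line.split()
            numeric = [f for f in fields[1:] if _NUMERIC_RE.match(f)]
            if len(numeric) != 4:
                raise MotifParseError(
                    f"matrix {accession}, line {lineno}: expected 4 numeric "
                    f"fields in count row, found {len(numeric)}: {line.strip()!r}"
                )


def read_transfac(path: str | Path) -> list[PWM]:
    """Parse a TRANSFAC flat-file (AC/ID/P0 count blocks) into PWMs.

    ``tf_name`` is derived from the ID (or AC when ID is absent) via
    :func:`normalize_tf_name`; counts are preserved exactly.
    """
    text = Path(path).read_text()
    _validate_transfac_text(text)
    if not text.strip():
        return []
    try:
        records = bio_motifs.parse(io.StringIO(text), "transfac", strict=False)
    except Exception as exc:  # format-level failure
        raise MotifParseError(f"{path}: {exc}") from exc
    pwms = []
    for rec in records:
        acc = rec.get("AC") or rec.get("ID") or f"record{len(pwms) + 1}"
        ident = rec.get("ID") or acc
        counts = np.column_stack([rec.counts[b] for b in ALPHABET])
        if counts.shape[0] == 0:
            raise MotifParseError(f"matrix {acc}: empty count block")
        pwms.append(PWM(id=acc, tf_name=normalize_tf_name(ident), counts=counts))
    return pwms


def write_transfac(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write PWMs back to the TRANSFAC flat-file dialect (count round-trip)."""
    lines: list[str] = []
    for pwm in pwms:
        lines.append(f"AC  {pwm.id}")
        lines.append("XX")
        lines.append(f"ID  {pwm.id}")
        lines.append("XX")
        lines.append("P0" + "".join(f"{b:>7}" for b in ALPHABET))
        for i, row in enumerate(pwm.counts, start=1):
            fields = "".join(f"{v:>7g}" for v in row)
            lines.append(f"{i:02d}{fields}")
        lines.append("XX")
        lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM format
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path) -> list[PWM]:
    """Parse JASPAR PFM records (``>ID name`` header, four bracketed rows)."""
    text = Path(path).read_text()
    if not text.strip():
        return []
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:
        raise MotifParseError(f"{path}: {exc}") from exc
    pwms = []
    for rec in records:
        lengths = {len(rec.counts[b]) for b in ALPHABET}
        if len(lengths) != 1:
            raise MotifParseError(
                f"matrix {rec.matrix_id}: base rows have unequal lengths {sorted(lengths)}"
            )
        counts = np.column_stack([rec.counts[b] for b in ALPHABET])
        label = rec.name or rec.matrix_id
        pwms.append(
            PWM(id=rec.matrix_id or label, tf_name=normalize_tf_name(label), counts=counts)
        )
    return pwms


def pooled_tf_names(pwms: Sequence[PWM]) -> dict[str, list[PWM]]:
    """Group matrices by normalized TF name (the pairing unit)."""
    groups: dict[str, list[PWM]] = {}
    for pwm in pwms:
        groups.setdefault(pwm.tf_name, []).append(pwm)
    return groups
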