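"""Promoter window construction and redundancy filtering.

The analysis unit is the strand-aware promoter window from −500 bp upstream to
+100 bp downstream of each gene's transcription start site (TSS), extracted
from a genome FASTA, or supplied directly as a promoter FASTA.  Windows whose
genomic intervals overlap any other promoter are removed entirely, as are
exact duplicate sequences (a coarse guard against recently duplicated genes);
both filters keep the co-occurrence statistics from double-counting the same
genomic sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_CHARS = set("ACGTN")
_COORD_RE = re.compile(r"(?P<chrom>[\w.\-]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)")

__all__ = [
    "TssRecord",
    "PromoterSequence",
    "extract_promoters",
    "filter_overlapping",
    "filter_duplicate_sequences",
    "read_promoter_fasta",
    "write_promoter_fasta",
]


@dataclass(frozen=True)
class TssRecord:
    """A gene's transcription start site (0-based genomic coordinate)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS coordinate")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter window with genomic provenance.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``sequence``
    is oriented along the transcribed strand: position 0 is the most upstream
    base regardless of ``strand``.  ``clipped`` marks windows truncated at a
    chromosome boundary.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty interval [{self.start}, {self.end})")
        seq = self.sequence.upper()
        if len(seq) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(seq)} != interval "
                f"length {self.end - self.start}"
            )
        if not set(seq) <= _VALID_CHARS:
            bad = sorted(set(seq) - _VALID_CHARS)
            raise ValueError(f"{self.gene_id}: invalid characters {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return self.end - self.start


def extract_promoters(
    tss_list: Sequence[TssRecord],
    genome,
    upstream: int = 500,
    downstream: int = 100,
) -> list[PromoterSequence]:
    """Extract strand-aware TSS windows from an indexed genome.

    ``genome`` is a mapping from chromosome name to sliceable sequence (a
    ``pyfaidx.Fasta`` or a plain dict of strings).  For a + strand gene the
    window is ``[tss - upstream, tss + downstream)``; for a − strand gene it is
    ``[tss - downstream + 1, tss + upstream + 1)`` and the returned sequence is
    reverse-complemented so the −500/+100 geometry is measured along the
    transcribed strand.  Windows are clipped at chromosome ends; records whose
    interval is empty after clipping are skipped with a warning.  Only the
    first record per gene_id is used.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    out: list[PromoterSequence] = []
    seen: set[str] = set()
    for rec in tss_list:
        if rec.gene_id in seen:
            logger.warning("duplicate gene_id %s: keeping first TSS record", rec.gene_id)
            continue
        seen.add(rec.gene_id)
        try:
            chrom_seq = genome[rec.chrom]
        except KeyError as exc:
            raise KeyError(f"gene {rec.gene_id}: chromosome {rec.chrom!r} not in genome") from exc
        chrom_len = len(chrom_seq)
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        else:
            start, end = rec.tss - downstream + 1, rec.tss + upstream + 1
        clipped_start, clipped_end = max(start, 0), min(end, chrom_len)
        if clipped_end <= clipped_start:
            logger.warning("gene %s: window empty after clipping, skipped", rec.gene_id)
            continue
        seq = str(chrom_seq[clipped_start:clipped_end]).upper()
        if rec.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append(
            PromoterSequence(
                gene_id=rec.gene_id,
                chrom=rec.chrom,
                start=clipped_start,
                end=clipped_end,
                strand=rec.strand,
                sequence=seq,
                clipped=(clipped_start, clipped_end) != (start, end),
            )
        )
    return out


def filter_overlapping(
    promoters: Sequence[PromoterSequence],
    policy: str = "drop-all",
) -> tuple[list[PromoterSequence], list[PromoterSequence]]:
    """Split promoters into (kept, removed) by genomic overlap.

    Under the default ``drop-all`` policy every member of a cluster of
    mutually/transitively overlapping intervals is removed — only promoters
    that overlap no other promoter survive.  ``keep-first`` instead keeps the
    leftmost promoter of each cluster.  Intervals are half-open, so touching
    intervals do not overlap.
    """
    if policy not in ("drop-all", "keep-first"):
        raise ValueError(f"unknown overlap policy {policy!r}")
    order = sorted(range(len(promoters)), key=lambda i: (promoters[i].chrom, promoters[i].start))
    overlapping: set[int] = set()
    kept_first: set[int] = set()
    cluster: list[int] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        if len(cluster) > 1:
            overlapping.update(cluster)
            kept_first.add(cluster[0])

    for i in order:
        p = promoters[i]
        if p.chrom == cluster_chrom and p.start < cluster_end:
            cluster.append(i)
            cluster_end = max(cluster_end, p.end)
        else:
            flush()
            cluster = [i]
            cluster_chrom, cluster_end = p.chrom, p.end
    flush()

    if policy == "keep-first":
        removed_idx = overlapping - kept_first
    else:
        removed_idx = overlapping
    kept = [p for i, p in enumerate(promoters) if i not in removed_idx]
    removed = [p for i, p in enumerate(promoters) if i in removed_idx]
    return kept, removed


def filter_duplicate_sequences(
    promoters: Sequence[PromoterSequence],
) -> tuple[list[PromoterSequence], list[PromoterSequence]]:
    """Remove promoters whose sequence is an exact duplicate of an earlier one."""
    seen: dict[str, str] = {}
    kept, removed = [], []
    for p in promoters:
        if p.sequence in seen:
            logger.warning("gene %s: sequence identical to %s, removed", p.gene_id, seen[p.sequence])
            removed.append(p)
        else:
            seen[p.sequence] = p.gene_id
            kept.append(p)
    return kept, removed


def read_promoter_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read pre-extracted promoters from FASTA.

    A header token ``chrom:start-end(strand)`` is parsed into genomic
    coordinates; records without one are assigned a synthetic coordinate
    system (one pseudo-chromosome per record) so overlap filtering is a no-op
    on them.
    """
    out: list[PromoterSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        m = _COORD_RE.search(rec.description)
        seq = str(rec.seq).upper()
        if m:
            out.append(
                PromoterSequence(
                    gene_id=rec.id,
                    chrom=m["chrom"],
                    start=int(m["start"]),
                    end=int(m["end"]),
                    strand=m["strand"],
                    sequence=seq,
                )
            )
        else:
            out.append(
                PromoterSequence(
                    gene_id=rec.id,
                    chrom=f"synthetic_{rec.id}",
                    start=0,
                    end=len(seq),
                    strand="+",
                    sequence=seq,
                )
            )
    return out


def write_promoter_fasta(promoters: Iterable[PromoterSequence], path: str | Path) -> None:
    """Write promoters to FASTA, embedding coordinates in the header."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.gene_id} {p.chrom}:{p.start}-{p.end}({p.strand})\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read TSS records from a BED file (chrom, start, end, name, score, strand).

    The TSS is the ``start`` coordinate for + strand features and ``end - 1``
    for − strand features; the score column is ignored.
    """
    records: list[TssRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"{path}:{lineno}: need 6 BED columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        tss = int(start) if strand == "+" else int(end) - 1
        records.append(TssRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    return records


def select_promoters(
    promoters: Sequence[PromoterSequence], gene_ids: Iterable[str]
) -> list[PromoterSequence]:
    """Subset promoters by gene list, preserving promoter order."""
    wanted = set(gene_ids)
    return [p for p in promoters if p.gene_id in wanted]
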