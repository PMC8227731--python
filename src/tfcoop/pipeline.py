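"""End-to-end study orchestration: promoters → scan → score → networks.

A study takes one motif library, a promoter source and two phenotype gene
lists, runs the full scoring pipeline per phenotype and compares the two
cooperation networks.  Every run is seeded and single-process; each stage
draws its randomness from a stream derived from the master seed and the stage
name, so e.g. changing the number of background shuffles does not perturb any
other stage.  A JSON manifest records input hashes, parameters, seed and tool
version, making a run reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .coop_score import (
    PairStatistics,
    ScoringConfig,
    score_corpus,
    significant_pairs,
    write_pairs_tsv,
)
from .motif_library import PWM
from .networks import (
    CooperationNetwork,
    NetworkComparison,
    build_network,
    compare_networks,
    export_comparison,
    export_network,
)
from .promoters import (
    PromoterSequence,
    filter_duplicate_sequences,
    filter_overlapping,
    select_promoters,
)
from .site_scanner import BindingSite, ScanProfile, scan_corpus, write_sites_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PhenotypeResult", "run_phenotype", "run_study", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunConfig:
    """Configuration of one study run."""

    scan: ScanProfile = field(default_factory=ScanProfile)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    seed: int = 0
    overlap_policy: str = "drop-all"
    out_dir: Path | None = None


@dataclass
class PhenotypeResult:
    phenotype: str
    promoters: list[PromoterSequence]
    sites: list[BindingSite]
    pairs: list[PairStatistics]
    network: CooperationNetwork
    manifest: dict


def _promoter_digest(promoters: Sequence[PromoterSequence]) -> str:
    return _sha256_text("\n".join(f"{p.gene_id}\t{p.sequence}" for p in promoters))


def _pwm_digest(pwms: Sequence[PWM]) -> str:
    return _sha256_text(
        "\n".join(f"{p.id}\t{p.tf_name}\t{p.counts.tolist()}" for p in pwms)
    )


def run_phenotype(
    config: RunConfig,
    promoters: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    phenotype: str,
    gene_list: Sequence[str] | None = None,
) -> PhenotypeResult:
    """Execute the full pipeline for one phenotype gene set.

    ``gene_list`` subsets the promoter collection (None = use all).  Promoters
    are overlap- and duplicate-filtered, scanned, scored against the shuffled
    background and assembled into a cooperation network of significant pairs.
    """
    selected = (
        select_promoters(promoters, gene_list) if gene_list is not None else list(promoters)
    )
    if not selected:
        raise ValueError(f"phenotype {phenotype!r}: no promoters after gene-list selection")
    kept, removed_overlap = filter_overlapping(selected, config.overlap_policy)
    kept, removed_dup = filter_duplicate_sequences(kept)
    if not kept:
        raise ValueError(f"phenotype {phenotype!r}: no promoters left after filtering")
    logger.info(
        "phenotype %s: %d promoters (%d overlap-removed, %d duplicates)",
        phenotype, len(kept), len(removed_overlap), len(removed_dup),
    )

    sites = scan_corpus(kept, pwms, config.scan)
    rng = np.random.default_rng(stage_seed(config.seed, f"background:{phenotype}"))
    pairs = score_corpus(kept, pwms, config.scan, config.scoring, sites=sites, rng=rng)
    sig = significant_pairs(pairs, config.scoring)
    network = build_network(sig, phenotype)

    manifest = {
        "tool": "tfcoop",
        "version": __version__,
        "phenotype": phenotype,
        "seed": config.seed,
        "inputs": {
            "promoters_sha256": _promoter_digest(kept),
            "motifs_sha256": _pwm_digest(pwms),
            "n_promoters": len(kept),
            "n_matrices": len(pwms),
        },
        "parameters": {
            "core_cutoff": config.scan.core_cutoff,
            "matrix_cutoff": config.scan.matrix_cutoff,
            "d_min": config.scoring.d_min,
            "d_max": config.scoring.d_max,
            "alpha": config.scoring.alpha,
            "z_threshold": config.scoring.z_threshold,
            "n_shuffles": config.scoring.n_shuffles,
            "log_base": config.scoring.log_base,
            "overlap_policy": config.overlap_policy,
        },
        "outputs": {
            "n_sites": len(sites),
            "n_scored_pairs": len(pairs),
            "n_significant_pairs": len(sig),
        },
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sites_tsv(sites, out / f"{phenotype}.sites.tsv")
        write_pairs_tsv(pairs, out / f"{phenotype}.pairs.tsv", config.scoring.z_threshold)
        export_network(network, out / f"{phenotype}.network.tsv", "tsv")
        export_network(network, out / f"{phenotype}.network.graphml", "graphml")
        (out / f"{phenotype}.manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    return PhenotypeResult(
        phenotype=phenotype, promoters=kept, sites=sites,
        pairs=pairs, network=network, manifest=manifest,
    )


def run_study(
    config: RunConfig,
    promoters_a: Sequence[PromoterSequence],
    promoters_b: Sequence[PromoterSequence],
    pwms: Sequence[PWM],
    phenotype_a: str = "phenotype_a",
    phenotype_b: str = "phenotype_b",
    gene_list_a: Sequence[str] | None = None,
    gene_list_b: Sequence[str] | None = None,
) -> tuple[PhenotypeResult, PhenotypeResult, NetworkComparison]:
    """Two phenotype runs sharing motifs and parameters, then a comparison."""
    res_a = run_phenotype(config, promoters_a, pwms, phenotype_a, gene_list_a)
    res_b = run_phenotype(config, promoters_b, pwms, phenotype_b, gene_list_b)
    cmp = compare_networks(res_a.network, res_b.network)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        export_comparison(cmp, out / "comparison.tsv", "tsv")
        export_comparison(cmp, out / "comparison.graphml", "graphml")
    return res_a, res_b, cmp
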