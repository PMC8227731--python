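"""Packaged synthetic benchmark scenarios with known ground truth.

Three standard evaluations of the cooperativity pipeline:

* :func:`recovery_benchmark` — can a planted cooperative pair (penetrance 0.4
  over 200 promoters, gaps uniform on the 5–20 bp scoring window, eight
  independent decoy motifs) be recovered at z >= 3 and rank 1?
* :func:`null_benchmark` — the same geometry at penetrance 0: what fraction
  of pure-decoy pairs reaches z >= 3?
* :func:`shared_private_study` — a two-phenotype study whose corpora share
  one planted pair and each hold one private pair; the network comparison
  should recover exactly that structure.

The scenario parameters are fixed study conditions, not tuning knobs; they
mirror the promoter-window geometry (600 bp) and a study-scale gene count.
"""

from __future__ import annotations

import numpy as np

from .coop_score import ScoringConfig, score_corpus
from .motif_library import PWM
from .networks import NetworkComparison
from .pipeline import PhenotypeResult, RunConfig, run_study
from .site_scanner import ScanProfile
from .synthetic_data import (
    Decoy,
    PlantedPair,
    SyntheticSpec,
    evaluate_recovery,
    generate_corpus,
)

__all__ = [
    "benchmark_pwm",
    "benchmark_library",
    "recovery_benchmark",
    "null_benchmark",
    "shared_private_study",
]

#: mutually dissimilar 10-mer consensus motifs for the benchmark library
BENCHMARK_CONSENSI = (
    "ACGTACGTAC",
    "TGCATGCATG",
    "GGATCCAATT",
    "TTGACGTCAT",
    "CCGGTTAACC",
    "ATATGCGCAT",
    "GACTGACTGA",
    "CTTAGGCTAA",
    "AACCGGTTAA",
    "TGTGCACACA",
)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def benchmark_pwm(
    pwm_id: str, tf_name: str, consensus: str, dominance: float = 0.85, total: int = 25
) -> PWM:
    """A PWM whose consensus base holds ``dominance`` of each position's counts.

    0.85 yields realistic motifs: sites sampled from the frequencies usually,
    but not always, pass conventional MATCH cutoffs.
    """
    counts = np.full((len(consensus), 4), total * (1 - dominance) / 3)
    for i, b in enumerate(consensus):
        counts[i, _BASE_INDEX[b]] = total * dominance
    return PWM(pwm_id, tf_name, counts)


def benchmark_library(n: int = 10, dominance: float = 0.85) -> list[PWM]:
    """The standard 10-motif benchmark library (TF0 ... TF9)."""
    return [
        benchmark_pwm(f"M{i:02d}", f"TF{i}", c, dominance)
        for i, c in enumerate(BENCHMARK_CONSENSI[:n])
    ]


def _benchmark_spec(seed: int, penetrance: float, n_promoters: int = 200) -> tuple:
    lib = benchmark_library()
    planted = (
        (PlantedPair(lib[0], lib[1], penetrance),) if penetrance > 0 else ()
    )
    spec = SyntheticSpec(
        n_promoters=n_promoters,
        length=600,
        planted_pairs=planted,
        decoys=tuple(Decoy(p, 0.5) for p in lib[2:]),
        seed=seed,
    )
    return spec, lib


def recovery_benchmark(
    seed: int,
    penetrance: float = 0.4,
    n_promoters: int = 200,
    n_shuffles: int = 10,
) -> dict:
    """One planted-pair recovery run; returns the evaluation report.

    The report (see :func:`tfcoop.synthetic_data.evaluate_recovery`) carries
    the planted pair's z, rank and significance flag plus the corpus-wide
    significant-pair counts.
    """
    spec, lib = _benchmark_spec(seed, penetrance, n_promoters)
    promoters, truth = generate_corpus(spec)
    config = ScoringConfig(n_shuffles=n_shuffles, seed=seed)
    stats = score_corpus(promoters, lib, ScanProfile(), config,
                         rng=np.random.default_rng(spec.seed + 1))
    return evaluate_recovery(stats, truth, config.z_threshold)


def null_benchmark(seed: int, n_promoters: int = 200, n_shuffles: int = 10) -> dict:
    """Decoy-only run (penetrance 0); returns the evaluation report.

    ``n_significant / n_scored`` estimates the false-positive rate of the
    z >= 3 rule under the null.
    """
    return recovery_benchmark(seed, penetrance=0.0, n_promoters=n_promoters,
                              n_shuffles=n_shuffles)


def _study_library() -> tuple[list[PWM], list[PWM]]:
    rng = np.random.default_rng(2)
    planted = [
        benchmark_pwm(f"S{i}", f"TF{i}", BENCHMARK_CONSENSI[i], dominance=0.92)
        for i in range(6)
    ]
    decoys = [
        benchmark_pwm(
            f"D{i:02d}", f"DEC{i}",
            "".join("ACGT"[b] for b in rng.integers(0, 4, 10)),
            dominance=0.85,
        )
        for i in range(18)
    ]
    return planted, decoys


def shared_private_study(
    seed: int = 31,
    penetrance: float = 0.7,
    n_promoters: int = 250,
    n_shuffles: int = 3,
) -> tuple[PhenotypeResult, PhenotypeResult, NetworkComparison]:
    """Two-phenotype study: corpora share pair TF0–TF1; phenotype A privately
    carries TF2–TF3 and phenotype B TF4–TF5.

    Every library PWM not planted in a given corpus is placed there as an
    independent decoy, so all factors have comparable site counts (rare-factor
    pairs would otherwise reach spuriously high PMI from tiny marginals).
    """
    planted_pwms, decoy_pwms = _study_library()
    lib = planted_pwms + decoy_pwms
    shared = PlantedPair(lib[0], lib[1], penetrance)
    private_a = PlantedPair(lib[2], lib[3], penetrance)
    private_b = PlantedPair(lib[4], lib[5], penetrance)

    def corpus(planted, corpus_seed):
        names = {p.tf_name for pr in planted for p in (pr.pwm_a, pr.pwm_b)}
        spec = SyntheticSpec(
            n_promoters=n_promoters, length=600, planted_pairs=planted,
            decoys=tuple(Decoy(p, 1.0) for p in lib if p.tf_name not in names),
            seed=corpus_seed,
        )
        return generate_corpus(spec)[0]

    proms_a = corpus((shared, private_a), seed)
    proms_b = corpus((shared, private_b), seed + 1)
    config = RunConfig(
        scan=ScanProfile(),
        scoring=ScoringConfig(n_shuffles=n_shuffles, seed=seed),
        seed=seed,
    )
    return run_study(config, proms_a, proms_b, lib, "phenotype_a", "phenotype_b")
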