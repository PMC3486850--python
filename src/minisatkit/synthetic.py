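"""Seeded generators for every input class the analysis modules consume.

Each generator derives an independent RNG stream from (seed, generator
name), so adding a generator never shifts the outputs of another, and every
generator is a pure function of its spec + seed.  Generators return truth
records sufficient to compute the expected downstream output without
re-deriving any randomness.

What the generators emulate — and what they do not:

* ``gen_catalog`` — a minisatellite catalog with a tunable linear terminal
  bias (density proportional to 1 + beta*x on the 0(CEN)-1(TEL) axis,
  giving closed-form terminal-fraction integrals), a two-component GC
  mixture, and a GC-class-linked G4-count rule.  It does not emulate real
  genome base composition or TRF score fields.
* ``gen_array`` — tandem arrays with seeded point mutations.
* ``gen_junction_reads`` — array-prefix + telomeric-suffix reads with the
  analytically known junction and shared span.
* ``gen_fluctuation`` — delegates to the Luria-Delbruck simulator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .fluctuation import FluctuationExperiment, LDSimParams, simulate_ld
from .genome_dist import ChromosomeArmModel, MinisatelliteRecord
from .junctions import TelomereModel, is_telomeric
from .motifs import NucleotideMotif, TandemArray

__all__ = [
    "CatalogGenSpec",
    "ArrayGenSpec",
    "JunctionGenSpec",
    "gen_catalog",
    "gen_array",
    "gen_junction_reads",
    "gen_fluctuation",
    "terminal_fraction_expected",
    "default_arms",
]

_BASES = np.array(list("ACGT"))


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per (seed, generator name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def default_arms(n_chroms: int = 4, arm_length: int = 50_000_000) -> list[ChromosomeArmModel]:
    """A simple arm model: n metacentric chromosomes of two equal arms."""
    arms = []
    for i in range(1, n_chroms + 1):
        cen = arm_length + 1
        arms.append(ChromosomeArmModel(f"chr{i}", "p", 1, cen - 1, "end"))
        arms.append(ChromosomeArmModel(f"chr{i}", "q", cen, 2 * arm_length, "start"))
    return arms


@dataclass(frozen=True)
class CatalogGenSpec:
    """Catalog generator settings.

    ``terminal_bias_beta`` shapes the along-arm density 1 + beta*x (beta=0
    is uniform); ``g4_terminal_coupling`` adds beta per G4 hit so terminal
    bias can grow with G4 count.  The GC mixture defaults emulate a
    GC-poor majority (mean 35%) and a GC-rich minority (mean 60%, weight
    0.25); GC-rich records carry Poisson(2) G4 hits, GC-poor none.
    """

    n_records: int
    arms: tuple = ()
    terminal_bias_beta: float = 0.0
    g4_terminal_coupling: float = 0.0
    gc_poor_mean: float = 0.35
    gc_rich_mean: float = 0.60
    gc_sd: float = 0.06
    gc_rich_weight: float = 0.25
    g4_rich_lambda: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_rich_weight <= 1:
            raise ValueError("gc_rich_weight must be in [0, 1]")
        if self.terminal_bias_beta < 0 or self.g4_terminal_coupling < 0:
            raise ValueError("bias parameters must be >= 0")


def _sample_biased_position(u: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of density proportional to 1 + beta*x on [0, 1]."""
    x = np.where(beta > 0,
                 (-1.0 + np.sqrt(1.0 + 2.0 * beta * u * (1.0 + beta / 2.0)))
                 / np.where(beta > 0, beta, 1.0),
                 u)
    return np.clip(x, 0.0, 1.0)


def terminal_fraction_expected(beta: float, f: float = 0.10) -> float:
    """Closed-form mass of the 1 + beta*x density over [1-f, 1]."""
    a = 1 - f
    return (f + beta * (1 - a * a) / 2) / (1 + beta / 2)


def gen_catalog(spec: CatalogGenSpec) -> list[MinisatelliteRecord]:
    """Generate a catalog with known class labels and true positions.

    Each record gains ``true_class`` ("rich"/"poor") and ``true_x`` (the
    normalized position it was placed at) attributes for recovery tests.
    """
    arms = list(spec.arms) or default_arms()
    if not arms:
        raise ValueError("arms must be non-empty")
    rng = _rng(spec.seed, "catalog")
    n = spec.n_records
    rich = rng.uniform(size=n) < spec.gc_rich_weight
    gc = np.where(
        rich,
        rng.normal(spec.gc_rich_mean, spec.gc_sd, size=n),
        rng.normal(spec.gc_poor_mean, spec.gc_sd, size=n),
    )
    # keep the rich/poor split consistent with the >50% classification rule
    gc = np.clip(gc, 0.01, 0.99)
    gc = np.where(rich, np.maximum(gc, 0.505), np.minimum(gc, 0.495))
    g4 = np.where(rich, rng.poisson(spec.g4_rich_lambda, size=n), 0)
    beta = spec.terminal_bias_beta + spec.g4_terminal_coupling * g4
    x = _sample_biased_position(rng.uniform(size=n), beta.astype(float))
    arm_idx = rng.integers(0, len(arms), size=n)
    motif_sizes = rng.integers(10, 101, size=n)
    copies = rng.integers(2, 60, size=n)
    records = []
    for i in range(n):
        arm = arms[arm_idx[i]]
        cen = arm.arm_start if arm.centromere_side == "start" else arm.arm_end
        tel = arm.arm_end if arm.centromere_side == "start" else arm.arm_start
        pos = cen + (tel - cen) * x[i]
        half = int(motif_sizes[i] * copies[i]) // 2
        start = max(arm.arm_start, int(round(pos)) - half)
        end = min(arm.arm_end, int(round(pos)) + half)
        rec = MinisatelliteRecord(
            chrom=arm.chrom,
            start=start,
            end=max(end, start),
            motif_size=int(motif_sizes[i]),
            copy_number=float(copies[i]),
            array_length=int(motif_sizes[i] * copies[i]),
            gc_content=float(gc[i]),
            gc_bias=0.5,
            g4_counts={30: int(g4[i])},
            g4_strand="G" if g4[i] > 0 else None,
        )
        rec.true_class = "rich" if rich[i] else "poor"
        rec.true_x = float(x[i])
        records.append(rec)
    return records


@dataclass(frozen=True)
class ArrayGenSpec:
    motif: NucleotideMotif
    copies: int
    point_mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.point_mutation_rate < 1:
            raise ValueError("point_mutation_rate must be in [0, 1)")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


def gen_array(spec: ArrayGenSpec) -> tuple[TandemArray, dict]:
    """Tandem array with seeded point mutations; truth lists mutated positions."""
    rng = _rng(spec.seed, "array")
    seq = list(spec.motif.sequence * spec.copies)
    mutated: list[tuple[int, str, str]] = []
    if spec.point_mutation_rate > 0:
        hits = np.nonzero(rng.uniform(size=len(seq)) < spec.point_mutation_rate)[0]
        for pos in hits:
            old = seq[pos]
            new = rng.choice([b for b in "ACGT" if b != old])
            seq[pos] = str(new)
            mutated.append((int(pos), old, str(new)))
    array = TandemArray(spec.motif, spec.copies, sequence="".join(seq))
    return array, {"mutations": mutated}


@dataclass(frozen=True)
class JunctionGenSpec:
    array: TandemArray
    breakpoint: int | str = "random"  # position in array coordinates, or "random"
    telomere_mean: float = 300.0
    telomere_sd: float = 75.0
    seed_at_overlap: bool = False  # place breakpoints at TG/GG/GT seeds only
    seed: int = 0


def _telomeric_tract(rng: np.random.Generator, length: int) -> str:
    """A TG1-3 tract of exactly *length* nt (possibly a partial last repeat)."""
    out: list[str] = []
    while len(out) < length:
        out.append("T")
        out.extend("G" * int(rng.integers(1, 4)))
    return "".join(out[:length])


def gen_junction_reads(spec: JunctionGenSpec, n: int) -> tuple[list[str], list[dict]]:
    """Junction reads = array prefix + telomeric suffix, with analytic truth.

    Truth per read: the breakpoint, the maximal motif-templated prefix end
    (which may exceed the breakpoint when the telomere start happens to
    continue the motif), and the shared span, all computed by direct string
    walks independent of the junction parser.
    """
    rng = _rng(spec.seed, "junction")
    arr = spec.array.sequence
    motif = spec.array.motif.sequence
    reads, truths = [], []
    if spec.seed_at_overlap:
        from .seqcomp import FORWARD_SEEDS

        candidates = [
            i for i in range(1, len(arr) - 1) if arr[i : i + 2] in FORWARD_SEEDS
        ]
    else:
        candidates = list(range(1, len(arr)))
    for _ in range(n):
        if spec.breakpoint == "random":
            bp = int(candidates[rng.integers(0, len(candidates))])
        else:
            bp = int(spec.breakpoint)
        tel_len = max(0, int(round(rng.normal(spec.telomere_mean, spec.telomere_sd))))
        read = arr[:bp] + _telomeric_tract(rng, tel_len)
        # analytic truth: walk the junction both ways
        periodic = motif * (len(read) // len(motif) + 2)
        jm = bp
        while jm < len(read) and read[jm] == periodic[jm]:
            jm += 1
        jt = jm
        while jt > 0 and is_telomeric(read[jt - 1 :]):
            jt -= 1
        reads.append(read)
        truths.append(
            {"breakpoint": bp, "junction_index": jm, "shared_span": (min(jt, jm), jm),
             "telomere_length": tel_len}
        )
    return reads, truths


def gen_fluctuation(params: LDSimParams) -> FluctuationExperiment:
    """Fluctuation-assay counts (delegates to the Luria-Delbruck simulator)."""
    return simulate_ld(params, rng=_rng(params.seed, "fluctuation"))
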