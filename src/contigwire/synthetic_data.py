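"""Synthetic genomes, contig sets and HiFi-like long reads with ground truth.

The generators emulate the experimental regime the scaffolder targets: a
short-read assembly reduced to fragmented contigs (lognormal lengths, a few
kb, tiling most but not all of the genome, random strands) and high-fidelity
long reads (10x coverage, ~10 kb median, ~0.2% substitution errors). Contigs
are shredded directly from the genome instead of being assembled from
simulated short reads; this preserves the statistical structure a scaffolder
consumes (fragment lengths, gaps, strand mixture) without external tools.
Every emitted sequence carries a truth placement on the genome, recorded
before errors are applied, so downstream order/orientation accuracy is
checkable exactly. All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hashing import revcomp
from .io_formats import SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthPlacement:
    """Where a contig or read truly sits on the genome (0-based half-open)."""

    seq_id: str
    genome_start: int
    genome_end: int
    strand: str

    def __post_init__(self):
        if not 0 <= self.genome_start < self.genome_end:
            raise ValueError("invalid truth interval")


@dataclass(frozen=True)
class RepeatSpec:
    """A planted repeat family: ``copies`` copies of one ``unit_length`` unit."""

    unit_length: int
    copies: int = 2
    identity: float = 1.0

    def __post_init__(self):
        if self.copies < 2 or self.unit_length < 1 or not 0.0 < self.identity <= 1.0:
            raise ValueError("invalid repeat spec")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return arr
    pos = rng.choice(len(arr), size=n_err, replace=False)
    out = arr.copy()
    for p in pos:  # substitute with a *different* base
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return out


def simulate_genome(
    length: int,
    repeats: tuple[RepeatSpec, ...] = (),
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """An i.i.d. random genome with optional planted repeat families.

    Each repeat family overwrites ``copies`` random non-overlapping loci with
    (near-)identical copies of a random unit. Returns the genome and the list
    of planted repeat intervals.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    genome = _random_bases(rng, length, gc)
    intervals: list[tuple[int, int]] = []
    for spec in repeats:
        if spec.copies * spec.unit_length >= length:
            raise ValueError("repeat copies do not fit in the genome")
        unit = _random_bases(rng, spec.unit_length, gc)
        placed = 0
        attempts = 0
        while placed < spec.copies:
            attempts += 1
            if attempts > 1000:
                raise ValueError("could not place non-overlapping repeat copies")
            start = int(rng.integers(0, length - spec.unit_length + 1))
            iv = (start, start + spec.unit_length)
            if any(iv[0] < e and s < iv[1] for s, e in intervals):
                continue
            genome[iv[0]:iv[1]] = _mutate(rng, unit, 1.0 - spec.identity)
            intervals.append(iv)
            placed += 1
    return SequenceRecord("genome", "".join(genome)), intervals


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def shred_to_contigs(
    genome: SequenceRecord,
    mean_len: int = 5000,
    len_cv: float = 0.3,
    covered_frac: float = 0.85,
    seed: int = 0,
    min_len: int = 200,
) -> tuple[list[SequenceRecord], list[TruthPlacement]]:
    """Shred a genome into non-overlapping contigs covering ~covered_frac.

    Contig lengths are lognormal (given mean and CV); gaps between contigs
    are sized so total contig bases approximate covered_frac x genome length.
    Each contig is emitted on a random strand; truth is recorded.
    """
    if not 0 < covered_frac <= 1:
        raise ValueError("covered_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    G = len(genome.sequence)
    gap_mean = mean_len * (1.0 - covered_frac) / covered_frac
    contigs: list[SequenceRecord] = []
    truth: list[TruthPlacement] = []
    pos = 0
    i = 0
    while pos + min_len <= G:
        L = max(min_len, int(round(_lognormal(rng, mean_len, len_cv))))
        L = min(L, G - pos)
        strand = "+" if rng.random() < 0.5 else "-"
        cid = f"contig{i:04d}"
        seg = genome.sequence[pos:pos + L]
        contigs.append(SequenceRecord(cid, revcomp(seg) if strand == "-" else seg))
        truth.append(TruthPlacement(cid, pos, pos + L, strand))
        gap = 0 if covered_frac >= 1.0 else int(round(_lognormal(rng, max(gap_mean, 1e-9), len_cv)))
        pos += L + gap
        i += 1
    return contigs, truth


def simulate_long_reads(
    genome: SequenceRecord,
    coverage: float = 10.0,
    median_len: int = 10_000,
    len_sd: int = 3400,
    error_rate: float = 0.002,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[TruthPlacement]]:
    """HiFi-like reads: uniform starts, truncated-normal lengths, random
    strands, uniform substitution errors; truth recorded pre-error.

    Reads are sampled until total bases reach coverage x genome length.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    rng = np.random.default_rng(seed)
    G = len(genome.sequence)
    target = coverage * G
    reads: list[SequenceRecord] = []
    truth: list[TruthPlacement] = []
    total = 0
    i = 0
    while total < target:
        L = int(round(rng.normal(median_len, len_sd)))
        L = max(1000, min(L, G))
        start = int(rng.integers(0, G - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        rid = f"read{i:05d}"
        arr = np.array(list(genome.sequence[start:start + L]))
        arr = _mutate(rng, arr, error_rate)
        seq = "".join(arr)
        reads.append(SequenceRecord(rid, revcomp(seq) if strand == "-" else seq))
        truth.append(TruthPlacement(rid, start, start + L, strand))
        total += L
        i += 1
    return reads, truth


@dataclass
class Fixture:
    """A complete synthetic study: genome, contigs, reads, and all truth."""

    genome: SequenceRecord
    repeat_intervals: list[tuple[int, int]]
    contigs: list[SequenceRecord]
    contig_truth: list[TruthPlacement]
    reads: list[SequenceRecord]
    read_truth: list[TruthPlacement]

    @property
    def truth_by_id(self) -> dict[str, TruthPlacement]:
        return {t.seq_id: t for t in self.contig_truth + self.read_truth}


def make_fixture(
    seed: int = 0,
    genome_length: int = 200_000,
    repeats: tuple[RepeatSpec, ...] = (RepeatSpec(3000, 2, 1.0),),
    contig_mean_len: int = 5000,
    contig_len_cv: float = 0.3,
    covered_frac: float = 0.85,
    coverage: float = 10.0,
    median_read_len: int = 10_000,
    read_len_sd: int = 3400,
    error_rate: float = 0.002,
    gap_regions: tuple[tuple[int, int], ...] = (),
) -> Fixture:
    """The packaged study conditions: 200 kb genome with one exact 3 kb repeat
    x2, contigs of mean 5 kb covering 85%, reads at 10x / 10 kb / 0.2% error.

    ``gap_regions`` removes all contigs overlapping the given genome intervals
    (emulating regions the prior assembly missed entirely).
    """
    genome, repeat_ivs = simulate_genome(genome_length, repeats, seed=seed)
    contigs, ctruth = shred_to_contigs(
        genome, contig_mean_len, contig_len_cv, covered_frac, seed=seed + 1
    )
    if gap_regions:
        keep = [
            i for i, t in enumerate(ctruth)
            if not any(t.genome_start < e and s < t.genome_end for s, e in gap_regions)
        ]
        contigs = [contigs[i] for i in keep]
        ctruth = [ctruth[i] for i in keep]
    reads, rtruth = simulate_long_reads(
        genome, coverage, median_read_len, read_len_sd, error_rate, seed=seed + 2
    )
    return Fixture(genome, repeat_ivs, contigs, ctruth, reads, rtruth)
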