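"""Alignment-free mapping of long-read ends to subject sequences.

Subjects (contigs, or partial scaffolds in later phases) are summarized by
minhash sketches of their canonical minimizer sets; each long read contributes
two sketches, one per ``end_len``-bp end. A sketch is ``T`` independent
minhash trials; the fraction of agreeing trials between two sketches is an
unbiased estimator of the Jaccard similarity of the underlying minimizer sets.
Restricting queries to read ends keeps the two ground sets comparable in size
and lets one spanning read link two distant contigs, which is exactly the
signal a scaffolder needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hashing import decode_kmer, encode_kmer, hash_kmer, splitmix64
from .io_formats import MappingTuple, SequenceRecord

logger = logging.getLogger(__name__)

_MAXU64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass(frozen=True)
class MapperParams:
    """Sketch-mapper tuning knobs.

    T=30 trials and end_len=2000 bp are the reference operating point; k/w
    give a minimizer density of ~2/(w+1) so a 2 kb end yields a few hundred
    minimizers. tau is the minimum sketch similarity to report; the default
    sits below 1/T, i.e. any nonzero sketch agreement is reported. Unrelated
    sequences share no minimizers (their agreement is ~0 up to 2^-64 hash
    collisions), while a read end overlapping a subject by even a few hundred
    bp has appreciable Jaccard — and those short straddling overlaps are what
    give one end multiple subjects and make wiring intersections informative.
    """

    k: int = 15
    w: int = 10
    T: int = 30
    end_len: int = 2000
    tau: float = 0.02
    top_n: int = 3
    salt: int = 42

    def __post_init__(self):
        if not 0 < self.k <= 31:
            raise ValueError("k must be in (0, 31]")
        if self.w < 1 or self.T < 1 or self.top_n < 1:
            raise ValueError("w, T and top_n must be >= 1")
        if self.end_len < self.k + self.w - 1:
            raise ValueError("end_len must be >= k + w - 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")


# ---------------------------------------------------------------------------
# Minimizers


def _kmer_values(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement 2-bit k-mer values plus validity mask."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(arr.shape, dtype=np.uint64)
    valid = np.zeros(arr.shape, dtype=bool)
    for base, code in zip("ACGT", range(4)):
        hit = arr == ord(base)
        codes[hit] = code
        valid |= hit
    m = len(seq) - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    comp = (np.uint64(3) - codes) * valid  # complement; invalid positions caught via mask
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | codes[j:j + m]
        rev |= comp[j:j + m] << np.uint64(2 * j)
    bad = ~valid
    ok = ~(np.lib.stride_tricks.sliding_window_view(bad, k).any(axis=1))
    return fwd, rev, ok


def extract_minimizers(
    sequence: str,
    k: int,
    w: int,
    ordering: str = "hash",
    canonical: bool = True,
) -> set[str]:
    """Standard (w,k)-minimizer scheme over canonical k-mers.

    For every window of ``w`` consecutive k-mers the minimum under the
    ordering ("hash" = fixed 64-bit mixer, "lexicographic" = 2-bit encoding)
    is emitted; k-mers containing N are skipped. ``canonical=False`` disables
    reverse-complement canonicalization (forward-strand only).
    Sequences shorter than k+w-1 yield the empty set.
    """
    if ordering not in ("hash", "lexicographic"):
        raise ValueError(f"unknown ordering {ordering!r}")
    if len(sequence) < k + w - 1:
        logger.debug("sequence of length %d too short for k=%d w=%d", len(sequence), k, w)
        return set()
    fwd, rev, ok = _kmer_values(sequence, k)

    def key_of(vals):
        return splitmix64(vals) if ordering == "hash" else vals

    if canonical:
        kf, kr = key_of(fwd), key_of(rev)
        take_f = kf <= kr
        vals = np.where(take_f, fwd, rev)
        keys = np.minimum(kf, kr)
    else:
        vals = fwd
        keys = key_of(fwd)
    keys = np.where(ok, keys, _MAXU64)

    win = np.lib.stride_tricks.sliding_window_view(keys, w)
    arg = win.argmin(axis=1) + np.arange(win.shape[0])
    chosen = np.unique(arg)
    chosen = chosen[keys[chosen] != _MAXU64]  # windows of all-N k-mers emit nothing
    return {decode_kmer(int(v), k) for v in vals[chosen]}


# ---------------------------------------------------------------------------
# Sketches


def _encode_set(minimizers) -> np.ndarray:
    return np.array(sorted(encode_kmer(m) for m in minimizers), dtype=np.uint64)


def jem_sketch(minimizers, T: int, salt: int) -> np.ndarray | None:
    """Minhash sketch over T random trials: sketch[t] = min_m H(m, salt^t).

    Returns None for an empty minimizer set (unsketchable; callers must treat
    the sequence as unmapped).
    """
    if not minimizers:
        return None
    enc = minimizers if isinstance(minimizers, np.ndarray) else _encode_set(minimizers)
    out = np.empty(T, dtype=np.uint64)
    for t in range(T):
        out[t] = hash_kmer(enc, salt ^ t).min()
    return out


def sketch_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of agreeing sketch slots; estimates Jaccard of the two sets."""
    if a is None or b is None or len(a) != len(b):
        raise ValueError("sketches must be non-empty and of equal length")
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# Read ends


def extract_read_ends(read: SequenceRecord, end_len: int) -> list[tuple[str, str]]:
    """The two end_len-bp ends of a read, or the whole read if shorter.

    For end_len <= len < 2*end_len the two ends overlap but are both emitted.
    """
    n = len(read.sequence)
    if n < end_len:
        return [("whole", read.sequence)]
    return [("5p", read.sequence[:end_len]), ("3p", read.sequence[n - end_len:])]


# ---------------------------------------------------------------------------
# Mapping


def map_reads_to_subjects(
    subjects: list[SequenceRecord],
    reads: list[SequenceRecord],
    params: MapperParams | None = None,
) -> list[MappingTuple]:
    """Map every read end against every subject sketch.

    Per end, subjects with similarity >= tau are reported in descending
    similarity (ties broken by subject id), capped at top_n and ranked from 1.
    With top_n=1 each read maps to at most two subjects, one per end.
    """
    params = params or MapperParams()
    if not subjects:
        raise ValueError("subjects must be non-empty")
    subj_ids: list[str] = []
    sketches: list[np.ndarray] = []
    skipped = 0
    for s in subjects:
        mins = extract_minimizers(s.sequence, params.k, params.w)
        sk = jem_sketch(mins, params.T, params.salt)
        if sk is None:
            skipped += 1
            continue
        subj_ids.append(s.id)
        sketches.append(sk)
    if skipped:
        logger.warning("%d subjects shorter than k+w-1 are unsketchable and never matched", skipped)
    if not sketches:
        return []
    matrix = np.stack(sketches)  # (n_subjects, T)

    out: list[MappingTuple] = []
    for read in reads:
        for end_label, subseq in extract_read_ends(read, params.end_len):
            mins = extract_minimizers(subseq, params.k, params.w)
            sk = jem_sketch(mins, params.T, params.salt)
            if sk is None:
                continue
            sims = np.mean(matrix == sk[np.newaxis, :], axis=1)
            candidates = [
                (float(sims[i]), subj_ids[i]) for i in range(len(subj_ids)) if sims[i] >= params.tau
            ]
            candidates.sort(key=lambda c: (-c[0], c[1]))
            for rank, (sim, cid) in enumerate(candidates[: params.top_n], start=1):
                out.append(MappingTuple(read.id, end_label, cid, sim, rank))
    return out
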