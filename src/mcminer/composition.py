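"""Sequence-composition features for binning and scaffold curation.

Tetranucleotide frequency profiles are the compositional signature used to
cluster genetic structures into draft genomes: each 4-mer is identified with
its reverse complement (256 words collapse to 136 canonical classes), so the
profile of an unoriented contig does not depend on which strand was assembled.
GC content and GC skew support cluster-coherence checks and the ordering and
orientation of scaffolds around a replication origin/terminus pair.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _build_canonical_map() -> tuple[np.ndarray, list[str]]:
    """Map each of the 256 4-mer codes to an index in 0..135.

    A 4-mer and its reverse complement share a class; palindromes are their
    own class. Class labels are the lexicographically smaller word.
    """
    canon_code = np.empty(256, dtype=np.int64)
    for code in range(256):
        b = [(code >> s) & 3 for s in (6, 4, 2, 0)]
        rc = 0
        for x in reversed(b):  # complement read 3'->5'
            rc = (rc << 2) | (3 - x)
        canon_code[code] = min(code, rc)
    classes = np.unique(canon_code)
    lookup = np.empty(256, dtype=np.int64)
    for idx, c in enumerate(classes):
        lookup[canon_code == c] = idx
    labels = []
    for c in classes:
        labels.append("".join(_CODE_BASE[(int(c) >> s) & 3] for s in (6, 4, 2, 0)))
    return lookup, labels


_CANON_LOOKUP, TETRA_CLASS_LABELS = _build_canonical_map()
N_TETRA_CLASSES = len(TETRA_CLASS_LABELS)  # 136

assert N_TETRA_CLASSES == 136


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (uppercase ACGTN)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Fragment:
    parent_id: str
    start: int
    end: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.parent_id}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TetraProfile:
    """Canonical 4-mer frequency vector over the 136 strand-insensitive classes."""

    vector: np.ndarray
    n_counted: int

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (N_TETRA_CLASSES,):
            raise ValueError(f"expected {N_TETRA_CLASSES} classes, got {self.vector.shape}")


@dataclass
class GCSkewProfile:
    window_size: int
    skew: np.ndarray
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.skew = np.asarray(self.skew, dtype=float)
        self.cumulative = np.cumsum(self.skew)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3; any other symbol (N etc.) as -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def tetra_profile(record: SequenceRecord | str) -> TetraProfile:
    """Canonical tetranucleotide frequency profile of a sequence.

    Slides a 4-bp window with step 1; windows containing any non-ACGT symbol
    are skipped entirely. Counts are collapsed onto the 136 reverse-complement
    classes and normalised to frequencies.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record.upper()
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 bp has no tetranucleotides")
    codes = encode_sequence(seq)
    valid = codes >= 0
    # window valid iff all 4 positions valid
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    word = (
        (codes[:-3] << 6)
        | (codes[1:-2] << 4)
        | (codes[2:-1] << 2)
        | codes[3:]
    )
    word = word[ok]
    counts = np.bincount(_CANON_LOOKUP[word], minlength=N_TETRA_CLASSES).astype(float)
    n = int(word.size)
    if n > 0:
        counts /= n
    return TetraProfile(vector=counts, n_counted=n)


def gc_content(record: SequenceRecord | str) -> float:
    """(G+C) / (A+C+G+T); Ns are excluded from the denominator."""
    seq = record.sequence if isinstance(record, SequenceRecord) else record.upper()
    if not seq:
        raise ValueError("empty sequence")
    codes = encode_sequence(seq)
    acgt = int(np.count_nonzero(codes >= 0))
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases; GC undefined")
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / acgt


def fragment_sections(
    record: SequenceRecord,
    section_len: int = 20_000,
    min_len: int = 10_000,
) -> list[Fragment]:
    """Tile a record into sections of ``section_len`` with a length floor.

    Records shorter than ``min_len`` yield nothing. A terminal remainder
    shorter than the floor is appended to the previous section when the merged
    section stays within ``section_len``; otherwise the previous section and
    the remainder are re-split into two near-equal parts, each at least
    ``min_len``. The tiling is gap-free and covers the whole record.
    """
    L = len(record)
    if L < min_len:
        return []
    bounds: list[tuple[int, int]] = []
    pos = 0
    while L - pos >= section_len:
        bounds.append((pos, pos + section_len))
        pos += section_len
    r = L - pos
    if r >= min_len:
        bounds.append((pos, L))
    elif r > 0:
        last_start, last_end = bounds.pop()
        if (last_end - last_start) + r <= section_len:
            bounds.append((last_start, L))
        else:
            total = L - last_start
            half = total // 2
            bounds.append((last_start, last_start + half))
            bounds.append((last_start + half, L))
    return [
        Fragment(record.id, s, e, record.sequence[s:e]) for s, e in bounds
    ]


def gc_skew(record: SequenceRecord | str, window: int) -> GCSkewProfile:
    """Per-window (G-C)/(G+C) skew; trailing partial window dropped.

    Windows with no G or C score 0. The cumulative curve of a well-assembled
    circular replicon changes slope at the replication origin and terminus.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    seq = record.sequence if isinstance(record, SequenceRecord) else record.upper()
    codes = encode_sequence(seq)
    n_win = len(codes) // window
    skews = np.zeros(n_win, dtype=float)
    for i in range(n_win):
        w = codes[i * window : (i + 1) * window]
        g = int(np.count_nonzero(w == 2))
        c = int(np.count_nonzero(w == 1))
        skews[i] = 0.0 if g + c == 0 else (g - c) / (g + c)
    return GCSkewProfile(window_size=window, skew=skews)


def _vshape_score(steps: np.ndarray) -> float:
    """Fraction of steps consistent with a single origin/terminus pair.

    The cumulative skew of a correctly arranged replicon is unimodal: it
    rises until one turning point and falls after it (or the mirror image).
    Zero steps are consistent with either phase.
    """
    m = steps.size
    if m == 0:
        return 1.0
    inc = (steps >= 0).astype(int)
    dec = (steps <= 0).astype(int)
    inc_prefix = np.concatenate([[0], np.cumsum(inc)])
    dec_prefix = np.concatenate([[0], np.cumsum(dec)])
    total_dec = dec_prefix[-1]
    total_inc = inc_prefix[-1]
    # peak at p: rises on [0,p), falls on [p,m)
    up_down = max(inc_prefix[p] + (total_dec - dec_prefix[p]) for p in range(m + 1))
    down_up = max(dec_prefix[p] + (total_inc - inc_prefix[p]) for p in range(m + 1))
    return max(up_down, down_up) / m


def order_and_orient(
    scaffolds: list[SequenceRecord],
    window: int = 1000,
    max_exhaustive: int = 6,
) -> tuple[list[tuple[str, str]], float]:
    """Order and orient scaffolds by maximising GC-skew smoothness.

    Searches arrangements (orders and per-scaffold orientations) for the one
    whose concatenated cumulative skew is closest to unimodal — one global
    maximum and one global minimum, the signature of a single replication
    origin/terminus pair. Among equally unimodal arrangements the smoothest
    skew series wins (smallest total variation of the windowed skew): skew
    drifts gradually along a replichore, so an out-of-order scaffold shows
    up as a jump. Exhaustive for small inputs, greedy insertion beyond
    ``max_exhaustive`` scaffolds.

    Returns ([(scaffold_id, '+'|'-'), ...], score) where score is the
    fraction of skew steps consistent with the best unimodal shape. The
    mirror arrangement (reversed order, every orientation flipped) describes
    the same molecule read from the other strand and scores identically;
    which of the two is returned is arbitrary.
    """
    if not scaffolds:
        raise ValueError("need at least one scaffold")
    fwd = [gc_skew(s, window).skew for s in scaffolds]
    if len(scaffolds) == 1:
        return [(scaffolds[0].id, "+")], _vshape_score(fwd[0])
    rev = [-a[::-1] for a in fwd]

    def steps_for(arr: list[tuple[int, str]]) -> np.ndarray:
        parts = [fwd[i] if o == "+" else rev[i] for i, o in arr]
        return np.concatenate(parts)

    def key(arr: list[tuple[int, str]]) -> tuple[float, float]:
        steps = steps_for(arr)
        tv = float(np.sum(np.abs(np.diff(steps)))) if steps.size > 1 else 0.0
        return (_vshape_score(steps), -tv)

    n = len(scaffolds)
    if n <= max_exhaustive:
        best_arr, best_key = None, (-2.0, 0.0)
        for perm in itertools.permutations(range(n)):
            for mask in range(2 ** n):
                arr = [
                    (perm[k], "+" if not (mask >> k) & 1 else "-")
                    for k in range(n)
                ]
                k = key(arr)
                if k > best_key:
                    best_arr, best_key = arr, k
    else:
        order = sorted(range(n), key=lambda i: -fwd[i].size)
        best_arr = [(order[0], "+")]
        for i in order[1:]:
            cands = []
            for pos in range(len(best_arr) + 1):
                for o in ("+", "-"):
                    trial = best_arr[:pos] + [(i, o)] + best_arr[pos:]
                    cands.append((key(trial), trial))
            _best_key, best_arr = max(cands, key=lambda t: t[0])
    return (
        [(scaffolds[i].id, o) for i, o in best_arr],
        float(_vshape_score(steps_for(best_arr))),
    )
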