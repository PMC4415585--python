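"""Read recruitment at identity thresholds and enrichment arithmetic.

Metagenomic reads are mapped to reconstructed genetic structures with an
ungapped, full-read-length identity requirement (canonical thresholds 97%
and 90%). Per-structure read counts become relative proportions (% of the
sample's reads), detection calls (>= 10 reads), relative in-situ enrichment
factors (microcosm proportion over natural proportion, or a lower bound when
the structure sits below the natural dataset's detection limit), and
cells-per-gram estimates assuming ~1e9 bacterial cells per gram of surface
soil.

Identity is matches / read length for an ungapped placement spanning every
read base; placements are found by exact 16-mer seeding on both strands and
verified by direct comparison. This is a deliberate simplification of gapped
read mapping, adequate for substitution-only reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .composition import SequenceRecord, encode_sequence
from .synthetic import ReadSet

SEED_K = 16
DETECTION_MIN_READS = 10


@dataclass(frozen=True)
class MappingPolicy:
    identity_threshold: float = 0.97
    require_full_read_length: bool = True
    min_alignment_length: int = 200  # screening mode only
    one_best_target: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class RecruitmentResult:
    sample_id: str
    structure_id: str
    reads_mapped: int
    proportion_pct: float
    mean_coverage: float


@dataclass
class EnrichmentFactor:
    structure_id: str
    factor: float
    is_lower_bound: bool
    sig_figs: int = 2


@dataclass
class CellAbundanceEstimate:
    structure_id: str
    cells_per_gram: float


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


class StructureIndex:
    """Exact 16-mer positional index over a set of structures."""

    def __init__(self, structures: list[SequenceRecord]):
        if not structures:
            raise ValueError("need at least one structure")
        self.structures = structures
        self.codes = [encode_sequence(s.sequence) for s in structures]
        self.index: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for si, codes in enumerate(self.codes):
            for pos, kmer in _kmer_codes(codes, SEED_K):
                self.index[kmer].append((si, pos))


def _kmer_codes(codes: np.ndarray, k: int):
    """Yield (position, integer code) for each k-mer without Ns."""
    n = codes.size
    if n < k:
        return
    valid = codes >= 0
    ok = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        ok &= valid[off : off + n - k + 1]
    kmers = np.zeros(n - k + 1, dtype=np.int64)
    for off in range(k):
        kmers = (kmers << 2) | np.where(valid[off : off + n - k + 1], codes[off : off + n - k + 1], 0)
    for pos in np.flatnonzero(ok):
        yield int(pos), int(kmers[pos])


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    mask = out >= 0
    out[mask] = 3 - out[mask]
    return out


def _best_placement(
    read_codes: np.ndarray, struct_codes: np.ndarray, starts: set[int]
) -> tuple[float, int]:
    """Best full-length ungapped identity among candidate start offsets."""
    L = read_codes.size
    best, best_start = -1.0, -1
    for s in starts:
        if s < 0 or s + L > struct_codes.size:
            continue
        ident = float(np.mean(read_codes == struct_codes[s : s + L]))
        if ident > best:
            best, best_start = ident, s
    return best, best_start


def _candidate_starts(
    index: StructureIndex, read_codes: np.ndarray, stride: int = 4
) -> dict[int, set[int]]:
    """Seed hits -> candidate placement starts per structure."""
    cands: dict[int, set[int]] = defaultdict(set)
    kmers = list(_kmer_codes(read_codes, SEED_K))
    for off, kmer in kmers[::stride] + kmers[-1:]:
        for si, pos in index.index.get(kmer, ()):
            cands[si].add(pos - off)
    return cands


def map_reads(
    reads: ReadSet,
    structures: list[SequenceRecord],
    policy: MappingPolicy = MappingPolicy(),
) -> list[RecruitmentResult]:
    """Recruit reads to structures under an identity policy.

    A read is recruited iff an ungapped placement (either strand) covers the
    entire read at identity >= the threshold. With ``one_best_target`` each
    read counts toward a single structure: highest identity, ties to the
    lexicographically smallest structure id. Returns one result per
    structure, including zero-read structures.
    """
    idx = StructureIndex(structures)
    n_total = len(reads)
    order = sorted(range(len(structures)), key=lambda i: structures[i].id)
    counts = np.zeros(len(structures), dtype=int)
    mapped_bases = np.zeros(len(structures), dtype=float)
    for read in reads:
        rc_fwd = encode_sequence(read.sequence)
        hits: list[tuple[float, str, int]] = []  # (identity, structure_id, si)
        for codes in (rc_fwd, _revcomp_codes(rc_fwd)):
            for si, starts in _candidate_starts(idx, codes).items():
                ident, _ = _best_placement(codes, idx.codes[si], starts)
                if ident >= policy.identity_threshold:
                    hits.append((ident, structures[si].id, si))
        if not hits:
            continue
        if policy.one_best_target:
            # highest identity; ties to the smallest structure id
            ident, _sid, si = min(hits, key=lambda h: (-h[0], h[1]))
            counts[si] += 1
            mapped_bases[si] += rc_fwd.size
        else:
            seen = set()
            for ident, _sid, si in hits:
                if si not in seen:
                    counts[si] += 1
                    mapped_bases[si] += rc_fwd.size
                    seen.add(si)
    results = []
    for i in order:
        s = structures[i]
        results.append(
            RecruitmentResult(
                sample_id=reads.sample_id,
                structure_id=s.id,
                reads_mapped=int(counts[i]),
                proportion_pct=100.0 * counts[i] / n_total if n_total else 0.0,
                mean_coverage=mapped_bases[i] / len(s.sequence),
            )
        )
    return results


def detect(result: RecruitmentResult, min_reads: int = DETECTION_MIN_READS) -> bool:
    """Positive detection: at least ``min_reads`` recruited reads."""
    return result.reads_mapped >= min_reads


def detection_limit_pct(total_reads: int, min_reads: int = DETECTION_MIN_READS) -> float:
    """Smallest detectable proportion (%) given the dataset's read count."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return 100.0 * min_reads / total_reads


def enrichment_factor(
    p_microcosm_pct: float,
    p_natural_pct: float | None,
    detection_limit_pct: float,
    structure_id: str = "",
) -> EnrichmentFactor:
    """Relative in-situ enrichment: microcosm proportion over natural.

    When the structure was undetected in the natural community
    (``p_natural_pct`` below the detection limit or None), the factor is a
    lower bound computed against the detection limit. Reported at 2
    significant figures.
    """
    if p_microcosm_pct <= 0:
        raise ValueError("microcosm proportion must be positive")
    undetected = p_natural_pct is None or p_natural_pct < detection_limit_pct
    if undetected:
        if detection_limit_pct <= 0:
            raise ValueError("need a positive detection limit for a lower bound")
        factor = p_microcosm_pct / detection_limit_pct
    else:
        if p_natural_pct <= 0:
            raise ValueError("natural proportion and detection limit both zero")
        factor = p_microcosm_pct / p_natural_pct
    return EnrichmentFactor(
        structure_id=structure_id,
        factor=round_sig(factor, 2),
        is_lower_bound=bool(undetected),
    )


def estimate_cells(
    p_natural_pct: float, structure_id: str = "", cells_per_gram_soil: float = 1e9
) -> CellAbundanceEstimate:
    """Cells per gram of soil from a natural-community read proportion."""
    if p_natural_pct < 0:
        raise ValueError("proportion must be >= 0")
    return CellAbundanceEstimate(
        structure_id=structure_id,
        cells_per_gram=round_sig(p_natural_pct / 100.0 * cells_per_gram_soil, 2),
    )


# ---------------------------------------------------------------------------
# marker-read screening and consensus building
# ---------------------------------------------------------------------------

def _best_local_window(
    read_codes: np.ndarray, struct_codes: np.ndarray, start: int, min_len: int
) -> float:
    """Best identity over windows of exactly ``min_len`` on one diagonal.

    The diagonal is the ungapped placement of the read at structure offset
    ``start`` (may hang off either end; only the overlapping part counts).
    """
    L = read_codes.size
    r0 = max(0, -start)
    s0 = max(0, start)
    span = min(L - r0, struct_codes.size - s0)
    if span < min_len:
        return -1.0
    m = (read_codes[r0 : r0 + span] == struct_codes[s0 : s0 + span]).astype(float)
    c = np.concatenate([[0.0], np.cumsum(m)])
    wins = (c[min_len:] - c[:-min_len]) / min_len
    return float(wins.max())


def screen_marker_reads(
    reads: ReadSet,
    marker_refs: list[tuple[str, SequenceRecord]],
    policy: MappingPolicy = MappingPolicy(identity_threshold=0.90, min_alignment_length=200),
) -> dict[str, list]:
    """Partition reads by best-matching taxon via local ungapped alignment.

    ``marker_refs`` pairs a genus-like taxon label with a reference sequence
    (e.g. a 16S gene). A read is kept when some reference carries a local
    ungapped alignment of at least ``min_alignment_length`` bases at the
    identity threshold; it is assigned to the taxon of the best-identity
    reference.
    """
    refs = [r for _t, r in marker_refs]
    taxa = [t for t, _r in marker_refs]
    idx = StructureIndex(refs)
    out: dict[str, list] = defaultdict(list)
    for read in reads:
        fwd = encode_sequence(read.sequence)
        best_t, best_i = None, -1.0
        for codes in (fwd, _revcomp_codes(fwd)):
            for si, starts in _candidate_starts(idx, codes, stride=2).items():
                for s in starts:
                    ident = _best_local_window(
                        codes, idx.codes[si], s, policy.min_alignment_length
                    )
                    if ident > best_i:
                        best_i, best_t = ident, taxa[si]
        if best_t is not None and best_i >= policy.identity_threshold:
            out[best_t].append(read)
    return dict(out)


def _overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Largest suffix(a)/prefix(b) ungapped overlap meeting the thresholds."""
    ca, cb = encode_sequence(a), encode_sequence(b)
    for L in range(min(len(a), len(b)), min_overlap - 1, -1):
        ident = float(np.mean(ca[-L:] == cb[:L]))
        if ident >= min_identity:
            return L
    return 0


def consensus_by_taxon(
    partitioned: dict[str, list],
    min_overlap: int = 100,
    min_identity: float = 0.99,
) -> dict[str, SequenceRecord]:
    """Greedy overlap-layout consensus per taxon.

    Reads are laid out by repeatedly appending the read with the best
    qualifying overlap (>= ``min_overlap`` nt at >= ``min_identity``); each
    read joins at most one contig; columns are resolved by majority vote.
    The longest contig is returned as the taxon consensus; with no
    qualifying overlaps the longest read stands in.
    """
    out: dict[str, SequenceRecord] = {}
    for taxon, reads in partitioned.items():
        if not reads:
            raise ValueError(f"no reads for taxon {taxon!r}")
        seqs = sorted((r.sequence for r in reads), key=len, reverse=True)
        contigs: list[list[tuple[int, str]]] = []  # layout: (offset, read seq)
        unused = list(seqs)
        while unused:
            layout = [(0, unused.pop(0))]
            grown = True
            while grown and unused:
                grown = False
                cur = _layout_consensus(layout)
                for i, s in enumerate(unused):
                    L = _overlap(cur, s, min_overlap, min_identity)
                    if L >= min_overlap:
                        layout.append((len(cur) - L, unused.pop(i)))
                        grown = True
                        break
                    L = _overlap(s, cur, min_overlap, min_identity)
                    if L >= min_overlap:
                        shift = len(s) - L
                        layout = [(off + shift, q) for off, q in layout]
                        layout.append((0, unused.pop(i)))
                        grown = True
                        break
            contigs.append(layout)
        best = max((_layout_consensus(lay) for lay in contigs), key=len)
        out[taxon] = SequenceRecord(id=f"consensus_{taxon}", sequence=best)
    return out


def _layout_consensus(layout: list[tuple[int, str]]) -> str:
    """Per-column majority vote over a pile of offset reads."""
    end = max(off + len(s) for off, s in layout)
    counts = np.zeros((end, 4), dtype=int)
    for off, s in layout:
        codes = encode_sequence(s)
        for j, c in enumerate(codes):
            if c >= 0:
                counts[off + j, c] += 1
    covered = counts.sum(axis=1) > 0
    best = counts.argmax(axis=1)
    return "".join("ACGT"[b] for b, ok in zip(best, covered) if ok)
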