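"""Synthetic soil-community generator.

Emulates the inputs of an enrichment-microcosm metagenomics experiment so the
whole analysis pipeline can be exercised and validated without any external
download:

* genomes drawn from an order-3 Markov chain whose transition matrix is
  perturbed per genome, giving direct control over the tetranucleotide
  signature that composition-based binning relies on;
* a diverse "natural" community with near-uniform low abundances;
* stress-condition (ESC) scenarios in which a few genomes are multiplied by
  10^2-10^5 while the total DNA yield declines;
* 454-like reads (~350 nt) carrying substitution noise, with full truth
  records; and
* assembly-like contigs (>=10 kb) with per-contig coverage and carried-over
  gene/marker/function annotations.

All randomness flows through explicit integer seeds; identical (spec, seed)
pairs yield identical output. Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import _CODE_BASE, reverse_complement

# Shared base transition matrix: every genome starts from these logits and
# diverges by Gaussian perturbation. Fixed internal seed so the base
# composition is a package constant, not a user-visible parameter.
_BASE_MATRIX_SEED = 771_203
_N_CONTEXTS = 64  # order-3: context = previous 3 bases

ANNOT_COLUMNS = ["start", "end", "kind", "label"]

MARKER_FAMILY_FMT = "SCG{:03d}"
TRNA_CLASS_FMT = "aaRS{:02d}"
N_TRNA_CLASSES = 20


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome."""

    genome_id: str
    length_bp: int = 100_000
    gc_target: float = 0.5
    composition_divergence: float = 1.0
    taxon_label: str = "GenusA"
    n_marker_families: int = 40
    function_pool_shared: int = 200
    function_pool_unique: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if self.composition_divergence < 0:
            raise ValueError("composition_divergence must be >= 0")


@dataclass
class AnnotatedGenome:
    """A generated genome with marker/tRNA-synthetase/function annotations.

    ``annotations`` columns: start, end, kind ∈ {marker, trna, gene}, label.
    """

    genome_id: str
    sequence: str
    taxon_label: str
    annotations: pd.DataFrame
    spec: GenomeSpec

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunityProfile:
    condition_label: str
    replicate_id: str
    abundances: dict[str, float]
    dna_yield: float = 25.0

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("negative abundance")
        if self.dna_yield < 0:
            raise ValueError("dna_yield must be >= 0")


@dataclass(frozen=True)
class EnrichmentScenario:
    """Per-ESC enrichment: genome multipliers plus a DNA-yield decline.

    Genomes absent from ``multipliers`` implicitly keep multiplier 1.
    """

    esc_label: str
    multipliers: dict[str, float]
    dna_decline_factor: float = 1.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be positive")
        if not 0 < self.dna_decline_factor <= 1:
            raise ValueError("dna_decline_factor must be in (0, 1]")


@dataclass
class Read:
    read_id: str
    sequence: str
    true_origin: str
    true_start: int
    true_substitutions: int
    strand: str = "+"


@dataclass
class ReadSet:
    reads: list[Read]
    mean_length: float
    length_sd: float
    error_rate: float
    sample_id: str = "sample"

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class Contig:
    contig_id: str
    source: str
    start: int
    end: int
    sequence: str
    mean_coverage: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ContigSet:
    """Assembly-like output: contigs plus annotations in contig coordinates.

    ``annotations`` columns: contig_id, start, end, kind, label.
    """

    contigs: list[Contig]
    annotations: pd.DataFrame

    def __len__(self) -> int:
        return len(self.contigs)

    def get(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _base_logits() -> np.ndarray:
    rng = np.random.default_rng(_BASE_MATRIX_SEED)
    return rng.normal(0.0, 0.3, size=(_N_CONTEXTS, 4))


def _stationary_gc(probs: np.ndarray) -> float:
    """Stationary single-base GC fraction of the order-3 chain."""
    # context transition: c=(b1,b2,b3) -> c'=(b2,b3,b); 64x64
    T = np.zeros((_N_CONTEXTS, _N_CONTEXTS))
    for c in range(_N_CONTEXTS):
        nxt_base = (c * 4) % _N_CONTEXTS
        for b in range(4):
            T[c, nxt_base + b] += probs[c, b]
    pi = np.full(_N_CONTEXTS, 1.0 / _N_CONTEXTS)
    for _ in range(300):
        pi = pi @ T
    base_freq = np.zeros(4)
    for b in range(4):
        base_freq[b] = float(np.sum(pi * probs[:, b]))
    return base_freq[1] + base_freq[2]  # C + G


def _tilted_probs(logits: np.ndarray, w: float) -> np.ndarray:
    tilt = np.array([0.0, w, w, 0.0])
    z = logits + tilt
    z = z - z.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


def _calibrate_gc(logits: np.ndarray, gc_target: float) -> np.ndarray:
    """Bisect the GC tilt so the chain's stationary GC hits the target."""
    lo, hi = -12.0, 12.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _stationary_gc(_tilted_probs(logits, mid)) < gc_target:
            lo = mid
        else:
            hi = mid
    return _tilted_probs(logits, 0.5 * (lo + hi))


def _sample_chain(probs: np.ndarray, length: int, rng: np.random.Generator) -> str:
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    ctx = int(rng.integers(_N_CONTEXTS))
    for i in range(length):
        row = cum[ctx]
        b = int(np.searchsorted(row, u[i], side="right"))
        if b > 3:
            b = 3
        out[i] = b
        ctx = ((ctx * 4) + b) % _N_CONTEXTS
    return "".join(_CODE_BASE[b] for b in out)


def _place_annotations(spec: GenomeSpec, rng: np.random.Generator) -> pd.DataFrame:
    L = spec.length_bp
    rows: list[tuple[int, int, str, str]] = []
    marker_len = 900
    if spec.n_marker_families > 0:
        stride = L / spec.n_marker_families
        if stride < marker_len:
            raise ValueError(
                f"genome of {L} bp too short to place "
                f"{spec.n_marker_families} non-overlapping {marker_len}-bp markers"
            )
        for i in range(spec.n_marker_families):
            s = int(i * stride)
            rows.append((s, s + marker_len, "marker", MARKER_FAMILY_FMT.format(i)))
    trna_len = 300
    if L >= N_TRNA_CLASSES * 2 * trna_len:
        stride = L / N_TRNA_CLASSES
        for i in range(N_TRNA_CLASSES):
            s = int(i * stride) + marker_len + 50  # phase-shifted past markers
            rows.append((s, s + trna_len, "trna", TRNA_CLASS_FMT.format(i)))
    # protein-coding genes every ~1 kb, labels drawn from shared+unique pools
    gene_len, gene_stride = 700, 1000
    labels = [f"FN{j:05d}" for j in range(spec.function_pool_shared)]
    labels += [f"FN:{spec.genome_id}:u{j:03d}" for j in range(spec.function_pool_unique)]
    pos = 0
    while pos + gene_len <= L:
        lab = labels[int(rng.integers(len(labels)))]
        rows.append((pos, pos + gene_len, "gene", lab))
        pos += gene_stride
    df = pd.DataFrame(rows, columns=ANNOT_COLUMNS)
    return df.sort_values(["start", "kind"], kind="stable").reset_index(drop=True)


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Generate one annotated genome from its spec, deterministically.

    The sequence comes from an order-3 Markov chain: shared base logits are
    perturbed with Gaussian noise of scale ``composition_divergence`` (seeded
    per genome), then exponentially tilted so the stationary GC fraction hits
    ``gc_target``; the realised GC lands within ~0.02 of the target for
    genomes of tens of kilobases and up.
    """
    rng = np.random.default_rng(spec.seed)
    logits = _base_logits()
    if spec.composition_divergence > 0:
        logits = logits + rng.normal(0.0, spec.composition_divergence, size=logits.shape)
    probs = _calibrate_gc(logits, spec.gc_target)
    seq = _sample_chain(probs, spec.length_bp, rng)
    ann = _place_annotations(spec, rng)
    return AnnotatedGenome(
        genome_id=spec.genome_id,
        sequence=seq,
        taxon_label=spec.taxon_label,
        annotations=ann,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# communities and enrichment
# ---------------------------------------------------------------------------

def generate_community(
    genome_ids: list[str],
    model: str = "lognormal",
    sigma: float = 1.0,
    seed: int = 0,
    condition_label: str = "natural",
    replicate_id: str = "r1",
    dna_yield: float = 25.0,
) -> CommunityProfile:
    """Relative-abundance profile over genomes.

    ``model='uniform'`` gives equal abundances (the near-uniform natural soil
    community); ``model='lognormal'`` draws exp(N(0, sigma)) weights and
    normalises (sigma=0 degenerates to uniform).
    """
    if not genome_ids:
        raise ValueError("need at least one genome")
    n = len(genome_ids)
    if model == "uniform" or (model == "lognormal" and sigma == 0):
        weights = np.ones(n)
    elif model == "lognormal":
        rng = np.random.default_rng(seed)
        weights = np.exp(rng.normal(0.0, sigma, size=n))
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    weights = weights / weights.sum()
    return CommunityProfile(
        condition_label=condition_label,
        replicate_id=replicate_id,
        abundances=dict(zip(genome_ids, weights.tolist())),
        dna_yield=dna_yield,
    )


def apply_esc(natural: CommunityProfile, scenario: EnrichmentScenario) -> CommunityProfile:
    """Apply a stress-condition enrichment to a community.

    New abundances are proportional to old x multiplier, renormalised; the
    DNA yield is multiplied by the decline factor (enriched populations grow
    relative to a community whose total DNA is shrinking).
    """
    unknown = set(scenario.multipliers) - set(natural.abundances)
    if unknown:
        raise KeyError(f"multipliers reference unknown genomes: {sorted(unknown)}")
    raw = {
        g: a * scenario.multipliers.get(g, 1.0)
        for g, a in natural.abundances.items()
    }
    total = sum(raw.values())
    return CommunityProfile(
        condition_label=scenario.esc_label,
        replicate_id=natural.replicate_id,
        abundances={g: v / total for g, v in raw.items()},
        dna_yield=natural.dna_yield * scenario.dna_decline_factor,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    profile: CommunityProfile,
    genomes: dict[str, AnnotatedGenome],
    n_reads: int,
    mean_length: float = 350.0,
    length_sd: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_id: str | None = None,
    both_strands: bool = False,
) -> ReadSet:
    """Simulate pyrosequencing-like reads from a community.

    Expected reads per genome are proportional to abundance x genome length
    (longer genomes shed more fragments per cell); positions are uniform,
    lengths Gaussian (clipped to [50, genome length]), substitutions i.i.d.
    per base at ``error_rate``. Forward strand only unless ``both_strands``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = sorted(profile.abundances)
    weights = np.array(
        [profile.abundances[g] * len(genomes[g]) for g in ids], dtype=float
    )
    weights = weights / weights.sum()
    origins = rng.choice(len(ids), size=n_reads, p=weights)
    lengths = np.clip(
        np.rint(rng.normal(mean_length, length_sd, size=n_reads)), 50, None
    ).astype(int)
    reads: list[Read] = []
    other = "ACGT"
    for i in range(n_reads):
        g = genomes[ids[origins[i]]]
        L = min(int(lengths[i]), len(g))
        start = int(rng.integers(0, len(g) - L + 1))
        seq = g.sequence[start : start + L]
        strand = "+"
        if both_strands and rng.random() < 0.5:
            seq = reverse_complement(seq)
            strand = "-"
        n_sub = 0
        if error_rate > 0:
            hits = np.flatnonzero(rng.random(L) < error_rate)
            if hits.size:
                chars = list(seq)
                for j in hits:
                    cur = chars[j]
                    repl = other[int(rng.integers(3))]
                    if repl == cur:  # pick a different base deterministically
                        repl = other[(other.index(cur) + 1) % 4]
                    chars[j] = repl
                seq = "".join(chars)
                n_sub = int(hits.size)
        reads.append(
            Read(
                read_id=f"read{i:07d}",
                sequence=seq,
                true_origin=g.genome_id,
                true_start=start,
                true_substitutions=n_sub,
                strand=strand,
            )
        )
    return ReadSet(
        reads=reads,
        mean_length=mean_length,
        length_sd=length_sd,
        error_rate=error_rate,
        sample_id=sample_id or f"{profile.condition_label}_{profile.replicate_id}",
    )


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def emit_contigs(
    profile: CommunityProfile,
    genomes: dict[str, AnnotatedGenome],
    coverage_per_abundance: float = 100.0,
    assembly_floor_coverage: float = 5.0,
    mean_contig_len: int = 40_000,
    min_contig_len: int = 10_000,
    seed: int = 0,
) -> ContigSet:
    """Emulate assembly output without running an assembler.

    A genome's implied coverage is abundance x ``coverage_per_abundance``.
    Genomes at or above the assembly floor yield contigs tiling >=80% of the
    genome, broken at random points with small inter-contig gaps; genomes
    below the floor yield nothing (they stay unassembled, like the rare
    biosphere). Annotations fully contained in a contig are carried over in
    contig coordinates. Per-contig coverage is the implied coverage with
    ~5% multiplicative noise.
    """
    if coverage_per_abundance <= 0 or assembly_floor_coverage <= 0:
        raise ValueError("coverage parameters must be positive")
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    ann_rows: list[tuple] = []
    for gid in sorted(profile.abundances):
        implied = profile.abundances[gid] * coverage_per_abundance
        if implied < assembly_floor_coverage:
            continue
        g = genomes[gid]
        L = len(g)
        pos, k = 0, 0
        while L - pos >= min_contig_len:
            clen = int(rng.normal(mean_contig_len, mean_contig_len * 0.3))
            clen = max(min_contig_len, min(clen, L - pos))
            if L - (pos + clen) < min_contig_len:
                clen = L - pos  # absorb the unassemblable tail
            end = pos + clen
            cov = implied * float(np.clip(rng.normal(1.0, 0.05), 0.5, 1.5))
            cid = f"{gid}.c{k:03d}"
            contigs.append(
                Contig(cid, gid, pos, end, g.sequence[pos:end], cov)
            )
            sub = g.annotations[
                (g.annotations["start"] >= pos) & (g.annotations["end"] <= end)
            ]
            for _, r in sub.iterrows():
                ann_rows.append(
                    (cid, int(r["start"] - pos), int(r["end"] - pos), r["kind"], r["label"])
                )
            gap = int(rng.integers(0, max(1, int(0.04 * clen))))  # <=4% loss per junction
            pos = end + gap
            k += 1
    ann = pd.DataFrame(ann_rows, columns=["contig_id", *ANNOT_COLUMNS])
    return ContigSet(contigs=contigs, annotations=ann)


def tile_genome(
    genome: AnnotatedGenome, tile_len: int, coverage: float = 30.0
) -> ContigSet:
    """Exact gap-free partition of a genome into fixed-length tiles.

    Unlike :func:`emit_contigs` there are no inter-contig gaps, so an
    annotation is lost only when it straddles a tile boundary. Useful for
    constructing truth bins and subsampling experiments where the retained
    genome fraction should translate directly into retained annotations.
    """
    if tile_len < 1:
        raise ValueError("tile_len must be positive")
    L = len(genome)
    contigs = []
    ann_rows = []
    k = 0
    for pos in range(0, L, tile_len):
        end = min(pos + tile_len, L)
        cid = f"{genome.genome_id}.t{k:04d}"
        contigs.append(
            Contig(cid, genome.genome_id, pos, end, genome.sequence[pos:end], coverage)
        )
        sub = genome.annotations[
            (genome.annotations["start"] >= pos) & (genome.annotations["end"] <= end)
        ]
        for _, r in sub.iterrows():
            ann_rows.append(
                (cid, int(r["start"] - pos), int(r["end"] - pos), r["kind"], r["label"])
            )
        k += 1
    ann = pd.DataFrame(ann_rows, columns=["contig_id", *ANNOT_COLUMNS])
    return ContigSet(contigs=contigs, annotations=ann)


def default_scenarios(genome_ids: list[str], seed: int = 0) -> list[EnrichmentScenario]:
    """Canonical ESC set: each scenario enriches 1-3 genomes by 10^2-10^5
    while total DNA declines to a few percent of the untreated yield."""
    rng = np.random.default_rng(seed)
    labels = ["ethanol", "salt", "heat", "nitrogen", "diesel", "metals", "mercury"]
    scenarios = []
    ids = list(genome_ids)
    for i, lab in enumerate(labels[: max(1, len(ids) // 2)]):
        k = int(rng.integers(1, min(3, len(ids)) + 1))
        chosen = rng.choice(len(ids), size=k, replace=False)
        mult = {
            ids[int(c)]: float(10 ** rng.uniform(2, 5)) for c in chosen
        }
        scenarios.append(
            EnrichmentScenario(
                esc_label=lab,
                multipliers=mult,
                dna_decline_factor=float(rng.uniform(0.03, 0.6)),
            )
        )
    return scenarios
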