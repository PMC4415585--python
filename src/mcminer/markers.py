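"""Marker-gene tallies, completion scores and function catalogs.

Bins are scored for completeness against a collection of universal
single-copy gene families (default 40 synthetic families, one expected copy
per genome): the completion score is simply the fraction of families with at
least one copy in the bin. Duplicated families are reported separately —
they signal co-binned relatives — but do not reduce the score. tRNA
synthetase classes (20, one per amino acid) give a second, coarser
completeness axis. Function catalogs are deduplicated label sets used for
unique/core accounting and network building downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import MARKER_FAMILY_FMT, N_TRNA_CLASSES


@dataclass(frozen=True)
class MarkerSet:
    family_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("marker family ids must be unique")

    def __len__(self) -> int:
        return len(self.family_ids)


def default_marker_set(n_families: int = 40) -> MarkerSet:
    return MarkerSet(tuple(MARKER_FAMILY_FMT.format(i) for i in range(n_families)))


@dataclass
class CompletionEstimate:
    bin_id: str
    fraction_present: float
    duplicated_families: int


@dataclass
class FunctionCatalog:
    owner_id: str
    labels: frozenset[str]
    gene_count: int

    def __len__(self) -> int:
        return len(self.labels)


def _bin_annotations(contig_ids: list[str], annotations: pd.DataFrame) -> pd.DataFrame:
    return annotations[annotations["contig_id"].isin(set(contig_ids))]


def tally_markers(contig_ids: list[str], annotations: pd.DataFrame) -> dict[str, int]:
    """Copy count per marker family among the given contigs.

    ``annotations`` columns: contig_id, start, end, kind, label.
    """
    sub = _bin_annotations(contig_ids, annotations)
    markers = sub[sub["kind"] == "marker"]
    return markers["label"].value_counts().to_dict()


def completion_score(
    tally: dict[str, int], marker_set: MarkerSet, bin_id: str = ""
) -> CompletionEstimate:
    """Fraction of single-copy families present; duplicates counted apart."""
    if len(marker_set) == 0:
        raise ValueError("empty marker set")
    present = sum(1 for f in marker_set.family_ids if tally.get(f, 0) >= 1)
    dup = sum(1 for f in marker_set.family_ids if tally.get(f, 0) >= 2)
    return CompletionEstimate(
        bin_id=bin_id,
        fraction_present=present / len(marker_set),
        duplicated_families=dup,
    )


def count_trna_classes(contig_ids: list[str], annotations: pd.DataFrame) -> int:
    """Number of distinct tRNA-synthetase classes (0..20) in the contigs."""
    sub = _bin_annotations(contig_ids, annotations)
    n = sub.loc[sub["kind"] == "trna", "label"].nunique()
    return int(min(n, N_TRNA_CLASSES))


def catalog_functions(
    owner_id: str, contig_ids: list[str], annotations: pd.DataFrame
) -> FunctionCatalog:
    """Deduplicated function-label set plus raw gene count for an owner."""
    sub = _bin_annotations(contig_ids, annotations)
    genes = sub[sub["kind"] == "gene"]
    return FunctionCatalog(
        owner_id=owner_id,
        labels=frozenset(genes["label"]),
        gene_count=int(len(genes)),
    )


def reference_coverage(draft: FunctionCatalog, reference: FunctionCatalog) -> float:
    """Fraction of the reference's functions found in the draft."""
    if not reference.labels:
        raise ValueError("empty reference catalog")
    return len(draft.labels & reference.labels) / len(reference.labels)
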