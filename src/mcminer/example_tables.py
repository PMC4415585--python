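"""Worked-example inputs: published summary values from a soil-microcosm
enrichment experiment.

These are the printed per-structure read proportions, sizes and unique
function counts from the study this pipeline emulates, bundled as *inputs*
for the arithmetic operations (enrichment factors, cell estimates, mean
draft-genome size, fold increases). Values below the natural dataset's
detection floor (printed as "<0.0001") are stored as None.

``genome_sizes_mb`` groups multi-replicon genomes (chromosomes plus
mega-plasmid) so per-genome sizes are the sum over replicons.
"""

from __future__ import annotations

import pandas as pd

# Natural-community detection floor implied by the >12M-read reference
# dataset and the 10-read detection rule.
NATURAL_DETECTION_LIMIT_PCT = 0.0001

# structure, microcosm proportion (%), natural proportion (% or None when
# below the detection floor)
_STRUCTURES = [
    ("Leifsonia_Metals-1", 7.5, 0.00012),
    ("Rhodanobacter_Metals-1", 14.1, None),
    ("Rhodanobacter_Metals-2", 9.4, 0.0008),
    ("Sporolactobacillus_Eth-1", 6.4, None),
    ("Ktedonobacter_Eth-1", 28.9, None),
    ("Acidobacteria_Mer-1", 4.0, None),
    ("Rhodanobacter_Mer-1-A", 12.6, 0.00034),
    ("Rhodanobacter_Mer-1-B", 5.0, 0.00038),
    ("Streptomyces_Mer-1-A", 8.9, 0.00042),
    ("Rhodanobacter_Mer-2", 11.5, 0.0008),
    ("Streptomyces_Mer-2-A", 8.2, 0.00061),
    ("Streptomyces_Mer-2-B", 3.8, 0.011),
    ("Burkholderia_Mer3-B", 7.9, 0.0079),
]


def structure_proportions() -> pd.DataFrame:
    """Self-consistent published (structure, microcosm %, natural %) rows."""
    return pd.DataFrame(
        _STRUCTURES, columns=["structure_id", "microcosm_pct", "natural_pct"]
    )


# Published draft-genome sizes (Mb); multi-replicon genomes summed.
GENOME_SIZES_MB: dict[str, float] = {
    "Leifsonia_Metals-1": 3.8,
    "Rhodanobacter_Metals-1": 4.0,
    "Leifsonia_Metals-2": 3.7,
    "Rhodanobacter_Metals-2": 4.0,
    "Sporolactobacillus_Eth-1": 3.4,
    "Ktedonobacter_Eth-1": 6.3,
    "Sporolactobacillus_Eth-2": 3.3,
    "Acidobacteria_Mer-1": 5.0,
    "Rhodanobacter_Mer-1-A": 5.4,
    "Rhodanobacter_Mer-1-B": 7.8,
    "Streptomyces_Mer-1-A": 9.0,
    "Acidobacteria_Mer-2": 4.8,
    "Rhodanobacter_Mer-2": 4.6,
    "Streptomyces_Mer-2-A": 9.0,
    "Streptomyces_Mer-2-B": 7.8,
    # two replicons + mega-plasmid each
    "Burkholderia_Mer3-A": 4.2 + 4.0 + 1.1,
    "Burkholderia_Mer3-B": 4.3 + 3.2 + 1.1,
}

# Unique-function counts: best enrichment condition vs controls.
UNIQUE_FUNCTIONS_BEST_ESC = 3155
UNIQUE_FUNCTIONS_CONTROL = 176

# Total natural-community proportion of all recovered structures (%), and
# the assumed bacterial cell density of surface soil (cells per gram).
TOTAL_NATURAL_PCT = 0.03
CELLS_PER_GRAM_SOIL = 1e9
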