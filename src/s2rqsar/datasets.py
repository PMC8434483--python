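"""Published dataset bookkeeping for the S2R ligand QSAR study.

The curated S2R ligand set was pooled from 16 literature sources; the
per-source compound counts and pKi ranges are recorded here so dataset
assembly arithmetic (159 modeled ligands; a screening benchmark of 191
actives plus 12,148 decoys totalling 12,339 entries) is reproducible
without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferenceSummary",
    "S2R_REFERENCE_SUMMARY",
    "total_curated_compounds",
    "assemble_screening_database",
    "PUBLISHED_N_ACTIVES",
    "PUBLISHED_N_DECOYS",
]

#: Published benchmark sizes for the pharmacophore-style screening set.
PUBLISHED_N_ACTIVES = 191
PUBLISHED_N_DECOYS = 12_148


@dataclass(frozen=True)
class ReferenceSummary:
    """One literature source of curated S2R ligands."""

    ref_id: int
    citation: str
    pki_min: float
    pki_max: float
    n_compounds: int


#: Per-source compound counts of the curated 159-ligand S2R set.
S2R_REFERENCE_SUMMARY: tuple[ReferenceSummary, ...] = (
    ReferenceSummary(1, "Ferorelli & Abate", 5.48, 7.71, 9),
    ReferenceSummary(2, "Mach & Huang (a)", 6.14, 8.09, 8),
    ReferenceSummary(3, "Huang & Luedtke", 6.39, 6.95, 4),
    ReferenceSummary(4, "Mach & Huang (b)", 6.29, 7.59, 9),
    ReferenceSummary(5, "Yarim & Koksal", 6.18, 8.00, 6),
    ReferenceSummary(6, "Abate & Ferorelli (a)", 6.51, 8.79, 14),
    ReferenceSummary(7, "Niso & Abate", 7.54, 10.40, 9),
    ReferenceSummary(8, "Abate & Ferorelli (b)", 7.29, 8.58, 8),
    ReferenceSummary(9, "Berardi & Ferorelli (a)", 7.52, 9.24, 4),
    ReferenceSummary(10, "Bai & Li", 5.99, 8.82, 22),
    ReferenceSummary(11, "Xie & Bergmann", 6.28, 7.64, 16),
    ReferenceSummary(12, "Berardi & Ferorelli (b)", 6.62, 7.75, 15),
    ReferenceSummary(13, "Ferorelli & Abate (b)", 6.17, 8.08, 8),
    ReferenceSummary(14, "Abate & Niso", 7.63, 9.31, 7),
    ReferenceSummary(15, "Xie & Kniess", 7.17, 8.52, 10),
    ReferenceSummary(16, "Schinina & Martorana", 5.33, 7.25, 10),
)


def total_curated_compounds() -> int:
    """Sum of per-source counts in the curated ligand set (159)."""
    return sum(r.n_compounds for r in S2R_REFERENCE_SUMMARY)


def assemble_screening_database(actives_ids, decoy_ids) -> list[str]:
    """Combine actives and decoys into one screening database.

    Validates that the two id sets are disjoint and free of internal
    duplicates; returns actives followed by decoys (the benchmark layout:
    191 actives + 12,148 decoys -> 12,339 entries).
    """
    actives = list(actives_ids)
    decoys = list(decoy_ids)
    if len(set(actives)) != len(actives):
        raise ValueError("duplicate ids in actives")
    if len(set(decoys)) != len(decoys):
        raise ValueError("duplicate ids in decoys")
    overlap = set(actives) & set(decoys)
    if overlap:
        raise ValueError(f"actives and decoys overlap: {sorted(overlap)[:5]}")
    return actives + decoys
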