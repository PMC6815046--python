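"""Curated neurodevelopmental-disorder (NDD) seed gene panels.

Seed genes are grouped into three classes by the strength of their
literature evidence for epilepsy association across OMIM, DDG2P,
EpilepsyGene, and published epilepsy gene reviews:

* class 1 - concurrently annotated as epilepsy-associated in all four
  resources (strong evidence);
* class 2 - annotated in only a subset of the resources (moderate);
* class 3 - not annotated as epilepsy-associated in any of them (weak
  or none; these are primarily autism/ID/DD genes).

Panel provenance: high-confidence SFARI genes (scores 1-2), genes
concurrently reported as epilepsy-associated across the databases
above, and a small set of genes moderately associated with epilepsy.
The ``PANEL_*`` totals record how the union of considered seeds was
assembled from those sources.
"""

from __future__ import annotations

CLASS1: tuple[str, ...] = (
    "ARHGEF9", "ALDH7A1", "ALG13", "CACNA1H", "CACNB4", "CDKL5", "CHD2",
    "CHRNB2", "DEPDC5", "DNM1", "EEF1A2", "GABRA1", "GABRB3", "GABRG2",
    "GNAO1", "GRIN2A", "GRIN2B", "HCN1", "KCNB1", "KCNMA1", "KCNQ2",
    "KCNT1", "KCTD7", "LGI1", "PCDH19", "PRRT2", "SCN1A", "SCN1B",
    "SCN2A", "SCN8A", "SLC25A22", "SPTAN1", "STX1B", "STXBP1", "TBC1D24",
)

CLASS2: tuple[str, ...] = (
    "ASH1L", "BCKDK", "CACNA1D", "CNTNAP2", "DIP2C", "DYRK1A", "FLNA",
    "FMR1", "GRIN1", "HNRNPU", "KMT2A", "MBOAT7", "MECP2", "NECAP1",
    "NEDD4L", "PTEN", "RANBP17", "SCN9A", "SLC6A1", "SYNGAP1", "TRIO",
)

CLASS3: tuple[str, ...] = (
    "ADNP", "ANK2", "ANKRD11", "ARID1B", "ASXL3", "BAZ2B", "BCL11A",
    "CHD8", "CIC", "CTNND2", "CUL3", "DDX3X", "DSCAM", "ERBIN", "GIGYF2",
    "GRIA1", "GRIP1", "ILF2", "INTS6", "IRF2BPL", "KDM5B", "KDM6A",
    "KMT2C", "KMT5B", "LEO1", "MED13", "MED13L", "MET", "MYT1L", "NAA15",
    "NCKAP1", "NLGN3", "NRXN1", "PHF3", "POGZ", "RIMS1", "SETD5",
    "SHANK2", "SHANK3", "SMARCC2", "SPAST", "SRCAP", "SRSF11", "TAOK2",
    "TBL1XR1", "TBR1", "TCF20", "TNRC6B", "TRIP12", "UBN2", "UPF3B",
    "USP15", "USP7", "WAC", "WDFY3",
)

ALL_SEEDS: tuple[str, ...] = CLASS1 + CLASS2 + CLASS3

#: Source-panel composition of the full considered seed list.
PANEL_SFARI_HIGH_CONFIDENCE = 84   # SFARI gene score 1 or 2
PANEL_EPILEPSY_CONCURRENT = 41     # concurrently epilepsy-annotated genes
PANEL_OVERLAP = 4                  # epilepsy panel genes also in the SFARI set
PANEL_MODERATE_EPILEPSY = 6        # additional moderately associated genes


def seeds_considered() -> int:
    """Total distinct seed genes assembled from the source panels."""
    return (
        PANEL_SFARI_HIGH_CONFIDENCE
        + PANEL_EPILEPSY_CONCURRENT
        - PANEL_OVERLAP
        + PANEL_MODERATE_EPILEPSY
    )


def class_sizes() -> dict[str, int]:
    return {"class1": len(CLASS1), "class2": len(CLASS2), "class3": len(CLASS3)}
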