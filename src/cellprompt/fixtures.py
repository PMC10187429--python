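"""Synthetic inputs for offline testing and benchmarks.

Everything here is generated or curated in-code: a small dictionary of breast
cell types with mutually disjoint marker lists (disjointness makes the mock
backend's overlap scoring unambiguous), fully synthetic marker sets with
generated symbols, a synthetic gene universe guaranteed not to collide with
any marker, and differential-gene tables whose low ranks are genuine markers
and whose deeper ranks are decoys borrowed from other cell types — the
construction used to probe how annotation quality degrades as more, noisier
genes enter the prompt.
"""

from __future__ import annotations

import numpy as np

from .backends import MockDictionary
from .marker_io import DifferentialGeneRecord, DifferentialGeneTable, MarkerGeneSet

#: Twelve human breast / immune / stromal cell types with ten marker genes
#: each. Curated so that no gene appears under two cell types; real symbols
#: are used for realism, but the lists are a synthetic test dictionary, not a
#: vetted literature resource.
BREAST_CELL_TYPE_MARKERS: dict[str, list[str]] = {
    "T cell": ["CD3D", "CD3E", "CD3G", "CD2", "CD7", "IL7R", "TRAC", "LCK", "CD8A", "CCL5"],
    "B cell": ["CD19", "MS4A1", "CD79A", "CD79B", "IGHM", "IGHD", "PAX5", "BANK1", "TNFRSF13B", "BLNK"],
    "natural killer cell": ["NKG7", "GNLY", "KLRD1", "KLRF1", "NCR1", "PRF1", "GZMB", "FCGR3A", "EOMES", "XCL2"],
    "macrophage": ["CD68", "CD163", "LYZ", "MRC1", "CSF1R", "MSR1", "C1QA", "C1QB", "ITGAM", "MERTK"],
    "dendritic cell": ["FCER1A", "CD1C", "CLEC9A", "CLEC10A", "ITGAX", "LAMP3", "IRF8", "BATF3", "FLT3", "ZBTB46"],
    "mast cell": ["TPSAB1", "TPSB2", "CPA3", "KIT", "MS4A2", "CMA1", "HDC", "GATA2", "SLC18A2", "RGS13"],
    "fibroblast": ["COL1A1", "COL1A2", "COL3A1", "PDGFRA", "LUM", "DCN", "FBLN1", "THY1", "POSTN", "FAP"],
    "endothelial cell": ["PECAM1", "VWF", "CDH5", "CLDN5", "FLT1", "KDR", "TEK", "EGFL7", "RAMP2", "SOX18"],
    "pericyte": ["RGS5", "PDGFRB", "ACTA2", "MYH11", "CSPG4", "NOTCH3", "TAGLN", "MCAM", "KCNJ8", "HIGD1B"],
    "luminal epithelial cell": ["KRT8", "KRT18", "KRT19", "EPCAM", "ELF3", "FOXA1", "GATA3", "AR", "ANKRD30A", "SLPI"],
    "basal epithelial cell": ["KRT5", "KRT14", "KRT17", "TP63", "MYLK", "OXTR", "SNAI2", "EGFR", "DST", "MME"],
    "adipocyte": ["ADIPOQ", "LEP", "PLIN1", "FABP4", "LPL", "CIDEC", "PPARG", "CEBPA", "GPD1", "PDE3B"],
}


def breast_marker_set() -> MarkerGeneSet:
    """The curated 12-type breast marker dictionary as a :class:`MarkerGeneSet`."""
    return MarkerGeneSet(
        entries={name: list(genes) for name, genes in BREAST_CELL_TYPE_MARKERS.items()},
        species="human",
    )


def synthetic_marker_set(
    n_types: int = 12,
    genes_per_type: int = 10,
    seed: int = 0,
    prefix: str = "SYN",
) -> MarkerGeneSet:
    """A fully synthetic marker set with generated, pairwise-disjoint symbols."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_types * genes_per_type)
    entries = {
        f"synthetic type {t + 1}": [
            f"{prefix}{order[t * genes_per_type + g]:04d}" for g in range(genes_per_type)
        ]
        for t in range(n_types)
    }
    return MarkerGeneSet(entries=entries, species="other")


def mock_dictionary_from(markers: MarkerGeneSet, **kwargs) -> MockDictionary:
    """Build the mock backend's dictionary from a marker set."""
    return MockDictionary(
        entries={name: frozenset(genes) for name, genes in markers.entries.items()},
        **kwargs,
    )


def synthetic_gene_universe(
    n: int = 200, seed: int = 0, prefix: str = "RNDG"
) -> list[str]:
    """A synthetic gene universe disjoint (by prefix) from every fixture marker."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [f"{prefix}{i:05d}" for i in order]


def synthetic_differential_table(
    markers: MarkerGeneSet,
    n_decoys: int = 40,
    seed: int = 0,
) -> tuple[DifferentialGeneTable, dict[str, str]]:
    """Differential table whose top ranks are true markers, deeper ranks decoys.

    One cluster per cell type (ids "0", "1", ...). Ranks 1..len(markers) carry
    the type's own markers at steeply increasing p-values; the next
    ``n_decoys`` ranks are genes sampled without replacement from *other*
    types' marker lists. Returns the table and the cluster -> true type map.
    """
    rng = np.random.default_rng(seed)
    names = list(markers.entries)
    records: list[DifferentialGeneRecord] = []
    truth: dict[str, str] = {}
    for ci, name in enumerate(names):
        cluster_id = str(ci)
        truth[cluster_id] = name
        own = markers.entries[name]
        pool = [g for other in names if other != name for g in markers.entries[other]]
        if n_decoys > len(pool):
            raise ValueError(f"cannot draw {n_decoys} decoys from {len(pool)} genes")
        decoys = [pool[j] for j in rng.choice(len(pool), size=n_decoys, replace=False)]
        for rank, gene in enumerate(own + decoys, start=1):
            records.append(
                DifferentialGeneRecord(
                    gene=gene,
                    cluster_id=cluster_id,
                    p_value=rank * 1e-6,
                    effect_size=float(round(3.0 - 0.02 * rank, 4)),
                )
            )
    return DifferentialGeneTable(records=records, source_dialect="generic"), truth
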