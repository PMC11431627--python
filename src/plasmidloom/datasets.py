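"""Packaged reference tables for the published plasmid set.

Two small TSV fixtures ship with the package:

* ``plasmid_summary.tsv`` — per-plasmid country, size (bp), %G+C and
  accession for the twenty published pL6-family plasmids;
* ``core_gene_variants.tsv`` — the published core-gene presence vectors
  and variant labels.  A cell may name the gene carried (``F1``, ``F1b``,
  ``F2b/F2a``...), ``-`` for absent, or carry a ``/ps.`` pseudogene mark.

Mapped-read counts for the fraction experiment on pPOLA-c1 (intracellular,
two dissolved-DNA protocols, virus pellet; 3 million pairs mapped per
fraction) are provided as a constant for ratio recomputation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Mapped-read counts of the published four-fraction experiment (pPOLA-c1).
FRACTION_COUNTS = {"iDNA": 1228, "FdDNA": 3217, "CdDNA": 1982, "vDNA": 39}
FRACTION_REFERENCE = "iDNA"


def _load(name: str) -> pd.DataFrame:
    with resources.files("plasmidloom.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def plasmid_summary_table() -> pd.DataFrame:
    return _load("plasmid_summary.tsv")


def core_gene_variant_table() -> pd.DataFrame:
    return _load("core_gene_variants.tsv")


def presence_labels(row: pd.Series) -> set[str]:
    """Core-gene labels present in one variant-table row.

    Composite cells like ``F2b/F2a`` expand to both labels; ``/ps.`` marks
    a pseudogene, which still counts as presence for classification.
    """
    labels: set[str] = set()
    for col in ("F1", "F2", "F3", "R4", "R5", "R6", "R7"):
        cell = str(row[col]).strip()
        if cell in {"-", "nan", ""}:
            continue
        for token in cell.split("/"):
            token = token.strip()
            if token and token != "ps.":
                labels.add(token)
    return labels
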