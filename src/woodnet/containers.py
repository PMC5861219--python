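"""Core in-memory containers for the wood-formation analysis pipeline.

Two kinds of expression data flow through the pipeline:

* :class:`SectionSeries` — VST-scale expression of genes across a tangential
  cryosection series through the stem of one or more trees, each section
  annotated with its tree of origin, developmental zone (phloem/cambium,
  expanding xylem, secondary-cell-wall formation, cell death) and position
  along the sampling axis.
* :class:`CountExperiment` — raw RNA-Seq read counts for a factorial
  genotype × treatment design (wild type plus two ethylene-insensitive
  etr1-1 transgenic lines, mock vs ACC treatment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Developmental zones of wood formation, in anatomical order from the
#: phloem/cambium outwards-in: phloem/cambium, expanding xylem, secondary
#: cell wall formation, cell death (xylem maturation).
ZONES = ("P/C", "Ex", "SCW", "CD")

#: Genotypes of the ACC-treatment experiment: wild type and the two
#: ethylene-insensitive receptor-mutant lines.
GENOTYPES = ("WT", "etr1_LMX5", "etr1_35S")

#: Treatments: water control vs the ethylene precursor ACC.
TREATMENTS = ("mock", "ACC")


@dataclass
class SectionSeries:
    """Gene × section expression matrix with per-section metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per section id, holding
        finite VST-scale expression values.
    section_meta
        DataFrame indexed by section id with columns ``tree`` (tree id),
        ``zone`` (one of :data:`ZONES`) and ``position`` (integer index
        along the section series, strictly increasing within each tree).
    """

    values: pd.DataFrame
    section_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.section_meta.index):
            raise ValueError("section ids of values and section_meta disagree")
        for col in ("tree", "zone", "position"):
            if col not in self.section_meta.columns:
                raise ValueError(f"section_meta lacks required column {col!r}")
        bad = set(self.section_meta["zone"]) - set(ZONES)
        if bad:
            raise ValueError(f"unknown zone label(s): {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        for tree, sub in self.section_meta.groupby("tree", sort=False):
            pos = sub["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing in tree {tree!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sections(self) -> list[str]:
        return list(self.values.columns)

    @property
    def trees(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.section_meta["tree"]:
            seen.setdefault(t, None)
        return list(seen)

    def subset_genes(self, genes) -> "SectionSeries":
        """Return a new series restricted to ``genes`` (order preserved)."""
        return SectionSeries(self.values.loc[list(genes)], self.section_meta)


@dataclass
class CountExperiment:
    """Gene × library integer count matrix with library metadata.

    ``library_meta`` is indexed by library id with columns ``genotype``
    (one of :data:`GENOTYPES`), ``treatment`` (one of :data:`TREATMENTS`)
    and ``replicate``.  Every genotype × treatment cell must contain at
    least one library.
    """

    counts: pd.DataFrame
    library_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.library_meta.index):
            raise ValueError("library ids of counts and library_meta disagree")
        for col in ("genotype", "treatment", "replicate"):
            if col not in self.library_meta.columns:
                raise ValueError(f"library_meta lacks required column {col!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if set(self.library_meta["genotype"]) - set(GENOTYPES):
            raise ValueError("unknown genotype label")
        if set(self.library_meta["treatment"]) - set(TREATMENTS):
            raise ValueError("unknown treatment label")
        cells = {
            (g, t)
            for g, t in zip(self.library_meta["genotype"], self.library_meta["treatment"])
        }
        missing = {(g, t) for g in GENOTYPES for t in TREATMENTS} - cells
        if missing:
            raise ValueError(f"empty genotype×treatment cell(s): {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountExperiment":
        return CountExperiment(self.counts.loc[list(genes)], self.library_meta)
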