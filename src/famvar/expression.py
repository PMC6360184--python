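"""Relative tissue expression and brain-specificity reporting.

Expression is summarized per species by dividing each tissue's FPKM by the
maximum over the profiled tissues, so the top tissue scores exactly 1 and
all others fall in [0, 1]. Ties at the maximum all map to 1 (normalization
is by value, not rank). The cross-species report flags whether the same
tissue is maximal in every species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FamvarError, GeneLookupError, ValidationError

logger = logging.getLogger(__name__)


class UndefinedNormalizationError(FamvarError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM values for one or more species (long-format frame)."""

    data: pd.DataFrame  # columns: gene, species, tissue, fpkm

    def __post_init__(self) -> None:
        required = {"gene", "species", "tissue", "fpkm"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"missing columns {required - set(self.data.columns)}")
        if (self.data["fpkm"] < 0).any():
            raise ValidationError("negative FPKM values")
        dup = self.data.duplicated(subset=["gene", "species", "tissue"])
        if dup.any():
            raise ValidationError("duplicate (gene, species, tissue) rows")

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def row(self, gene: str, species: str) -> pd.Series:
        sub = self.data[(self.data["gene"] == gene)
                        & (self.data["species"] == species)]
        if sub.empty:
            raise GeneLookupError(f"no expression data for {gene!r} in {species!r}")
        return sub.set_index("tissue")["fpkm"]


def relative_expression(row) -> np.ndarray:
    """Normalize an FPKM vector by its maximum (top tissue -> exactly 1)."""
    values = np.asarray(row, dtype=float)
    if values.size == 0 or np.all(values == 0):
        raise UndefinedNormalizationError("cannot normalize an all-zero FPKM vector")
    if (values < 0).any():
        raise ValidationError("negative FPKM values")
    return values / values.max()


@dataclass
class SpeciesProfile:
    species: str
    max_tissue: str
    relative: dict[str, float]


@dataclass
class SpecificityReport:
    gene: str
    profiles: list[SpeciesProfile]
    cross_species_consistent: bool

    @property
    def max_tissues(self) -> list[str]:
        return [p.max_tissue for p in self.profiles]


def specificity_report(m: ExpressionMatrix, gene: str) -> SpecificityReport:
    """Per-species maximal tissue and normalized profile for one gene.

    ``cross_species_consistent`` is True when the same tissue is maximal in
    every species with data for the gene. The maximal tissue is the first
    (in tissue order) achieving the row maximum; ties still all normalize
    to 1 in the relative vector.
    """
    species = [s for s in m.species
               if not m.data[(m.data["gene"] == gene)
                             & (m.data["species"] == s)].empty]
    if not species:
        raise GeneLookupError(f"gene {gene!r} not present in the matrix")
    profiles = []
    for sp in species:
        row = m.row(gene, sp)
        rel = relative_expression(row.to_numpy())
        profiles.append(SpeciesProfile(
            species=sp,
            max_tissue=str(row.index[int(np.argmax(row.to_numpy()))]),
            relative=dict(zip(row.index, rel.tolist())),
        ))
    consistent = len({p.max_tissue for p in profiles}) == 1
    logger.info("%s maximal tissue per species: %s", gene,
                {p.species: p.max_tissue for p in profiles})
    return SpecificityReport(gene=gene, profiles=profiles,
                             cross_species_consistent=consistent)
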