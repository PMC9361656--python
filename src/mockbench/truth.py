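"""Ground-truth registry for defined mock communities.

Holds the strain inventory of a whole-cell or DNA reference reagent —
per-strain gram stain, genome size, 16S rRNA gene copy number and mixing
weights — and derives the expected taxonomic profile of the community
under different measurement bases:

``cells``
    relative cell counts (flow-cytometry-equalised whole-cell mixes);
``dna_mass``
    cell counts weighted by genome length, the composition shotgun
    sequencing of extracted DNA should recover;
``amplicon_16s``
    cell counts weighted by 16S copy number, the composition 16S amplicon
    sequencing should recover.

The bundled 20-strain gut community (``gut20``) is a synthetic
reconstruction of the canonical gut whole-cell reference reagent: the
strain roster and per-strain genome sizes / copy numbers are
literature-typical values chosen to reproduce the community's published
cardinalities (20 strains, 19 species, 16 genera, 13 families, 5 phyla,
12 gram-positive and 8 gram-negative strains), not certified values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FormatError, ParameterError, ValidationError
from .profiles import RANKS, TaxonProfile, canonicalize_name

BASES = ("cells", "dna_mass", "amplicon_16s")
GRAM_VALUES = ("positive", "negative")

_TSV_COLUMNS = [
    "strain_label", "species_name", "phylum", "family", "genus",
    "dsmz_id", "gram", "genome_size_bp", "copies_16s", "cell_weight",
    "mass_ng",
]


@dataclass(frozen=True)
class StrainRecord:
    """One reference strain and its physical bookkeeping.

    ``cell_weight`` is a dimensionless relative cell count (whole-cell
    reagents); ``mass_ng`` is nanograms of DNA added (DNA-only reagents).
    At least one of the two must be present.
    """

    strain_label: str
    species_name: str
    lineage: dict[str, str]  # rank -> taxon name, phylum..species
    culture_collection_id: str
    gram: str
    genome_size: int
    copies_16s: int
    cell_weight: float | None = None
    mass_ng: float | None = None

    def __post_init__(self) -> None:
        if self.gram not in GRAM_VALUES:
            raise ValidationError(
                f"strain {self.strain_label!r}: gram must be one of "
                f"{GRAM_VALUES}, got {self.gram!r}"
            )
        if self.genome_size <= 0:
            raise ValidationError(
                f"strain {self.strain_label!r}: genome_size must be > 0"
            )
        if self.copies_16s < 1:
            raise ValidationError(
                f"strain {self.strain_label!r}: copies_16s must be >= 1"
            )
        if self.cell_weight is None and self.mass_ng is None:
            raise ValidationError(
                f"strain {self.strain_label!r}: cell_weight and mass_ng "
                "cannot both be absent"
            )
        for name, value in (("cell_weight", self.cell_weight),
                            ("mass_ng", self.mass_ng)):
            if value is not None and value < 0:
                raise ValidationError(
                    f"strain {self.strain_label!r}: {name} must be >= 0"
                )

    def taxon_at(self, rank: str) -> str:
        if rank not in self.lineage or not self.lineage[rank]:
            raise ParameterError(
                f"strain {self.strain_label!r}: lineage has no rank {rank!r}"
            )
        return canonicalize_name(self.lineage[rank])

    def basis_weight(self, basis: str) -> float:
        """Relative weight of this strain under a measurement basis."""
        if basis == "cells":
            if self.cell_weight is None:
                raise ParameterError(
                    f"strain {self.strain_label!r}: basis 'cells' needs "
                    "cell_weight"
                )
            return self.cell_weight
        if basis == "dna_mass":
            if self.cell_weight is not None:
                return self.cell_weight * self.genome_size
            return float(self.mass_ng)  # DNA-only reagent truth
        if basis == "amplicon_16s":
            if self.cell_weight is not None:
                return self.cell_weight * self.copies_16s
            # mass -> cells -> amplicon copies
            return float(self.mass_ng) / self.genome_size * self.copies_16s
        raise ParameterError(f"unknown basis: {basis!r}")


@dataclass
class CommunityTruth:
    """A named reference community: a validated list of strains."""

    name: str
    strains: list[StrainRecord]
    default_basis: str = "cells"

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValidationError(f"community {self.name!r} has no strains")
        if self.default_basis not in BASES:
            raise ParameterError(f"unknown basis: {self.default_basis!r}")
        labels = [s.strain_label for s in self.strains]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(
                f"community {self.name!r}: duplicate strain_label(s) {dupes}"
            )

    def taxa_at(self, rank: str) -> set[str]:
        if rank not in RANKS:
            raise ParameterError(f"unknown taxonomic rank: {rank!r}")
        return {s.taxon_at(rank) for s in self.strains}

    def gram_of(self, rank: str) -> dict[str, str]:
        """Map taxon name at ``rank`` to its gram label.

        Raises if strains with different gram stains collapse into the
        same taxon at that rank (ambiguous grouping).
        """
        mapping: dict[str, str] = {}
        for s in self.strains:
            taxon = s.taxon_at(rank)
            if mapping.setdefault(taxon, s.gram) != s.gram:
                raise ParameterError(
                    f"taxon {taxon!r} at rank {rank!r} mixes gram stains"
                )
        return mapping


def _strain_from_mapping(row: dict) -> StrainRecord:
    def opt_float(key: str) -> float | None:
        value = row.get(key)
        if value is None or value == "" or pd.isna(value):
            return None
        return float(value)

    species = str(row["species_name"])
    lineage = {
        "phylum": str(row["phylum"]),
        "family": str(row["family"]),
        "genus": str(row["genus"]),
        "species": species,
    }
    return StrainRecord(
        strain_label=str(row["strain_label"]),
        species_name=species,
        lineage=lineage,
        culture_collection_id=str(row.get("dsmz_id", "")),
        gram=str(row["gram"]).strip().lower(),
        genome_size=int(row["genome_size_bp"]),
        copies_16s=int(row["copies_16s"]),
        cell_weight=opt_float("cell_weight"),
        mass_ng=opt_float("mass_ng"),
    )


def load_truth(path: str | Path, format: str | None = None) -> CommunityTruth:
    """Load a community truth from TSV or JSON.

    The TSV dialect has one row per strain with the columns
    ``strain_label species_name phylum family genus dsmz_id gram
    genome_size_bp copies_16s cell_weight mass_ng`` (blank cells for
    absent optional values).  The JSON form carries the same keys under
    ``strains`` plus a community ``name`` and optional ``default_basis``.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "json":
        payload = json.loads(path.read_text())
        rows = payload.get("strains")
        if rows is None:
            raise FormatError(f"{path}: JSON truth must have a 'strains' key")
        name = payload.get("name", path.stem)
        basis = payload.get("default_basis", "cells")
    elif format == "tsv":
        table = pd.read_csv(path, sep="\t", dtype={"strain_label": str})
        missing = [c for c in _TSV_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        rows = table.to_dict(orient="records")
        name = path.stem
        basis = "cells"
    else:
        raise ParameterError(f"unknown truth format: {format!r}")
    for required in ("strain_label", "species_name", "phylum", "family",
                     "genus", "gram", "genome_size_bp", "copies_16s"):
        for row in rows:
            if required not in row or row[required] is None:
                raise FormatError(
                    f"{path}: strain row missing key {required!r}"
                )
    strains = [_strain_from_mapping(row) for row in rows]
    return CommunityTruth(name=name, strains=strains, default_basis=basis)


def gut20() -> CommunityTruth:
    """The bundled synthetic 20-strain gut reference community."""
    source = resources.files("mockbench.data") / "gut20_synthetic.tsv"
    with resources.as_file(source) as path:
        truth = load_truth(path, format="tsv")
    truth.name = "gut20_synthetic"
    return truth


def expected_profile(
    truth: CommunityTruth, basis: str | None = None, rank: str = "species"
) -> TaxonProfile:
    """Expected taxonomic profile of a community under a measurement basis.

    Per-strain weights (see :meth:`StrainRecord.basis_weight`) are summed
    within each taxon at ``rank`` and normalised to sum to 1, so strains of
    the same species collapse into one entry.
    """
    basis = basis or truth.default_basis
    if basis not in BASES:
        raise ParameterError(f"unknown basis: {basis!r}")
    if rank not in RANKS:
        raise ParameterError(f"unknown taxonomic rank: {rank!r}")
    entries: dict[str, float] = {}
    for s in truth.strains:
        taxon = s.taxon_at(rank)
        entries[taxon] = entries.get(taxon, 0.0) + s.basis_weight(basis)
    return TaxonProfile.from_entries(
        sample_id=f"{truth.name}:{basis}",
        rank=rank,
        entries=entries,
        source=f"expected_profile({truth.name}, {basis}, {rank})",
    )


def count_taxa(truth: CommunityTruth, rank: str) -> int:
    """Number of distinct taxon names in the community at ``rank``."""
    return len(truth.taxa_at(rank))


def gram_expected(truth: CommunityTruth, basis: str | None = None) -> tuple[float, float]:
    """Fractions of total basis-weight carried by gram-positive/-negative strains."""
    basis = basis or truth.default_basis
    if basis not in BASES:
        raise ParameterError(f"unknown basis: {basis!r}")
    pos = sum(s.basis_weight(basis) for s in truth.strains if s.gram == "positive")
    neg = sum(s.basis_weight(basis) for s in truth.strains if s.gram == "negative")
    total = pos + neg
    if total == 0:
        raise ValidationError("community carries zero total weight")
    return pos / total, neg / total
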