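"""Taxonomic abundance profiles and profiler-output parsing.

A :class:`TaxonProfile` is the canonical in-memory form of one sample's
relative-abundance table at a fixed taxonomic rank.  Parsers are provided
for MetaPhlAn-style merged clade tables and for a generic two-column (or
multi-sample) taxon/abundance TSV; QIIME2 taxa-level exports are consumed
through the generic reader.  Taxon names are canonicalised (lower case,
single spaces, rank prefixes stripped) so that names from different
profilers can be matched against a ground-truth community.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ParameterError, ValidationError

RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: Rank-prefix letters used by MetaPhlAn/Kraken-style lineage strings.
_PREFIX_TO_RANK = {
    "k": "kingdom",
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
    "t": "strain",
}

# Matches "s__", "g__", "D_6__", "k__" etc. at the start of a name.
_RANK_PREFIX_RE = re.compile(r"^(?:[a-zA-Z]__|D_\d+__)")
_BRACKET_RE = re.compile(r"[\[\]()]")
_WS_RE = re.compile(r"\s+")


def canonicalize_name(raw: str) -> str:
    """Return the canonical form of a taxon name.

    Lower-case, underscores become single spaces, leading rank prefixes
    (``s__``, ``g__``, SILVA-style ``D_6__``) are removed, brackets are
    dropped and runs of whitespace collapse.  Idempotent by construction.
    """
    name = raw.strip()
    name = _RANK_PREFIX_RE.sub("", name)
    name = name.replace("_", " ")
    name = _BRACKET_RE.sub("", name)
    name = _WS_RE.sub(" ", name).strip()
    return name.lower()


@dataclass
class TaxonProfile:
    """Relative abundances of taxa at one rank for one sample.

    ``entries`` maps canonical taxon name to a non-negative fraction.
    Profiles are normalised to sum to 1 unless constructed with
    ``normalize=False`` (useful for FPRA-on-raw analyses).
    """

    sample_id: str
    rank: str
    entries: dict[str, float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ParameterError(f"unknown taxonomic rank: {self.rank!r}")
        for name, value in self.entries.items():
            if value < 0:
                raise ValidationError(
                    f"negative abundance {value} for taxon {name!r}"
                )

    @classmethod
    def from_entries(
        cls,
        sample_id: str,
        rank: str,
        entries: Mapping[str, float],
        source: str = "",
        normalize: bool = True,
    ) -> "TaxonProfile":
        """Build a profile, canonicalising names and optionally normalising."""
        merged: dict[str, float] = {}
        for raw, value in entries.items():
            if value < 0:
                raise ValidationError(
                    f"negative abundance {value} for taxon {raw!r}"
                )
            name = canonicalize_name(str(raw))
            if not name or value == 0:
                continue
            merged[name] = merged.get(name, 0.0) + float(value)
        profile = cls(sample_id=sample_id, rank=rank, entries=merged, source=source)
        return profile.normalized() if normalize else profile

    def total(self) -> float:
        return float(sum(self.entries.values()))

    def is_empty(self) -> bool:
        return self.total() == 0.0

    def normalized(self) -> "TaxonProfile":
        """Return a copy whose entries sum to 1 (empty profiles unchanged)."""
        total = self.total()
        if total == 0:
            return TaxonProfile(self.sample_id, self.rank, {}, self.source)
        entries = {k: v / total for k, v in self.entries.items()}
        return TaxonProfile(self.sample_id, self.rank, entries, self.source)

    def abundance(self, name: str) -> float:
        return self.entries.get(canonicalize_name(name), 0.0)


@dataclass
class MatchResult:
    """Outcome of matching a predicted profile against a truth taxon set.

    The three name sets are disjoint; ``true_positives`` and
    ``false_negatives`` together cover the truth set at the profile's rank.
    ``tp_abundance``/``fp_abundance`` partition the full profile mass:
    abundance of entries whose name matches a truth taxon versus the rest,
    independent of the detection threshold (which only gates membership of
    the counting sets).
    """

    true_positives: set[str]
    false_positives: set[str]
    false_negatives: set[str]
    tp_abundance: float
    fp_abundance: float


def match_taxa(
    profile: TaxonProfile,
    truth,
    synonyms: Mapping[str, str] | None = None,
    detection_threshold: float = 0.0,
    rank: str | None = None,
) -> MatchResult:
    """Classify profile entries as true/false positives against a truth.

    A truth taxon is a true positive iff some profile entry (after
    canonicalisation and optional synonym mapping) equals it with abundance
    strictly greater than ``detection_threshold``; entries matching no truth
    taxon and above the threshold are false positives; truth taxa left over
    are false negatives.
    """
    rank = rank or profile.rank
    if rank != profile.rank:
        raise ParameterError(
            f"profile rank {profile.rank!r} does not match requested {rank!r}"
        )
    truth_taxa = truth.taxa_at(rank)
    synmap = {
        canonicalize_name(k): canonicalize_name(v)
        for k, v in (synonyms or {}).items()
    }

    tp: set[str] = set()
    fp: set[str] = set()
    tp_mass = 0.0
    fp_mass = 0.0
    for name, value in profile.entries.items():
        mapped = synmap.get(name, name)
        if mapped in truth_taxa:
            tp_mass += value
            if value > detection_threshold:
                tp.add(mapped)
        else:
            fp_mass += value
            if value > detection_threshold:
                fp.add(name)
    fn = truth_taxa - tp
    return MatchResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        tp_abundance=tp_mass,
        fp_abundance=fp_mass,
    )


# ---------------------------------------------------------------------------
# Parsers and writers


def _rank_of_clade(clade: str) -> str | None:
    """Rank of the terminal element of a pipe-delimited lineage string."""
    last = clade.split("|")[-1]
    m = re.match(r"^([a-zA-Z])__", last)
    if m:
        return _PREFIX_TO_RANK.get(m.group(1).lower())
    m = re.match(r"^D_(\d+)__", last)
    if m:
        # SILVA levels: D_1 phylum ... D_6 species
        silva = {1: "phylum", 2: "class", 3: "order", 4: "family",
                 5: "genus", 6: "species"}
        return silva.get(int(m.group(1)))
    return None


def read_metaphlan(path: str | Path, rank: str = "species") -> TaxonProfile:
    """Read one sample from a MetaPhlAn-style clade-percentage table.

    Keeps only rows whose lineage terminates exactly at ``rank`` (so a
    species row is kept for rank="species" but its strain sub-rows are not),
    strips rank prefixes, divides percentages by 100 and renormalises.
    The abundance is taken from the first numeric column after the clade
    name, which skips MetaPhlAn3's pipe-delimited NCBI_tax_id column.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown taxonomic rank: {rank!r}")
    path = Path(path)
    entries: dict[str, float] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            clade = fields[0]
            if clade.lower() in {"clade_name", "taxon", "taxonomy"}:
                continue
            if _rank_of_clade(clade) != rank:
                continue
            value = None
            for cell in fields[1:]:
                try:
                    value = float(cell)
                    break
                except ValueError:
                    continue
            if value is None:
                raise FormatError(
                    f"{path}:{lineno}: no numeric abundance in line {line!r}"
                )
            name = canonicalize_name(clade.split("|")[-1])
            entries[name] = entries.get(name, 0.0) + value / 100.0
    if not entries:
        warnings.warn(
            f"{path}: no rows at rank {rank!r}; returning an empty profile",
            stacklevel=2,
        )
    return TaxonProfile.from_entries(
        sample_id=path.stem, rank=rank, entries=entries, source=str(path)
    )


def read_generic_tsv(
    path: str | Path, rank: str = "species", normalize: bool = True
) -> list[TaxonProfile]:
    """Read a generic abundance TSV: one taxon column plus sample columns.

    Values on any consistent scale (percent or fraction) are renormalised
    to fractions unless ``normalize`` is False.  An all-zero sample column
    yields an empty profile with a warning.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise FormatError(
            f"{path}: need a taxon column and at least one sample column"
        )
    taxon_col = table.columns[0]
    profiles: list[TaxonProfile] = []
    for col in table.columns[1:]:
        values = pd.to_numeric(table[col], errors="coerce").fillna(0.0)
        if (values < 0).any():
            raise ValidationError(f"{path}: negative abundance in column {col!r}")
        entries = dict(zip(table[taxon_col].astype(str), values))
        if values.sum() == 0:
            warnings.warn(
                f"{path}: column {col!r} is all zeros; empty profile",
                stacklevel=2,
            )
        profiles.append(
            TaxonProfile.from_entries(
                sample_id=str(col),
                rank=rank,
                entries=entries,
                source=str(path),
                normalize=normalize,
            )
        )
    return profiles


def write_generic_tsv(profiles: Iterable[TaxonProfile], path: str | Path) -> None:
    """Write profiles in the generic abundance TSV dialect (taxon + samples)."""
    profiles = list(profiles)
    if not profiles:
        raise ParameterError("no profiles to write")
    taxa = sorted({name for p in profiles for name in p.entries})
    table = pd.DataFrame(
        {p.sample_id: [p.entries.get(t, 0.0) for t in taxa] for p in profiles},
        index=pd.Index(taxa, name="taxon"),
    )
    table.to_csv(path, sep="\t")
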