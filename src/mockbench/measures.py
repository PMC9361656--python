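"""The four-measure reporting system and derived comparisons.

Given a predicted taxonomic profile and a reference-community truth, four
measures summarise how faithfully a pipeline recovered the community:

* **Sensitivity** — percent of reference taxa correctly detected,
  ``100 · |TP| / n_truth``;
* **FPRA** (false-positive relative abundance) — percent of total predicted
  abundance assigned to taxa not in the reference,
  ``100 · A_FP / (A_TP + A_FP)``;
* **Diversity** — total count of observed taxa (true plus false positives)
  above the detection threshold;
* **Similarity** — ``100 · 2·C_ij / (S_i + S_j)`` where ``C_ij`` sums, over
  taxa found in both profiles, the lesser of the two abundances; this is the
  percent complement of Bray-Curtis dissimilarity.

Also provided: gram-stain recovery (the gram-positive/-negative split of the
matched abundance), replicate coefficient of variation, pairwise Bray-Curtis
dissimilarity matrices for beta-diversity exports, and a partition of the
total similarity loss into its bioinformatic and DNA-extraction components
using a paired whole-cell / DNA-only reagent design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from statistics import mean as _mean, stdev as _stdev
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ParameterError
from .profiles import MatchResult, TaxonProfile, match_taxa
from .truth import CommunityTruth, count_taxa, expected_profile


def sensitivity(match: MatchResult, truth_size: int) -> float:
    """Percent of reference taxa detected; stored unrounded.

    The conventional display rounds to an integer percent (16/19 -> 84%);
    use :func:`round` at presentation time.
    """
    if truth_size < 1:
        raise ParameterError("truth_size must be >= 1")
    return 100.0 * len(match.true_positives) / truth_size


def fpra(match: MatchResult) -> float:
    """Percent of predicted abundance carried by false-positive taxa."""
    total = match.tp_abundance + match.fp_abundance
    if total <= 0:
        warnings.warn("empty profile: FPRA defined as 0", stacklevel=2)
        return 0.0
    return 100.0 * match.fp_abundance / total


def diversity(profile: TaxonProfile, detection_threshold: float = 0.0) -> int:
    """Count of observed taxa above the detection threshold."""
    return sum(1 for v in profile.entries.values() if v > detection_threshold)


def similarity(profile_i: TaxonProfile, profile_j: TaxonProfile) -> float:
    """Bray-Curtis similarity between two profiles, as a percent.

    ``100 · 2·Σ_t min(a_it, a_jt) / (S_i + S_j)`` over the taxon union,
    with ``S`` the profile totals.  The formula is computed in full
    generality, so un-normalised profiles are valid; two empty profiles
    score 0 (vacuous agreement does not count).
    """
    if profile_i.rank != profile_j.rank:
        raise ParameterError(
            f"rank mismatch: {profile_i.rank!r} vs {profile_j.rank!r}"
        )
    s_i = profile_i.total()
    s_j = profile_j.total()
    if s_i == 0 and s_j == 0:
        warnings.warn("both profiles empty: similarity defined as 0",
                      stacklevel=2)
        return 0.0
    shared = profile_i.entries.keys() & profile_j.entries.keys()
    c_ij = sum(min(profile_i.entries[t], profile_j.entries[t]) for t in shared)
    return 100.0 * 2.0 * c_ij / (s_i + s_j)


def dissimilarity_matrix(profiles: Sequence[TaxonProfile]) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities (fractions) between profiles.

    Symmetric with a zero diagonal; suitable for export to ordination or
    PERMANOVA tooling.
    """
    if len(profiles) < 2:
        raise ParameterError("need at least 2 profiles")
    ranks = {p.rank for p in profiles}
    if len(ranks) > 1:
        raise ParameterError(f"profiles mix ranks: {sorted(ranks)}")
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    matrix = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - similarity(profiles[i], profiles[j]) / 100.0
            matrix[i][j] = matrix[j][i] = d
    return pd.DataFrame(matrix, index=ids, columns=ids)


def gram_recovery(
    profile: TaxonProfile,
    truth: CommunityTruth,
    synonyms: Mapping[str, str] | None = None,
) -> tuple[float, float]:
    """Percent of matched abundance from gram-positive vs gram-negative taxa.

    False-positive taxa carry no gram label and are excluded; the two
    percents are renormalised over the matched abundance and sum to 100.
    """
    gram_map = truth.gram_of(profile.rank)
    from .profiles import canonicalize_name

    synmap = {
        canonicalize_name(k): canonicalize_name(v)
        for k, v in (synonyms or {}).items()
    }
    pos = neg = 0.0
    for name, value in profile.entries.items():
        label = gram_map.get(synmap.get(name, name))
        if label == "positive":
            pos += value
        elif label == "negative":
            neg += value
    total = pos + neg
    if total == 0:
        warnings.warn("no matched abundance: gram recovery undefined",
                      stacklevel=2)
        return math.nan, math.nan
    return 100.0 * pos / total, 100.0 * neg / total


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation across replicates, as a percent.

    ``100 · sd / mean`` with the sample (n-1) standard deviation.
    """
    if len(values) < 2:
        raise ParameterError("replicate_cv needs at least 2 values")
    mu = _mean(values)
    if mu == 0:
        warnings.warn("mean is 0: CV undefined", stacklevel=2)
        return math.nan
    return 100.0 * _stdev(values) / mu


@dataclass
class BiasPartition:
    """Similarity losses attributable to each pipeline stage, in percent.

    ``total_loss`` is 100 minus the whole-cell profile's similarity to the
    actual composition; ``bioinformatic_loss`` is 100 minus the DNA-reagent
    profile's similarity to the actual (no extraction step, so the loss is
    sequencing + classification); ``extraction_loss`` is 100 minus the
    similarity between the whole-cell and DNA-reagent profiles.
    ``achievable_ceiling`` is that last similarity itself: the best a
    perfect classifier could do given the extraction.  The components are
    bounds from a paired design, not an additive decomposition, so
    ``total_loss`` is reported independently.
    """

    total_loss: float
    bioinformatic_loss: float
    extraction_loss: float
    achievable_ceiling: float


def bias_partition(
    wc_profile: TaxonProfile,
    dna_profile: TaxonProfile,
    actual: TaxonProfile,
) -> BiasPartition:
    """Partition similarity loss between extraction and bioinformatics."""
    sim_wc_actual = similarity(wc_profile, actual)
    sim_dna_actual = similarity(dna_profile, actual)
    sim_wc_dna = similarity(wc_profile, dna_profile)
    return BiasPartition(
        total_loss=100.0 - sim_wc_actual,
        bioinformatic_loss=100.0 - sim_dna_actual,
        extraction_loss=100.0 - sim_wc_dna,
        achievable_ceiling=sim_wc_dna,
    )


@dataclass
class ScoreReport:
    """All measures for one sample profile against one truth."""

    sample_id: str
    sensitivity: float
    fpra: float
    diversity: int
    similarity_to_actual: float
    similarity_to_dna_reference: float | None
    gram_positive_fraction: float
    gram_negative_fraction: float

    @property
    def sensitivity_rounded(self) -> int:
        """Display convention: integer percent."""
        return round(self.sensitivity)

    def to_dict(self) -> dict:
        return asdict(self)


def score_profile(
    profile: TaxonProfile,
    truth: CommunityTruth,
    basis: str | None = None,
    rank: str | None = None,
    dna_profile: TaxonProfile | None = None,
    detection_threshold: float = 0.0,
    synonyms: Mapping[str, str] | None = None,
) -> ScoreReport:
    """Score one predicted profile with the four-measure reporting system.

    The profile is renormalised, matched against the truth taxon set at
    ``rank``, and compared against the expected profile under ``basis``
    (and, when given, against a paired DNA-reagent profile).
    """
    rank = rank or profile.rank
    prof = profile.normalized()
    match = match_taxa(
        prof, truth, synonyms=synonyms,
        detection_threshold=detection_threshold, rank=rank,
    )
    actual = expected_profile(truth, basis=basis, rank=rank)
    gram_pos, gram_neg = gram_recovery(prof, truth, synonyms=synonyms)
    return ScoreReport(
        sample_id=profile.sample_id,
        sensitivity=sensitivity(match, count_taxa(truth, rank)),
        fpra=fpra(match),
        diversity=diversity(prof, detection_threshold),
        similarity_to_actual=similarity(prof, actual),
        similarity_to_dna_reference=(
            similarity(prof, dna_profile.normalized())
            if dna_profile is not None else None
        ),
        gram_positive_fraction=gram_pos,
        gram_negative_fraction=gram_neg,
    )


def replicate_summary(reports: Iterable[ScoreReport]) -> pd.DataFrame:
    """Mean and sd of each measure across replicate score reports."""
    reports = list(reports)
    if not reports:
        raise ParameterError("no reports to summarise")
    table = pd.DataFrame([r.to_dict() for r in reports]).drop(columns="sample_id")
    return table.agg(["mean", "std"]).T.rename(columns={"std": "sd"})
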