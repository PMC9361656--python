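"""Synthetic mock-community profile generator.

Emulates the statistical structure of a whole-cell reference-reagent
benchmarking experiment so every scoring stage has inputs with known
expected values:

1. **Extraction** — each strain's DNA is recovered with a gram-stain-
   dependent efficiency drawn log-normally (gram-positive cell walls are
   harder to lyse), with named hard-to-lyse species optionally dropping
   out entirely;
2. **Classification** — a fixed total mass of false-positive abundance
   (the FPRA regime of real classifiers, a few percent) is injected over
   randomly chosen non-community taxa, true taxa scaled down accordingly;
3. **Replication** — replicate profiles are resampled from a Dirichlet
   centred on the sample profile, emulating between-extraction noise.

Each sub-model can be switched off (unit efficiencies / zero FPRA /
noise-free replicates), in which limit the pipeline reproduces the
community's expected profile exactly.  A single integer seed drives one
master generator; the three stages consume deterministically derived
substreams, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError, ValidationError
from .profiles import TaxonProfile, canonicalize_name
from .truth import CommunityTruth, expected_profile

#: Common gut commensals / contaminants outside the 20-strain community,
#: used as identities for injected false-positive calls.
DEFAULT_FP_POOL = (
    "streptococcus parasanguinis",
    "klebsiella pneumoniae",
    "eggerthella lenta",
    "dorea formicigenerans",
    "parabacteroides distasonis",
    "anaerostipes hadrus",
    "coprococcus comes",
    "dialister invisus",
    "sutterella wadsworthensis",
    "veillonella parvula",
)


@dataclass
class ExtractionModel:
    """Gram-dependent lysis efficiency and hard-to-lyse dropouts."""

    efficiency_mean_positive: float = 1.0
    efficiency_mean_negative: float = 1.0
    efficiency_sd_log: float = 0.0
    dropout_taxa: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.efficiency_mean_positive <= 0 or self.efficiency_mean_negative <= 0:
            raise ValidationError("efficiency means must be > 0")
        if self.efficiency_sd_log < 0:
            raise ValidationError("efficiency_sd_log must be >= 0")
        self.dropout_taxa = frozenset(
            canonicalize_name(t) for t in self.dropout_taxa
        )


@dataclass
class ClassifierModel:
    """False-positive injection at a fixed total relative abundance."""

    target_fpra_percent: float = 0.0
    n_false_taxa: int = 0
    fp_name_pool: tuple[str, ...] = DEFAULT_FP_POOL

    def __post_init__(self) -> None:
        if not (0 <= self.target_fpra_percent < 100):
            raise ValidationError("target_fpra_percent must be in [0, 100)")
        if self.n_false_taxa < 0:
            raise ValidationError("n_false_taxa must be >= 0")
        if self.n_false_taxa == 0 and self.target_fpra_percent != 0:
            raise ValidationError(
                "target_fpra_percent must be 0 when n_false_taxa is 0"
            )
        if self.n_false_taxa > len(self.fp_name_pool):
            raise ParameterError(
                f"fp_name_pool has {len(self.fp_name_pool)} names, "
                f"need {self.n_false_taxa}"
            )
        self.fp_name_pool = tuple(
            canonicalize_name(t) for t in self.fp_name_pool
        )


@dataclass
class ReplicateModel:
    """Replicate count and Dirichlet dispersion (None = noise-free)."""

    n: int = 5
    dirichlet_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("replicate n must be >= 1")
        if (self.dirichlet_concentration is not None
                and self.dirichlet_concentration <= 0):
            raise ParameterError("dirichlet_concentration must be > 0")


@dataclass
class SimulationConfig:
    """Full parameterisation of one simulated benchmarking run."""

    seed: int = 0
    basis: str = "dna_mass"
    extraction: ExtractionModel = field(default_factory=ExtractionModel)
    classifier: ClassifierModel = field(default_factory=ClassifierModel)
    replicates: ReplicateModel = field(default_factory=ReplicateModel)

    def __post_init__(self) -> None:
        if self.basis not in ("dna_mass", "amplicon_16s"):
            raise ParameterError(
                f"simulation basis must be dna_mass or amplicon_16s, "
                f"got {self.basis!r}"
            )

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["extraction"]["dropout_taxa"] = sorted(
            self.extraction.dropout_taxa
        )
        payload["classifier"]["fp_name_pool"] = list(
            self.classifier.fp_name_pool
        )
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "SimulationConfig":
        return cls(
            seed=int(payload.get("seed", 0)),
            basis=payload.get("basis", "dna_mass"),
            extraction=ExtractionModel(**payload.get("extraction", {})),
            classifier=ClassifierModel(
                **{
                    **payload.get("classifier", {}),
                    **(
                        {"fp_name_pool": tuple(payload["classifier"]["fp_name_pool"])}
                        if "fp_name_pool" in payload.get("classifier", {})
                        else {}
                    ),
                }
            ),
            replicates=ReplicateModel(**payload.get("replicates", {})),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        payload = (json.loads(text) if path.suffix.lower() == ".json"
                   else yaml.safe_load(text))
        return cls.from_dict(payload)

    def _streams(self) -> tuple[np.random.Generator, ...]:
        """Three independent substreams derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)


def study_config(seed: int = 0) -> SimulationConfig:
    """Configuration emulating the benchmark's observed regime.

    Whole-cell extraction with the two hard-to-lyse dropouts, a gram-
    positive efficiency deficit, classifier false positives in the
    single-digit-percent FPRA range, and five replicates with mild
    compositional noise.
    """
    return SimulationConfig(
        seed=seed,
        basis="dna_mass",
        extraction=ExtractionModel(
            efficiency_mean_positive=0.6,
            efficiency_mean_negative=1.0,
            efficiency_sd_log=0.2,
            dropout_taxa=frozenset(
                {"clostridium butyricum", "alistipes finegoldii"}
            ),
        ),
        classifier=ClassifierModel(
            target_fpra_percent=6.0,
            n_false_taxa=2,
        ),
        replicates=ReplicateModel(n=5, dirichlet_concentration=500.0),
    )


def simulate_extraction(
    truth: CommunityTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TaxonProfile:
    """Apply gram-dependent extraction efficiencies to a community truth.

    Per strain, efficiency is 0 if its species is a dropout, else drawn
    log-normally with median equal to the gram-class mean efficiency and
    log-sd ``efficiency_sd_log``.  Strain weights (cell count × genome
    size or × 16S copies, per the basis) are scaled by efficiency,
    aggregated to species and normalised.
    """
    if rng is None:
        rng = config._streams()[0]
    ext = config.extraction
    entries: dict[str, float] = {}
    for s in truth.strains:
        species = canonicalize_name(s.species_name)
        if species in ext.dropout_taxa:
            continue
        mu = (ext.efficiency_mean_positive if s.gram == "positive"
              else ext.efficiency_mean_negative)
        if ext.efficiency_sd_log > 0:
            eff = rng.lognormal(mean=math.log(mu), sigma=ext.efficiency_sd_log)
        else:
            eff = mu
        entries[species] = entries.get(species, 0.0) + (
            s.basis_weight(config.basis) * eff
        )
    if not entries or sum(entries.values()) == 0:
        raise ValidationError(
            "all extraction efficiencies are zero: degenerate community"
        )
    return TaxonProfile.from_entries(
        sample_id=f"{truth.name}:extracted",
        rank="species",
        entries=entries,
        source="simulate_extraction",
    )


def simulate_classifier(
    profile: TaxonProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TaxonProfile:
    """Inject false-positive taxa at a fixed total relative abundance.

    The false-positive mass is exactly ``target_fpra_percent/100`` (so
    FPRA assertions on the output are exact); randomness enters only
    through which pool names are used and how the mass splits between
    them (symmetric Dirichlet).
    """
    if rng is None:
        rng = config._streams()[1]
    clf = config.classifier
    if clf.n_false_taxa == 0 or clf.target_fpra_percent == 0:
        return TaxonProfile(
            profile.sample_id, profile.rank, dict(profile.entries),
            source=profile.source,
        )
    pool = [t for t in clf.fp_name_pool if t not in profile.entries]
    if len(pool) < clf.n_false_taxa:
        raise ParameterError(
            "fp_name_pool (after removing taxa already present) is smaller "
            f"than n_false_taxa={clf.n_false_taxa}"
        )
    names = list(rng.choice(pool, size=clf.n_false_taxa, replace=False))
    f = clf.target_fpra_percent / 100.0
    split = (rng.dirichlet(np.ones(clf.n_false_taxa))
             if clf.n_false_taxa > 1 else np.array([1.0]))
    entries = {t: v * (1.0 - f) for t, v in profile.normalized().entries.items()}
    for name, share in zip(names, split):
        entries[name] = f * float(share)
    return TaxonProfile.from_entries(
        sample_id=profile.sample_id,
        rank=profile.rank,
        entries=entries,
        source="simulate_classifier",
    )


def simulate_replicates(
    profile: TaxonProfile,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[TaxonProfile]:
    """Draw replicate profiles around a sample profile.

    Noise-free mode (``dirichlet_concentration`` None) returns ``n``
    copies; otherwise each replicate is a Dirichlet draw with mean equal
    to the input profile and concentration ``dirichlet_concentration``
    (larger = tighter replicates; the per-taxon variance is
    ``p(1-p)/(c+1)``).
    """
    if rng is None:
        rng = config._streams()[2]
    rep = config.replicates
    base = profile.normalized()
    taxa = sorted(base.entries)
    p = np.array([base.entries[t] for t in taxa])
    out: list[TaxonProfile] = []
    for i in range(1, rep.n + 1):
        if rep.dirichlet_concentration is None:
            entries = dict(base.entries)
        else:
            draw = rng.dirichlet(rep.dirichlet_concentration * p)
            entries = {t: float(v) for t, v in zip(taxa, draw) if v > 0}
        out.append(
            TaxonProfile.from_entries(
                sample_id=f"{profile.sample_id}:rep{i}",
                rank=profile.rank,
                entries=entries,
                source="simulate_replicates",
            )
        )
    return out


def simulate_experiment(
    truth: CommunityTruth, config: SimulationConfig
) -> list[TaxonProfile]:
    """Extraction → classifier → replicates, fully seed-deterministic."""
    s_ext, s_clf, s_rep = config._streams()
    extracted = simulate_extraction(truth, config, rng=s_ext)
    called = simulate_classifier(extracted, config, rng=s_clf)
    return simulate_replicates(called, config, rng=s_rep)
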