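"""Domain types shared by every pipeline stage.

The vocabulary follows untargeted LC-MS practice: a *feature observation* is
one detected peak (m/z, retention time, intensity) in one run; a *consensus
feature* is the cross-run merged representation of the same ion after
alignment; lipid identities are carried at sum-composition level (total
carbons : double bonds) with class-specific adduct rules.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import pandas as pd

from .masses import adduct_polarity, canonical_adduct, monoisotopic_mass

POLARITIES = ("positive", "negative")

#: Lipid subclasses annotated by the pipeline.  "other" covers species (e.g.
#: PS or LPC internal standards) that are carried for QC but have no
#: class-specific annotation rule.
SUBCLASSES = ("FFA", "PE", "PG", "PC", "MGDG", "DGDG", "LPG", "other")


class FormatError(ValueError):
    """A delimited input file violates the expected layout."""


class StageError(RuntimeError):
    """A pipeline operation was applied at the wrong processing stage."""


@dataclass(frozen=True, slots=True)
class FeatureObservation:
    """One detected peak in one chromatographic run."""

    sample_id: str
    strain: str
    polarity: str  # 'positive' | 'negative'
    mz: float  # Th
    rt: float  # seconds
    intensity: float  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be non-negative, got {self.rt}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass(slots=True)
class ConsensusFeature:
    """Cross-run merged feature: representative (median) m/z and RT plus
    per-sample intensities (a sample absent from ``intensities`` is missing)."""

    feature_id: str
    polarity: str
    mz: float
    rt: float
    intensities: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class SampleInfo:
    """One biological sample (strain replicate)."""

    sample_id: str
    strain: str
    replicate_index: int  # 1-based

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValueError("replicate_index is 1-based and must be >= 1")


@dataclass(slots=True)
class FeatureMatrix:
    """Aligned feature x sample intensity table.

    ``values`` is a float DataFrame indexed by feature_id with one column per
    sample_id; NaN marks a missing (undetected) cell.
    """

    features: list[ConsensusFeature]
    samples: list[SampleInfo]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"values grid {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative intensities in feature matrix")

    @property
    def feature_map(self) -> dict[str, ConsensusFeature]:
        return {f.feature_id: f for f in self.features}

    def strain_samples(self, strain: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.strain == strain]

    @property
    def strains(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.strain not in seen:
                seen.append(s.strain)
        return seen


@dataclass(frozen=True, slots=True)
class LipidRecord:
    """A lipid library entry at sum-composition level."""

    name: str
    subclass: str
    formula: str | None
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        if not self.monoisotopic_mass > 0:
            raise ValueError("monoisotopic_mass must be positive")
        if self.formula:
            derived = monoisotopic_mass(self.formula)
            if abs(derived - self.monoisotopic_mass) > 1e-4:
                raise ValueError(
                    f"{self.name}: stated mass {self.monoisotopic_mass} disagrees "
                    f"with formula-derived {derived:.5f} by more than 1e-4 Da"
                )


@dataclass(frozen=True, slots=True)
class AdductRule:
    """Required ion forms of a lipid subclass, one per polarity (None = the
    subclass does not ionize usefully in that polarity)."""

    subclass: str
    positive_adduct: str | None
    negative_adduct: str | None

    def __post_init__(self) -> None:
        if self.positive_adduct is None and self.negative_adduct is None:
            raise ValueError(f"{self.subclass}: at least one polarity needs an adduct")
        for adduct, pol in (
            (self.positive_adduct, "positive"),
            (self.negative_adduct, "negative"),
        ):
            if adduct is not None and adduct_polarity(adduct) != pol:
                raise ValueError(f"{adduct} is not a {pol}-mode adduct")

    def adduct_for(self, polarity: str) -> str | None:
        return self.positive_adduct if polarity == "positive" else self.negative_adduct


#: Class-specific ion forms used for annotation and cross-polarity
#: confirmation.  MGDG/DGDG are positive-only (ammonium adduct); LPG is
#: negative-only; the four dual-polarity classes require both forms to coelute.
DEFAULT_ADDUCT_RULES: dict[str, AdductRule] = {
    "FFA": AdductRule("FFA", "[M+NH4]+", "[M-H]-"),
    "PE": AdductRule("PE", "[M+H]+", "[M-H]-"),
    "PG": AdductRule("PG", "[M+NH4]+", "[M-H]-"),
    "PC": AdductRule("PC", "[M+H]+", "[M+FA-H]-"),
    "MGDG": AdductRule("MGDG", "[M+NH4]+", None),
    "DGDG": AdductRule("DGDG", "[M+NH4]+", None),
    "LPG": AdductRule("LPG", None, "[M-H]-"),
}


@dataclass(slots=True)
class PipelineConfig:
    """Tunable parameters of the full pipeline, with field-standard defaults.

    Distances are in ppm (mass) and seconds (retention time); fold-change
    bounds are on the linear intensity scale.
    """

    ppm_tolerance: float = 5.0  # annotation and alignment m/z gate
    rt_tolerance_s: float = 30.0  # cross-polarity coelution gate
    rt_align_tolerance_s: float = 15.0  # alignment RT gate
    presence_threshold: float = 0.8  # fraction of replicates required present
    imputation_factor: float = 0.9  # x per-feature minimum for missing cells
    p_threshold: float = 0.01
    q_threshold: float = 0.05
    fc_upper: float = 1.5
    fc_lower: float = 0.667
    loess_span: float = 0.7
    loess_iterations: int = 3
    random_seed: int = 0
    # documented alternatives for genuinely underdetermined choices
    log_base: float = 2.0  # scale for "scale data": log2 by default
    test_method: str = "pooled"  # 'pooled' regression t or 'welch'
    fc_mode: str = "arithmetic"  # group means: 'arithmetic' or 'geometric'
    impute_before_normalize: bool = True
    composition_confirmed_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.presence_threshold <= 1:
            raise ValueError("presence_threshold must be in (0, 1]")
        if not self.fc_lower < 1 < self.fc_upper:
            raise ValueError("need fc_lower < 1 < fc_upper")
        for name in (
            "ppm_tolerance",
            "rt_tolerance_s",
            "rt_align_tolerance_s",
            "imputation_factor",
            "p_threshold",
            "q_threshold",
            "loess_span",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.test_method not in ("pooled", "welch"):
            raise ValueError("test_method must be 'pooled' or 'welch'")
        if self.fc_mode not in ("arithmetic", "geometric"):
            raise ValueError("fc_mode must be 'arithmetic' or 'geometric'")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_samples(samples: list[SampleInfo]) -> None:
    """Reject duplicate sample ids or duplicate (strain, replicate) pairs."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample list")
    keys = [(s.strain, s.replicate_index) for s in samples]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (strain, replicate_index) in sample list")


def presence_count_required(n_replicates: int, threshold: float) -> int:
    """Minimum detections for 'present in >= threshold of replicates'.

    Uses the ceiling so that 80% of 6 replicates means at least 5 detections.
    """
    return math.ceil(threshold * n_replicates - 1e-9)
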