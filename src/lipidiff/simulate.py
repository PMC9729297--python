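"""Ground-truthed synthetic feature generator.

Emulates an untargeted dual-polarity LC-MS lipidomics experiment on three
bacterial strains with six replicates each: every expressed lipid emits one
peak per adduct required by its subclass, with truncated-Gaussian mass error,
Gaussian retention-time jitter, log-normal intensities, planted between-strain
fold changes, independent feature dropout, spiked internal standards, and a
configurable fraction of "unknown" features with no library counterpart.

Strain lipid-class composition is controlled exactly: each lipid's subclass
is drawn from the pooled class proportions and its per-strain expression is
thinned so that, among lipids expressed in a strain, subclass frequencies are
proportional to that strain's configured proportions (a class with proportion
zero, e.g. glycolipids in an E. coli-like strain, is never expressed there).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import read_feature_table, write_feature_table
from .library import default_library, internal_standards
from .masses import adduct_mz
from .model import (
    DEFAULT_ADDUCT_RULES,
    AdductRule,
    FeatureObservation,
    LipidRecord,
    SampleInfo,
)

#: Default per-strain lipid-class proportions.  The OP50-like strain carries
#: no glycolipids (MGDG/DGDG) and is PE-rich; the two lactobacilli carry
#: glycolipids and lysyl-PG.
DEFAULT_CLASS_PROPORTIONS: dict[str, dict[str, float]] = {
    "OP50": {"FFA": 0.35, "PE": 0.40, "PG": 0.15, "PC": 0.05, "LPG": 0.05},
    "HA-114": {
        "FFA": 0.30, "PE": 0.10, "PG": 0.15, "PC": 0.05,
        "MGDG": 0.15, "DGDG": 0.15, "LPG": 0.10,
    },
    "R0011": {
        "FFA": 0.25, "PE": 0.12, "PG": 0.18, "PC": 0.05,
        "MGDG": 0.15, "DGDG": 0.15, "LPG": 0.10,
    },
}

#: Generic ESI ion forms used for species whose subclass has no rule-table
#: entry (the PS/LPC internal standards).
_GENERIC_ADDUCTS = (("positive", "[M+H]+"), ("negative", "[M-H]-"))

_MIN_ISOMER_RT_GAP_S = 120.0  # isomers of one sum composition elute apart


@dataclass(slots=True)
class SimConfig:
    """Study-design and noise parameters of the simulator."""

    strains: tuple[str, ...] = ("OP50", "HA-114", "R0011")
    replicates: int = 6
    n_lipids: int = 120
    class_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(p) for s, p in DEFAULT_CLASS_PROPORTIONS.items()}
    )
    noise_cv: float = 0.2  # coefficient of variation of intensity
    ppm_noise_sd: float = 1.0  # mass-error scale, ppm (truncated at +/-5)
    rt_jitter_sd: float = 3.0  # seconds
    unknown_feature_rate: float = 0.1  # fraction of n_lipids with no library match
    dropout_prob: float = 0.05  # per-observation missingness when expressed
    left_censor: bool = False  # dropout probability rises as intensity falls
    n_differential: int = 30  # lipids with a planted between-strain effect
    effect_log2_fc: float = math.log2(3.0)  # magnitude of planted effects
    rt_range_s: tuple[float, float] = (60.0, 4900.0)  # usable gradient window
    base_log2_range: tuple[float, float] = (14.0, 20.0)
    spike_standards: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if set(self.class_proportions) != set(self.strains):
            raise ValueError("class_proportions must cover exactly the configured strains")
        for strain, props in self.class_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{strain}: class proportions sum to {total}, not 1")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{strain}: negative class proportion")

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        for key in ("strains", "rt_range_s", "base_log2_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(slots=True)
class GroundTruthLipid:
    """One simulated molecular species with its full generating state."""

    lipid: LipidRecord
    rt_true: float  # seconds
    expressed: dict[str, bool]
    base_log2_intensity: dict[str, float]
    dropout_prob: dict[str, float]
    planted_log2_fc: dict[tuple[str, str], float]
    ions: tuple[tuple[str, str, float], ...]  # (polarity, adduct, theoretical m/z)
    adduct_log2_offset: dict[str, float]
    is_standard: bool = False
    is_unknown: bool = False


def design_samples(cfg: SimConfig) -> list[SampleInfo]:
    """The simulated design: replicates nested in strains, ids 'STRAIN_r<i>'."""
    return [
        SampleInfo(f"{strain}_r{rep}", strain, rep)
        for strain in cfg.strains
        for rep in range(1, cfg.replicates + 1)
    ]


def _ions_for(lipid: LipidRecord, rules: dict[str, AdductRule]) -> tuple[tuple[str, str, float], ...]:
    rule = rules.get(lipid.subclass)
    if rule is None:
        pairs = _GENERIC_ADDUCTS
    else:
        pairs = tuple(
            (pol, adduct)
            for pol, adduct in (
                ("positive", rule.positive_adduct),
                ("negative", rule.negative_adduct),
            )
            if adduct is not None
        )
    return tuple(
        (pol, adduct, adduct_mz(lipid.monoisotopic_mass, adduct)) for pol, adduct in pairs
    )


def generate_ground_truth(
    cfg: SimConfig,
    library: list[LipidRecord] | None = None,
    rules: dict[str, AdductRule] | None = None,
) -> list[GroundTruthLipid]:
    """Draw the molecular ground truth for one simulated experiment.

    Deterministic for a fixed seed.  Returns library lipids first, then
    unknown features, then (if spiked) the internal standards.
    """
    rules = rules or DEFAULT_ADDUCT_RULES
    if library is None:
        library = default_library(include_standards=False)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))

    strains = list(cfg.strains)
    classes = sorted({c for p in cfg.class_proportions.values() for c in p if p[c] > 0})
    pooled = np.array(
        [np.mean([cfg.class_proportions[s].get(c, 0.0) for s in strains]) for c in classes]
    )
    pooled = pooled / pooled.sum()
    # thinning ratio so expressed-lipid class frequencies track each strain's
    # configured proportions exactly (see module docstring)
    ratio = max(
        cfg.class_proportions[s].get(c, 0.0) / pooled[i]
        for s in strains
        for i, c in enumerate(classes)
        if pooled[i] > 0
    )
    expr_prob = {
        s: {
            c: cfg.class_proportions[s].get(c, 0.0) / (ratio * pooled[i])
            for i, c in enumerate(classes)
        }
        for s in strains
    }

    by_class: dict[str, list[LipidRecord]] = {c: [] for c in classes}
    for rec in library:
        if rec.subclass in by_class:
            by_class[rec.subclass].append(rec)
    for c in classes:
        if not by_class[c]:
            raise ValueError(f"library has no species of configured subclass {c!r}")

    unused: dict[str, list[LipidRecord]] = {c: list(by_class[c]) for c in classes}
    rt_used: dict[str, list[float]] = {}
    truth: list[GroundTruthLipid] = []

    for _ in range(cfg.n_lipids):
        # rejection sampling of (class, lipid, expression): a draw expressed
        # nowhere is discarded entirely, which keeps the class distribution
        # among each strain's expressed lipids exactly proportional to that
        # strain's configured proportions
        while True:
            c = classes[rng.choice(len(classes), p=pooled)]
            pool = unused[c] if unused[c] else by_class[c]  # exhausted -> reuse (isomers)
            rec = pool[rng.integers(len(pool))]
            expressed = {s: bool(rng.random() < expr_prob[s][c]) for s in strains}
            if any(expressed.values()):
                break
        if unused[c]:
            unused[c].remove(rec)
        rt = _draw_rt(rng, cfg, rt_used.setdefault(rec.name, []))
        base = float(rng.uniform(*cfg.base_log2_range))
        truth.append(
            GroundTruthLipid(
                lipid=rec,
                rt_true=rt,
                expressed=expressed,
                base_log2_intensity={s: base for s in strains},
                dropout_prob={
                    s: (cfg.dropout_prob if expressed[s] else 1.0) for s in strains
                },
                planted_log2_fc={},
                ions=_ions_for(rec, rules),
                adduct_log2_offset={
                    adduct: float(rng.uniform(-1.0, 0.0)) for _, adduct, _ in _ions_for(rec, rules)
                },
            )
        )

    _plant_effects(rng, cfg, truth, strains)

    truth.extend(_unknown_features(rng, cfg, strains))
    if cfg.spike_standards:
        truth.extend(_spiked_standards(rng, cfg, rules, strains))

    for t in truth:
        pairs = [(a, b) for a in strains for b in strains if a != b]
        t.planted_log2_fc = {
            (a, b): t.base_log2_intensity[a] - t.base_log2_intensity[b]
            for a, b in pairs
            if t.expressed[a] and t.expressed[b]
        }
    return truth


def _draw_rt(rng: np.random.Generator, cfg: SimConfig, used: list[float]) -> float:
    for _ in range(200):
        rt = float(rng.uniform(*cfg.rt_range_s))
        if all(abs(rt - u) >= _MIN_ISOMER_RT_GAP_S for u in used):
            used.append(rt)
            return rt
    raise RuntimeError("could not place an isomer retention time; widen rt_range_s")


def _plant_effects(
    rng: np.random.Generator, cfg: SimConfig, truth: list[GroundTruthLipid], strains: list[str]
) -> None:
    eligible = [i for i, t in enumerate(truth) if sum(t.expressed.values()) >= 2]
    n = min(cfg.n_differential, len(eligible))
    chosen = rng.choice(len(eligible), size=n, replace=False) if n else []
    for j in chosen:
        t = truth[eligible[int(j)]]
        present = [s for s in strains if t.expressed[s]]
        a = present[rng.integers(len(present))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        t.base_log2_intensity[a] += sign * cfg.effect_log2_fc


def _unknown_features(
    rng: np.random.Generator, cfg: SimConfig, strains: list[str]
) -> list[GroundTruthLipid]:
    n_unknown = round(cfg.unknown_feature_rate * cfg.n_lipids)
    if n_unknown == 0:
        return []
    lib_mz = {
        pol: np.sort(np.array([adduct_mz(r.monoisotopic_mass, a) for r in default_library()
                               for p2, a in _all_rule_ions(r) if p2 == pol]))
        for pol in ("positive", "negative")
    }
    out = []
    for i in range(n_unknown):
        pol = "positive" if rng.random() < 0.5 else "negative"
        adduct = "[M+H]+" if pol == "positive" else "[M-H]-"
        while True:
            mz = float(rng.uniform(200.0, 1000.0))
            if _min_ppm_distance(mz, lib_mz[pol]) > 20.0:
                break
        neutral = mz - (1.007276 if pol == "positive" else -1.007276)
        rec = LipidRecord(f"unknown_{i:03d}", "other", None, neutral)
        base = float(rng.uniform(*cfg.base_log2_range))
        out.append(
            GroundTruthLipid(
                lipid=rec,
                rt_true=float(rng.uniform(*cfg.rt_range_s)),
                expressed={s: True for s in strains},
                base_log2_intensity={s: base for s in strains},
                dropout_prob={s: cfg.dropout_prob for s in strains},
                planted_log2_fc={},
                ions=((pol, adduct, mz),),
                adduct_log2_offset={adduct: 0.0},
                is_unknown=True,
            )
        )
    return out


def _all_rule_ions(rec: LipidRecord) -> tuple[tuple[str, str], ...]:
    rule = DEFAULT_ADDUCT_RULES.get(rec.subclass)
    if rule is None:
        return _GENERIC_ADDUCTS
    return tuple(
        (pol, adduct)
        for pol, adduct in (("positive", rule.positive_adduct), ("negative", rule.negative_adduct))
        if adduct is not None
    )


def _min_ppm_distance(mz: float, sorted_mz: np.ndarray) -> float:
    if len(sorted_mz) == 0:
        return math.inf
    i = int(np.searchsorted(sorted_mz, mz))
    best = math.inf
    for j in (i - 1, i):
        if 0 <= j < len(sorted_mz):
            best = min(best, abs(mz - sorted_mz[j]) / sorted_mz[j] * 1e6)
    return best


def _spiked_standards(
    rng: np.random.Generator, cfg: SimConfig, rules: dict[str, AdductRule], strains: list[str]
) -> list[GroundTruthLipid]:
    out = []
    for rec in internal_standards():
        base = float(rng.uniform(16.0, 18.0))
        ions = _ions_for(rec, rules)
        out.append(
            GroundTruthLipid(
                lipid=rec,
                rt_true=float(rng.uniform(*cfg.rt_range_s)),
                expressed={s: True for s in strains},
                base_log2_intensity={s: base for s in strains},
                dropout_prob={s: 0.0 for s in strains},
                planted_log2_fc={},
                ions=ions,
                adduct_log2_offset={adduct: 0.0 for _, adduct, _ in ions},
                is_standard=True,
            )
        )
    return out


def simulate_observations(
    truth: list[GroundTruthLipid], cfg: SimConfig
) -> list[FeatureObservation]:
    """Emit noisy per-sample peaks for every expressed (lipid, adduct) pair.

    Intensities are log-normal on the log2 scale with sd = log2(1 + noise_cv);
    mass errors are Gaussian in ppm, truncated at +/-5 ppm; retention times
    get Gaussian jitter.  Observations are dropped independently with the
    per-strain dropout probability (optionally intensity-dependent when
    ``left_censor`` is set).  Deterministic for a fixed seed.
    """
    if not truth:
        raise ValueError("truth list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples = design_samples(cfg)
    sd_log2 = math.log2(1.0 + cfg.noise_cv) if cfg.noise_cv > 0 else 0.0
    censor_ref = cfg.base_log2_range[0] + 1.0

    observations: list[FeatureObservation] = []
    # outer loop over samples mimics one peak list per chromatographic run
    for s in samples:
        for t in truth:
            for pol, adduct, theo_mz in t.ions:
                # draw the full noise vector every time so the stream is
                # stable under dropout decisions
                u_drop = rng.random()
                z_int = rng.standard_normal()
                z_ppm = rng.standard_normal()
                z_rt = rng.standard_normal()
                if not t.expressed[s.strain]:
                    continue
                offset = t.adduct_log2_offset.get(adduct, 0.0)
                x = t.base_log2_intensity[s.strain] + offset + sd_log2 * z_int
                p_drop = t.dropout_prob[s.strain]
                if cfg.left_censor and p_drop > 0:
                    p_drop = min(1.0, p_drop * 2.0 ** (censor_ref - x))
                if u_drop < p_drop:
                    continue
                eps = float(np.clip(cfg.ppm_noise_sd * z_ppm, -5.0, 5.0))
                mz = theo_mz * (1.0 + eps * 1e-6)
                rt = max(0.0, t.rt_true + cfg.rt_jitter_sd * z_rt)
                observations.append(
                    FeatureObservation(s.sample_id, s.strain, pol, mz, rt, 2.0 ** x)
                )
    return observations


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(
    observations: list[FeatureObservation],
    truth: list[GroundTruthLipid],
    directory: str | Path,
    cfg: SimConfig,
) -> dict[str, Path]:
    """Write observations.csv, truth.tsv and simconfig.yaml into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "observations": directory / "observations.csv",
        "truth": directory / "truth.tsv",
        "config": directory / "simconfig.yaml",
    }
    write_feature_table(observations, paths["observations"])

    strains = list(cfg.strains)
    rows = []
    for t in truth:
        row = {
            "name": t.lipid.name,
            "subclass": t.lipid.subclass,
            "formula": t.lipid.formula or "",
            "monoisotopic_mass": f"{t.lipid.monoisotopic_mass:.6f}",
            "rt_true_s": f"{t.rt_true:.3f}",
            "is_standard": int(t.is_standard),
            "is_unknown": int(t.is_unknown),
            "ions": ";".join(f"{pol}|{adduct}|{mz:.6f}" for pol, adduct, mz in t.ions),
            "planted_log2_fc": ";".join(
                f"{a}/{b}:{v:.6f}" for (a, b), v in sorted(t.planted_log2_fc.items())
            ),
        }
        for s in strains:
            row[f"expressed_{s}"] = int(t.expressed[s])
            row[f"base_log2_{s}"] = f"{t.base_log2_intensity[s]:.6f}"
            row[f"dropout_{s}"] = f"{t.dropout_prob[s]:.4f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)

    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths


def read_fixture(directory: str | Path):
    """Read back a fixture directory -> (observations, truth DataFrame, SimConfig)."""
    directory = Path(directory)
    observations = read_feature_table(directory / "observations.csv")
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", keep_default_na=False)
    with open(directory / "simconfig.yaml", encoding="utf-8") as fh:
        cfg = SimConfig.from_dict(yaml.safe_load(fh))
    return observations, truth, cfg
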