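"""Accurate-mass lipid annotation with cross-polarity confirmation.

Annotation is two-step, mirroring standard untargeted practice without MS/MS:

1. *Mass match*: every consensus feature is compared against the library at
   the class-specific adduct for its polarity; matches within the ppm gate
   become candidates.
2. *Coelution confirmation*: for dual-polarity subclasses (FFA, PE, PG, PC)
   a candidate is confirmed only when a feature of the opposite polarity
   matches the same lipid's required opposite adduct and elutes within the
   RT window; single-polarity subclasses (MGDG/DGDG positive-only, LPG
   negative-only) are confirmed on their single required adduct alone.

Features sharing one confirmed sum composition at different retention times
are chromatographic isomers and receive 'a', 'b', ... suffixes in ascending
RT order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .library import internal_standards
from .masses import adduct_mz, ppm_error
from .model import (
    DEFAULT_ADDUCT_RULES,
    AdductRule,
    ConsensusFeature,
    FeatureMatrix,
    LipidRecord,
    presence_count_required,
)

_ISOMER_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True, slots=True)
class Annotation:
    """A (feature, lipid, adduct) assignment with its confirmation state."""

    feature_id: str
    polarity: str
    mz: float
    rt: float
    lipid: LipidRecord
    adduct: str
    ppm: float
    confirmed: bool = False
    partner_feature_id: str | None = None
    isomer_label: str = ""

    @property
    def display_name(self) -> str:
        if self.isomer_label:
            return f"{self.lipid.name} isomer {self.isomer_label}"
        return self.lipid.name


@dataclass(slots=True)
class CompositionSummary:
    """Per-strain lipid-class census of confirmed, sufficiently present lipids."""

    strain: str
    counts: dict[str, int]
    proportions: dict[str, float]


def match_library(
    features: list[ConsensusFeature],
    library: list[LipidRecord],
    rules: dict[str, AdductRule] | None = None,
    ppm_tol: float = 5.0,
) -> list[Annotation]:
    """Accurate-mass candidates for every feature, ppm-sorted per feature.

    A lipid whose subclass has no adduct for the feature's polarity is
    skipped by design (e.g. MGDG can never match a negative feature).
    """
    rules = rules or DEFAULT_ADDUCT_RULES
    targets: dict[str, list[tuple[float, LipidRecord, str]]] = {"positive": [], "negative": []}
    for rec in library:
        rule = rules.get(rec.subclass)
        if rule is None:
            continue
        for pol in ("positive", "negative"):
            adduct = rule.adduct_for(pol)
            if adduct is not None:
                targets[pol].append((adduct_mz(rec.monoisotopic_mass, adduct), rec, adduct))
    sorted_targets = {
        pol: sorted(entries, key=lambda e: e[0]) for pol, entries in targets.items()
    }
    target_mz = {pol: np.array([e[0] for e in entries]) for pol, entries in sorted_targets.items()}

    annotations: list[Annotation] = []
    for feat in features:
        entries = sorted_targets[feat.polarity]
        if not entries:
            continue
        mz_arr = target_mz[feat.polarity]
        half_window = feat.mz * ppm_tol * 1e-6
        lo = int(np.searchsorted(mz_arr, feat.mz - half_window, side="left"))
        hi = int(np.searchsorted(mz_arr, feat.mz + half_window, side="right"))
        candidates = []
        for theo, rec, adduct in entries[lo:hi]:
            ppm = ppm_error(feat.mz, theo)
            if ppm <= ppm_tol:
                candidates.append(
                    Annotation(
                        feature_id=feat.feature_id,
                        polarity=feat.polarity,
                        mz=feat.mz,
                        rt=feat.rt,
                        lipid=rec,
                        adduct=adduct,
                        ppm=ppm,
                    )
                )
        candidates.sort(key=lambda a: (a.ppm, a.lipid.name))
        annotations.extend(candidates)
    return annotations


def cross_polarity_confirm(
    candidates: list[Annotation],
    rules: dict[str, AdductRule] | None = None,
    rt_tol: float = 30.0,
) -> list[Annotation]:
    """Apply the coelution confirmation rule; returns all candidates with
    ``confirmed`` and ``partner_feature_id`` filled in.

    Confirmation is symmetric: when a negative candidate confirms, the
    matching positive candidate for the same lipid confirms too.
    """
    rules = rules or DEFAULT_ADDUCT_RULES
    by_lipid: dict[str, dict[str, list[int]]] = {}
    out = list(candidates)
    for i, cand in enumerate(out):
        by_lipid.setdefault(cand.lipid.name, {"positive": [], "negative": []})[
            cand.polarity
        ].append(i)

    for name, sides in by_lipid.items():
        first = out[(sides["positive"] or sides["negative"])[0]]
        rule = rules[first.lipid.subclass]
        dual = rule.positive_adduct is not None and rule.negative_adduct is not None
        if not dual:
            # single-polarity subclass: the mass match at the required adduct
            # is itself the confirmation
            for i in sides["positive"] + sides["negative"]:
                out[i] = replace(out[i], confirmed=True)
            continue
        for this_pol, other_pol in (("positive", "negative"), ("negative", "positive")):
            for i in sides[this_pol]:
                partners = [
                    j for j in sides[other_pol] if abs(out[i].rt - out[j].rt) < rt_tol
                ]
                if not partners:
                    continue
                j = min(partners, key=lambda j: abs(out[i].rt - out[j].rt))
                out[i] = replace(
                    out[i], confirmed=True, partner_feature_id=out[j].feature_id
                )
    return out


def label_isomers(confirmed: list[Annotation]) -> list[Annotation]:
    """Suffix multiple confirmed features of one lipid (within a polarity)
    with 'a', 'b', ... in ascending RT; ties break by m/z then feature id."""
    groups: dict[tuple[str, str], list[int]] = {}
    out = list(confirmed)
    for i, ann in enumerate(out):
        if not ann.confirmed:
            raise ValueError("label_isomers expects confirmed annotations only")
        groups.setdefault((ann.lipid.name, ann.polarity), []).append(i)
    for (_, _), idxs in groups.items():
        distinct = {out[i].feature_id for i in idxs}
        if len(distinct) < 2:
            continue
        ordered_features = sorted(
            distinct,
            key=lambda fid: min(
                (out[i].rt, out[i].mz, out[i].feature_id) for i in idxs if out[i].feature_id == fid
            ),
        )
        letters = {fid: _ISOMER_LETTERS[k] for k, fid in enumerate(ordered_features)}
        for i in idxs:
            out[i] = replace(out[i], isomer_label=letters[out[i].feature_id])
    return out


def strain_composition(
    matrix: FeatureMatrix,
    confirmed: list[Annotation],
    presence_threshold: float = 0.8,
) -> dict[str, CompositionSummary]:
    """Lipid-class census per strain.

    A confirmed lipid entity — one (lipid name, isomer label), pooling its
    positive and negative features — counts for a strain when at least one of
    its features is observed (pre-imputation, non-missing) in at least
    ceil(threshold x replicates) of that strain's samples.  Proportions
    normalize the per-subclass counts to 1.
    """
    entities: dict[tuple[str, str], dict] = {}
    for ann in confirmed:
        if not ann.confirmed:
            continue
        key = (ann.lipid.name, ann.isomer_label)
        ent = entities.setdefault(key, {"subclass": ann.lipid.subclass, "features": set()})
        ent["features"].add(ann.feature_id)

    values = matrix.values
    summaries: dict[str, CompositionSummary] = {}
    for strain in matrix.strains:
        cols = matrix.strain_samples(strain)
        need = presence_count_required(len(cols), presence_threshold)
        counts: dict[str, int] = {}
        for (_, _), ent in entities.items():
            present = any(
                fid in values.index and int(values.loc[fid, cols].notna().sum()) >= need
                for fid in ent["features"]
            )
            if present:
                counts[ent["subclass"]] = counts.get(ent["subclass"], 0) + 1
        total = sum(counts.values())
        if total == 0:
            warnings.warn(
                f"{strain}: no confirmed lipid passes the presence threshold",
                RuntimeWarning,
                stacklevel=2,
            )
            proportions = {}
        else:
            proportions = {c: n / total for c, n in sorted(counts.items())}
        summaries[strain] = CompositionSummary(strain, dict(sorted(counts.items())), proportions)
    return summaries


def qc_internal_standards(
    features_pos: list[ConsensusFeature],
    features_neg: list[ConsensusFeature],
    rules: dict[str, AdductRule] | None = None,
    ppm_tol: float = 5.0,
) -> list[dict]:
    """Detection check for the six spiked standards (never used to normalize).

    Standards of rule-covered subclasses are searched at their class adduct;
    PS/LPC standards at generic [M+H]+ / [M-H]-.  Returns one record per
    (standard, polarity) probe with the best match and its ppm error.
    """
    rules = rules or DEFAULT_ADDUCT_RULES
    pools = {"positive": features_pos, "negative": features_neg}
    records = []
    for std in internal_standards():
        rule = rules.get(std.subclass)
        if rule is not None:
            probes = [
                (pol, rule.adduct_for(pol))
                for pol in ("positive", "negative")
                if rule.adduct_for(pol) is not None
            ]
        else:
            probes = [("positive", "[M+H]+"), ("negative", "[M-H]-")]
        for pol, adduct in probes:
            theo = adduct_mz(std.monoisotopic_mass, adduct)
            best = None
            for feat in pools[pol]:
                ppm = ppm_error(feat.mz, theo)
                if ppm <= ppm_tol and (best is None or ppm < best[1]):
                    best = (feat.feature_id, ppm)
            records.append(
                {
                    "standard": std.name,
                    "polarity": pol,
                    "adduct": adduct,
                    "detected": best is not None,
                    "feature_id": best[0] if best else "",
                    "ppm": round(best[1], 3) if best else None,
                }
            )
    return records
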