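"""End-to-end orchestration: read -> align -> pairwise preprocess ->
differential statistics -> annotation -> composition -> run report.

The comparison order follows the convention that the first-listed strain is
the reference (fold-change denominator) for the other two, and among the
non-reference strains the earlier-listed one is the numerator: with strains
(A, B, C) the comparisons are B vs A, C vs A, B vs C.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AlignmentParams, align_runs, build_matrix, write_matrix
from .annotate import (
    cross_polarity_confirm,
    label_isomers,
    match_library,
    qc_internal_standards,
    strain_composition,
)
from .io import read_feature_table, write_config
from .library import default_library
from .model import FeatureObservation, FeatureMatrix, PipelineConfig, SampleInfo
from .preprocess import (
    build_pairwise,
    cyclic_loess_normalize,
    filter_presence,
    filter_total_missing,
    impute_missing,
    write_exclusives,
    write_stage,
)
from .stats import (
    classify,
    estimate_pi0,
    feature_pvalues,
    fold_changes,
    storey_qvalues,
    volcano_export,
)

log = logging.getLogger("lipidiff")


@dataclass(slots=True)
class ComparisonReport:
    strain_a: str
    strain_b: str
    n_raw: int
    n_after_total_missing_filter: int
    n_after_presence_filter: int
    n_exclusives: int
    n_significant: int
    n_up: int
    n_down: int
    pi0: float


@dataclass(slots=True)
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    n_samples: int
    n_observations: dict[str, int]
    n_consensus: dict[str, int]
    comparisons: list[ComparisonReport]
    n_annotation_candidates: int
    n_confirmed_annotations: int
    n_confirmed_entities: int
    confirmed_by_subclass: dict[str, int]
    composition: dict[str, dict[str, float]]
    composition_counts: dict[str, dict[str, int]]
    internal_standard_qc: list[dict]
    timestamp: float = field(default_factory=time.time)

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def infer_samples(observations: list[FeatureObservation]) -> list[SampleInfo]:
    """Derive the sample sheet from the observations, preserving first-seen
    order of strains and samples; replicate indices follow within-strain order."""
    seen: dict[str, str] = {}
    for o in observations:
        if o.sample_id not in seen:
            seen[o.sample_id] = o.strain
        elif seen[o.sample_id] != o.strain:
            raise ValueError(f"sample {o.sample_id!r} appears under two strains")
    counters: dict[str, int] = {}
    samples = []
    for sid, strain in seen.items():
        counters[strain] = counters.get(strain, 0) + 1
        samples.append(SampleInfo(sid, strain, counters[strain]))
    return samples


def default_comparisons(strains: list[str]) -> list[tuple[str, str]]:
    pairs = []
    for i in range(len(strains)):
        for j in range(i + 1, len(strains)):
            if i == 0:
                pairs.append((strains[j], strains[i]))
            else:
                pairs.append((strains[i], strains[j]))
    return pairs


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    comparisons: list[tuple[str, str]] | None = None,
    library=None,
) -> RunReport:
    """Execute the full pipeline on a fixture/input directory.

    Expects ``observations.csv`` (the canonical feature-table dialect) in
    ``input_dir``; writes all intermediate artifacts plus ``report.json`` to
    ``output_dir``.  Deterministic for identical inputs and config.
    """
    cfg = config or PipelineConfig()
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    observations = read_feature_table(input_dir / "observations.csv")
    samples = infer_samples(observations)
    strains = []
    for s in samples:
        if s.strain not in strains:
            strains.append(s.strain)
    log.info("read %d observations, %d samples, strains %s",
             len(observations), len(samples), strains)

    by_pol = {"positive": [], "negative": []}
    for o in observations:
        by_pol[o.polarity].append(o)
    params = AlignmentParams(cfg.ppm_tolerance, cfg.rt_align_tolerance_s)
    consensus = {pol: align_runs(obs, params) for pol, obs in by_pol.items()}
    matrix = build_matrix(consensus["positive"], consensus["negative"], samples)
    write_matrix(matrix, output_dir / "feature_matrix.csv")
    log.info("aligned: %d positive / %d negative consensus features (%.1fs)",
             len(consensus["positive"]), len(consensus["negative"]),
             time.perf_counter() - t0)

    lib = library if library is not None else default_library()
    candidates = match_library(matrix.features, lib, ppm_tol=cfg.ppm_tolerance)
    confirmed_all = cross_polarity_confirm(candidates, rt_tol=cfg.rt_tolerance_s)
    confirmed = [a for a in confirmed_all if a.confirmed]
    confirmed = label_isomers(confirmed)
    _write_annotations(confirmed_all, confirmed, output_dir / "annotations.csv")
    annotation_names = _best_annotation_names(confirmed)

    comparisons = comparisons or default_comparisons(strains)
    comp_reports = []
    for strain_a, strain_b in comparisons:
        comp = f"{strain_a}_vs_{strain_b}"
        ds = build_pairwise(matrix, strain_a, strain_b)
        n_raw = len(ds.matrix.features)
        ds = filter_total_missing(ds)
        n_total_filtered = len(ds.matrix.features)
        ds = filter_presence(ds, cfg.presence_threshold)
        n_presence = len(ds.matrix.features)
        ds = impute_missing(ds, cfg.imputation_factor)
        ds = cyclic_loess_normalize(ds, cfg.loess_span, cfg.loess_iterations, cfg.log_base)
        write_stage(ds, output_dir / f"{comp}_normalized.csv")
        write_exclusives(ds, output_dir / f"{comp}_exclusives.csv")

        pvals = feature_pvalues(ds, cfg.test_method)
        pi0 = estimate_pi0(np.array(list(pvals.values())))
        qvals = storey_qvalues(pvals, pi0=pi0)
        fcs = fold_changes(ds, cfg.fc_mode)
        results = classify(ds, pvals, qvals, fcs, cfg)
        volcano_export(
            results,
            output_dir / f"{comp}_volcano.csv",
            feature_map=matrix.feature_map,
            annotations=annotation_names,
        )
        n_sig = sum(r.significant for r in results)
        comp_reports.append(
            ComparisonReport(
                strain_a=strain_a,
                strain_b=strain_b,
                n_raw=n_raw,
                n_after_total_missing_filter=n_total_filtered,
                n_after_presence_filter=n_presence,
                n_exclusives=len(ds.exclusives),
                n_significant=n_sig,
                n_up=sum(r.significant and r.direction == "up" for r in results),
                n_down=sum(r.significant and r.direction == "down" for r in results),
                pi0=round(float(pi0), 6),
            )
        )
        log.info("%s: %d tested, %d significant (%.1fs)",
                 comp, n_presence, n_sig, time.perf_counter() - t0)

    summaries = strain_composition(matrix, confirmed, cfg.presence_threshold)
    _write_composition(summaries, output_dir / "composition.csv")
    qc = qc_internal_standards(
        consensus["positive"], consensus["negative"], ppm_tol=cfg.ppm_tolerance
    )

    entities = {(a.lipid.name, a.isomer_label) for a in confirmed}
    by_subclass: dict[str, int] = {}
    for name, label in entities:
        sub = next(a.lipid.subclass for a in confirmed if (a.lipid.name, a.isomer_label) == (name, label))
        by_subclass[sub] = by_subclass.get(sub, 0) + 1

    report = RunReport(
        config=cfg.to_dict(),
        n_samples=len(samples),
        n_observations={pol: len(obs) for pol, obs in by_pol.items()},
        n_consensus={pol: len(feats) for pol, feats in consensus.items()},
        comparisons=comp_reports,
        n_annotation_candidates=len(candidates),
        n_confirmed_annotations=len(confirmed),
        n_confirmed_entities=len(entities),
        confirmed_by_subclass=dict(sorted(by_subclass.items())),
        composition={s: summ.proportions for s, summ in summaries.items()},
        composition_counts={s: summ.counts for s, summ in summaries.items()},
        internal_standard_qc=qc,
    )
    report.write(output_dir / "report.json")
    write_config(cfg, output_dir / "config_used.yaml")
    log.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    return report


def _best_annotation_names(confirmed) -> dict[str, str]:
    best: dict[str, tuple[float, str]] = {}
    for a in confirmed:
        if a.feature_id not in best or a.ppm < best[a.feature_id][0]:
            best[a.feature_id] = (a.ppm, a.display_name)
    return {fid: name for fid, (_, name) in best.items()}


def _write_annotations(all_candidates, confirmed, path) -> None:
    label = {(a.feature_id, a.lipid.name): a.isomer_label for a in confirmed}
    rows = [
        {
            "feature_id": a.feature_id,
            "polarity": a.polarity,
            "mz": f"{a.mz:.6f}",
            "rt_seconds": f"{a.rt:.3f}",
            "lipid": a.lipid.name,
            "subclass": a.lipid.subclass,
            "adduct": a.adduct,
            "ppm": f"{a.ppm:.3f}",
            "confirmed": int(a.confirmed),
            "partner": a.partner_feature_id or "",
            "isomer_label": label.get((a.feature_id, a.lipid.name), ""),
        }
        for a in all_candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "feature_id", "polarity", "mz", "rt_seconds", "lipid", "subclass",
            "adduct", "ppm", "confirmed", "partner", "isomer_label",
        ],
    ).to_csv(path, index=False)


def _write_composition(summaries, path) -> None:
    rows = []
    for strain, summ in summaries.items():
        for subclass, count in summ.counts.items():
            rows.append(
                {
                    "strain": strain,
                    "subclass": subclass,
                    "count": count,
                    "proportion": f"{summ.proportions[subclass]:.4f}",
                }
            )
    pd.DataFrame(rows, columns=["strain", "subclass", "count", "proportion"]).to_csv(
        path, index=False
    )
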