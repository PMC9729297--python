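"""Strain-pair preprocessing: missingness filters, imputation, normalization.

The three-strain matrix is first split into pairwise datasets; each pair is
then processed in a fixed order:

1. remove features entirely missing in one strain (kept aside as
   *exclusives* for qualitative presence/absence reporting),
2. keep only features detected in at least 80% of the replicates of at least
   one strain,
3. impute remaining missing cells with 90% of the feature's minimum observed
   intensity (a left-censoring assumption: what was not detected was below
   the feature's detection level),
4. cyclic loess normalization on log2 intensities.

Each step advances an explicit ``stage`` tag so out-of-order application is
an error rather than a silent bug.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import (
    FeatureMatrix,
    PipelineConfig,
    StageError,
    presence_count_required,
)

STAGES = ("raw", "filtered", "imputed", "normalized")


@dataclass(slots=True)
class PairwiseDataset:
    """A two-strain slice of the feature matrix with its processing state.

    ``strain_a`` is the first-named member of the comparison and the
    fold-change numerator.  ``exclusives`` holds features removed by the
    100%-missing rule, with per-strain presence counts.
    """

    strain_a: str
    strain_b: str
    matrix: FeatureMatrix
    stage: str = "raw"
    exclusives: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["feature_id", "present_in", "n_present", "n_samples"]
        )
    )

    @property
    def comparison(self) -> str:
        return f"{self.strain_a}_vs_{self.strain_b}"

    def strain_columns(self, strain: str) -> list[str]:
        return self.matrix.strain_samples(strain)


def build_pairwise(matrix: FeatureMatrix, strain_a: str, strain_b: str) -> PairwiseDataset:
    """Restrict the matrix to two strains; all features retained, stage='raw'."""
    strains = set(matrix.strains)
    for s in (strain_a, strain_b):
        if s not in strains:
            raise ValueError(f"strain {s!r} not present in matrix (has {sorted(strains)})")
    samples = [s for s in matrix.samples if s.strain in (strain_a, strain_b)]
    cols = [s.sample_id for s in samples]
    sub = FeatureMatrix(
        features=list(matrix.features),
        samples=samples,
        values=matrix.values[cols].copy(),
    )
    return PairwiseDataset(strain_a=strain_a, strain_b=strain_b, matrix=sub)


def _require_stage(ds: PairwiseDataset, expected: str, op: str) -> None:
    if ds.stage != expected:
        raise StageError(f"{op} requires stage {expected!r}, dataset is at {ds.stage!r}")


def _presence(ds: PairwiseDataset) -> tuple[pd.Series, pd.Series, int, int]:
    cols_a = ds.strain_columns(ds.strain_a)
    cols_b = ds.strain_columns(ds.strain_b)
    obs_a = ds.matrix.values[cols_a].notna().sum(axis=1)
    obs_b = ds.matrix.values[cols_b].notna().sum(axis=1)
    return obs_a, obs_b, len(cols_a), len(cols_b)


def _subset(matrix: FeatureMatrix, keep: pd.Series) -> FeatureMatrix:
    kept_ids = set(keep[keep].index)
    features = [f for f in matrix.features if f.feature_id in kept_ids]
    return FeatureMatrix(
        features=features,
        samples=list(matrix.samples),
        values=matrix.values.loc[[f.feature_id for f in features]],
    )


def filter_total_missing(ds: PairwiseDataset) -> PairwiseDataset:
    """Move features with zero detections in either strain to ``exclusives``.

    A feature seen only in strain A is qualitative evidence of an A-only
    lipid; it is reported but never tested statistically.
    """
    _require_stage(ds, "raw", "filter_total_missing")
    obs_a, obs_b, n_a, n_b = _presence(ds)
    keep = (obs_a > 0) & (obs_b > 0)
    dropped = ~keep
    excl_rows = []
    for fid in ds.matrix.values.index[dropped]:
        a, b = int(obs_a[fid]), int(obs_b[fid])
        present_in = ds.strain_a if a > 0 else (ds.strain_b if b > 0 else "none")
        excl_rows.append(
            {
                "feature_id": fid,
                "present_in": present_in,
                "n_present": max(a, b),
                "n_samples": n_a if present_in == ds.strain_a else n_b,
            }
        )
    exclusives = pd.DataFrame(
        excl_rows, columns=["feature_id", "present_in", "n_present", "n_samples"]
    )
    return replace(ds, matrix=_subset(ds.matrix, keep), stage="raw", exclusives=exclusives)


def filter_presence(ds: PairwiseDataset, threshold: float = 0.8) -> PairwiseDataset:
    """Keep features detected in >= ceil(threshold * n) replicates of at
    least one strain (with n = 6 and threshold 0.8 this means >= 5)."""
    _require_stage(ds, "raw", "filter_presence")
    obs_a, obs_b, n_a, n_b = _presence(ds)
    need_a = presence_count_required(n_a, threshold)
    need_b = presence_count_required(n_b, threshold)
    keep = (obs_a >= need_a) | (obs_b >= need_b)
    return replace(ds, matrix=_subset(ds.matrix, keep), stage="filtered")


def impute_missing(ds: PairwiseDataset, factor: float = 0.9) -> PairwiseDataset:
    """Replace each missing cell with ``factor`` x the feature's minimum
    observed intensity within this pairwise dataset."""
    _require_stage(ds, "filtered", "impute_missing")
    values = ds.matrix.values.copy()
    row_min = values.min(axis=1, skipna=True)
    if row_min.isna().any():
        bad = list(values.index[row_min.isna()])
        raise RuntimeError(
            f"features with zero observed values reached imputation: {bad[:5]}"
        )
    fill = pd.DataFrame(
        np.broadcast_to((factor * row_min).to_numpy()[:, None], values.shape),
        index=values.index,
        columns=values.columns,
    )
    imputed = values.where(values.notna(), fill)
    matrix = FeatureMatrix(
        features=list(ds.matrix.features), samples=list(ds.matrix.samples), values=imputed
    )
    return replace(ds, matrix=matrix, stage="imputed")


def cyclic_loess_normalize(
    ds: PairwiseDataset,
    span: float = 0.7,
    iterations: int = 3,
    log_base: float = 2.0,
) -> PairwiseDataset:
    """Cyclic loess normalization of all sample pairs on the log scale.

    For every ordered sample pair (j, k) the log-ratio M = x_j - x_k is
    regressed on the average log-intensity A = (x_j + x_k)/2 with a local
    linear (tri-cube weighted) smoother at the given span; half the fitted
    trend is subtracted from sample j and added to sample k.  A full pass
    over all pairs is repeated ``iterations`` times, then intensities are
    returned to the linear scale.  The grand mean of the log intensities is
    conserved exactly (the pairwise corrections cancel).
    """
    _require_stage(ds, "imputed", "cyclic_loess_normalize")
    values = ds.matrix.values
    arr = values.to_numpy(copy=True)
    if not (arr > 0).all():
        raise ValueError("cyclic loess requires strictly positive intensities")
    log = np.log(arr) / np.log(log_base)
    n_samples = log.shape[1]
    for _ in range(iterations):
        for j in range(n_samples):
            for k in range(j + 1, n_samples):
                m = log[:, j] - log[:, k]
                a = 0.5 * (log[:, j] + log[:, k])
                fitted = lowess(
                    m, a, frac=span, it=0, return_sorted=False, is_sorted=False
                )
                log[:, j] -= fitted / 2.0
                log[:, k] += fitted / 2.0
    normalized = pd.DataFrame(
        np.power(log_base, log), index=values.index, columns=values.columns
    )
    matrix = FeatureMatrix(
        features=list(ds.matrix.features), samples=list(ds.matrix.samples), values=normalized
    )
    return replace(ds, matrix=matrix, stage="normalized")


def preprocess_pair(
    matrix: FeatureMatrix, strain_a: str, strain_b: str, cfg: PipelineConfig
) -> PairwiseDataset:
    """Run the full filter -> impute -> normalize chain for one strain pair."""
    ds = build_pairwise(matrix, strain_a, strain_b)
    ds = filter_total_missing(ds)
    ds = filter_presence(ds, cfg.presence_threshold)
    ds = impute_missing(ds, cfg.imputation_factor)
    ds = cyclic_loess_normalize(ds, cfg.loess_span, cfg.loess_iterations, cfg.log_base)
    return ds


def write_stage(ds: PairwiseDataset, path) -> None:
    """Write the current stage's matrix with a stage tag column."""
    out = ds.matrix.values.copy()
    out.insert(0, "stage", ds.stage)
    out.to_csv(path, index_label="feature_id", float_format="%.6f")


def write_exclusives(ds: PairwiseDataset, path) -> None:
    ds.exclusives.to_csv(path, index=False)
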