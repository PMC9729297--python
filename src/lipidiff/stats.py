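"""Per-feature differential statistics, Storey FDR, and volcano classification.

Each feature's log2 normalized intensity is regressed on a two-level group
indicator; with two groups the coefficient test is the pooled-variance
two-sample t-test, which is what the closed form below computes (a Welch
variant is available).  Multiple testing is handled with Storey q-values:
the null proportion pi0 is estimated on a lambda grid, smoothed with a cubic
spline and read off at the last grid point, and q-values are the pi0-scaled
step-up adjusted p-values.  A feature is called significant when p is below
the p threshold AND the linear fold change is outside [fc_lower, fc_upper],
both strict; q-values are reported alongside but are not the primary gate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import t as t_dist

from .model import PipelineConfig
from .preprocess import PairwiseDataset


@dataclass(frozen=True, slots=True)
class DifferentialResult:
    """Fold change, p, q and volcano class of one feature in one comparison."""

    feature_id: str
    fc: float  # strain_a mean / strain_b mean, linear scale
    log2_fc: float
    p: float
    q: float
    significant: bool
    direction: str  # 'up' | 'down' | 'none'


def _group_arrays(ds: PairwiseDataset, log_base: float = 2.0) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    if ds.stage != "normalized":
        raise RuntimeError(f"statistics require a normalized dataset, got stage {ds.stage!r}")
    cols_a = ds.strain_columns(ds.strain_a)
    cols_b = ds.strain_columns(ds.strain_b)
    va = ds.matrix.values[cols_a].to_numpy()
    vb = ds.matrix.values[cols_b].to_numpy()
    return np.log(va) / np.log(log_base), np.log(vb) / np.log(log_base), ds.matrix.values.index


def feature_pvalues(ds: PairwiseDataset, method: str = "pooled") -> dict[str, float]:
    """Two-sided p-value of the group coefficient for every feature.

    'pooled' is the equal-variance linear-model t-test; 'welch' uses
    Satterthwaite degrees of freedom.  Features with zero residual variance
    get p = 1 when the group means are equal, else a degenerate-variance
    warning and p = 0.
    """
    xa, xb, index = _group_arrays(ds)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least two replicates per strain")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    diff = ma - mb

    if method == "pooled":
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = np.full_like(se, na + nb - 2.0)
    elif method == "welch":
        se = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
    else:
        raise ValueError("method must be 'pooled' or 'welch'")

    p = np.ones(len(diff))
    ok = se > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff[ok] / se[ok]
    p[ok] = 2.0 * t_dist.sf(np.abs(tstat), df[ok])
    degenerate = (~ok) & (diff != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero residual variance but a "
            "nonzero group effect; reporting p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        p[degenerate] = 0.0
    return dict(zip(index, p))


def estimate_pi0(
    pvalues: np.ndarray, lambdas: np.ndarray | None = None, min_m: int = 100
) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a 0.05..0.95 grid is
    smoothed with a cubic spline and evaluated at the largest lambda, then
    clipped into (0, 1].  With fewer than ``min_m`` p-values the spline is
    unstable and the estimate falls back to the conservative pi0 = 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < min_m:
        warnings.warn(
            f"only {p.size} p-values; falling back to pi0 = 1", RuntimeWarning, stacklevel=2
        )
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(pvalues, pi0: float | None = None) -> np.ndarray | dict[str, float]:
    """Storey q-values; with ``pi0=1`` these are exactly Benjamini-Hochberg.

    Accepts an array or a mapping feature_id -> p (returned in kind).
    q_i = pi0 * min over {j : p_j >= p_i} of m * p_j / rank(p_j).
    """
    keys = None
    if isinstance(pvalues, dict):
        keys = list(pvalues.keys())
        p = np.array([pvalues[k] for k in keys], dtype=float)
    else:
        p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    order = np.argsort(p, kind="mergesort")
    m = p.size
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    if keys is not None:
        return dict(zip(keys, q))
    return q


def fold_changes(ds: PairwiseDataset, mode: str = "arithmetic") -> dict[str, float]:
    """Linear fold change strain_a / strain_b per feature.

    'arithmetic' uses group means of the normalized intensities;
    'geometric' exponentiates the mean log2 difference.
    """
    if ds.stage != "normalized":
        raise RuntimeError(f"fold changes require a normalized dataset, got {ds.stage!r}")
    cols_a = ds.strain_columns(ds.strain_a)
    cols_b = ds.strain_columns(ds.strain_b)
    va = ds.matrix.values[cols_a].to_numpy()
    vb = ds.matrix.values[cols_b].to_numpy()
    if mode == "arithmetic":
        mean_a, mean_b = va.mean(axis=1), vb.mean(axis=1)
        if (mean_b <= 0).any():
            raise RuntimeError("non-positive group mean after imputation/normalization")
        fc = mean_a / mean_b
    elif mode == "geometric":
        fc = np.exp2(np.log2(va).mean(axis=1) - np.log2(vb).mean(axis=1))
    else:
        raise ValueError("mode must be 'arithmetic' or 'geometric'")
    return dict(zip(ds.matrix.values.index, fc))


def classify(
    ds: PairwiseDataset,
    pvalues: dict[str, float],
    qvalues: dict[str, float],
    fcs: dict[str, float],
    cfg: PipelineConfig,
) -> list[DifferentialResult]:
    """Volcano classification: significant iff p < p_threshold (strict) and
    fc outside (fc_lower, fc_upper) (strict)."""
    results = []
    for fid in ds.matrix.values.index:
        try:
            p, q, fc = pvalues[fid], qvalues[fid], fcs[fid]
        except KeyError as exc:
            raise ValueError(f"feature {fid!r} missing from statistics maps") from exc
        up = fc > cfg.fc_upper
        down = fc < cfg.fc_lower
        significant = bool(p < cfg.p_threshold and (up or down))
        direction = "up" if up else ("down" if down else "none")
        results.append(
            DifferentialResult(
                feature_id=fid,
                fc=float(fc),
                log2_fc=float(np.log2(fc)),
                p=float(p),
                q=float(q),
                significant=significant,
                direction=direction,
            )
        )
    return results


def volcano_export(
    results: list[DifferentialResult],
    path,
    feature_map: dict | None = None,
    annotations: dict[str, str] | None = None,
) -> None:
    """Write the volcano table with a '# total=N significant=K' footer line."""
    if not results:
        raise ValueError("no results to export")
    feature_map = feature_map or {}
    annotations = annotations or {}
    rows = []
    for r in results:
        feat = feature_map.get(r.feature_id)
        rows.append(
            {
                "feature_id": r.feature_id,
                "mz": f"{feat.mz:.6f}" if feat else "",
                "rt_seconds": f"{feat.rt:.3f}" if feat else "",
                "log2_fc": f"{r.log2_fc:.6f}",
                "neg_log10_p": f"{-np.log10(r.p):.6f}" if r.p > 0 else "inf",
                "q": f"{r.q:.6g}",
                "class": ("significant_" + r.direction) if r.significant else "ns",
                "annotation": annotations.get(r.feature_id, ""),
            }
        )
    df = pd.DataFrame(rows)
    n_sig = sum(r.significant for r in results)
    with open(path, "w", encoding="utf-8") as fh:
        df.to_csv(fh, index=False)
        fh.write(f"# total={len(results)} significant={n_sig}\n")


def read_volcano(path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a volcano export back -> (table, {'total': N, 'significant': K})."""
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    counts = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                for token in line[1:].split():
                    key, _, val = token.partition("=")
                    counts[key] = int(val)
    return df, counts
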