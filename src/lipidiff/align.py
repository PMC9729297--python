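"""Cross-run feature alignment.

Collapses per-run observations of one polarity into consensus features by
greedy median-anchored clustering: observations are scanned in ascending m/z
order and join an open group when they fall within the ppm tolerance of the
group's running median m/z and the RT tolerance of its running median RT.
When several groups qualify the nearest (scaled m/z + RT distance) wins; if
the chosen group already holds a peak from the same run, the more intense
peak stays and the other seeds a new group.  The procedure is deterministic
and near-linear in the number of observations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .model import (
    ConsensusFeature,
    FeatureMatrix,
    FeatureObservation,
    SampleInfo,
    validate_samples,
)


class AlignmentParams:
    """Alignment gates: m/z tolerance in ppm, RT tolerance in seconds."""

    def __init__(self, ppm_tolerance: float = 5.0, rt_align_tolerance_s: float = 15.0):
        if ppm_tolerance <= 0 or rt_align_tolerance_s <= 0:
            raise ValueError("alignment tolerances must be positive")
        self.ppm_tolerance = ppm_tolerance
        self.rt_align_tolerance_s = rt_align_tolerance_s


class _Group:
    __slots__ = ("members", "_mz_sorted", "_rt_sorted")

    def __init__(self, obs: FeatureObservation):
        self.members: dict[str, FeatureObservation] = {obs.sample_id: obs}
        self._mz_sorted = [obs.mz]
        self._rt_sorted = [obs.rt]

    @staticmethod
    def _median(sorted_vals: list[float]) -> float:
        n = len(sorted_vals)
        mid = n // 2
        if n % 2:
            return sorted_vals[mid]
        return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])

    @property
    def mz(self) -> float:
        return self._median(self._mz_sorted)

    @property
    def rt(self) -> float:
        return self._median(self._rt_sorted)

    def add(self, obs: FeatureObservation) -> None:
        self.members[obs.sample_id] = obs
        self._insort(self._mz_sorted, obs.mz)
        self._insort(self._rt_sorted, obs.rt)

    def remove(self, obs: FeatureObservation) -> None:
        del self.members[obs.sample_id]
        self._mz_sorted.remove(obs.mz)
        self._rt_sorted.remove(obs.rt)

    @staticmethod
    def _insort(vals: list[float], v: float) -> None:
        import bisect

        bisect.insort(vals, v)


def align_runs(
    observations: list[FeatureObservation], params: AlignmentParams | None = None
) -> list[ConsensusFeature]:
    """Group single-polarity observations into consensus features.

    Output is sorted by (m/z, RT); feature ids are '<pol>_<index>'.
    Raises ``ValueError`` on mixed polarities.
    """
    params = params or AlignmentParams()
    if not observations:
        return []
    polarities = {o.polarity for o in observations}
    if len(polarities) > 1:
        raise ValueError(f"align_runs expects one polarity, got {sorted(polarities)}")
    polarity = polarities.pop()

    ordered = sorted(observations, key=lambda o: (o.mz, o.rt, o.sample_id, -o.intensity))
    open_groups: list[_Group] = []
    closed: list[_Group] = []

    for obs in ordered:
        # close groups that can no longer match (input sorted by m/z)
        still_open = []
        for g in open_groups:
            if (obs.mz - g.mz) / g.mz * 1e6 > params.ppm_tolerance:
                closed.append(g)
            else:
                still_open.append(g)
        open_groups = still_open

        best: _Group | None = None
        best_dist = np.inf
        for g in open_groups:
            d_ppm = abs(obs.mz - g.mz) / g.mz * 1e6
            d_rt = abs(obs.rt - g.rt)
            if d_ppm <= params.ppm_tolerance and d_rt <= params.rt_align_tolerance_s:
                dist = (d_ppm / params.ppm_tolerance) ** 2 + (
                    d_rt / params.rt_align_tolerance_s
                ) ** 2
                if dist < best_dist:
                    best, best_dist = g, dist

        if best is None:
            open_groups.append(_Group(obs))
            continue
        existing = best.members.get(obs.sample_id)
        if existing is None:
            best.add(obs)
        elif obs.intensity > existing.intensity:
            best.remove(existing)
            best.add(obs)
            open_groups.append(_Group(existing))
        else:
            open_groups.append(_Group(obs))

    groups = closed + open_groups
    groups.sort(key=lambda g: (g.mz, g.rt))
    prefix = polarity[:3]
    return [
        ConsensusFeature(
            feature_id=f"{prefix}_{i:05d}",
            polarity=polarity,
            mz=g.mz,
            rt=g.rt,
            intensities={sid: o.intensity for sid, o in sorted(g.members.items())},
        )
        for i, g in enumerate(groups)
    ]


def build_matrix(
    consensus_pos: list[ConsensusFeature],
    consensus_neg: list[ConsensusFeature],
    samples: list[SampleInfo],
) -> FeatureMatrix:
    """Assemble both polarities into one feature x sample intensity matrix.

    Missing cells are NaN.  Raises on duplicate sample ids or on consensus
    members referencing unknown samples.
    """
    validate_samples(samples)
    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids)
    features = list(consensus_pos) + list(consensus_neg)
    data = np.full((len(features), len(sample_ids)), np.nan)
    col = {sid: j for j, sid in enumerate(sample_ids)}
    for i, f in enumerate(features):
        for sid, intensity in f.intensities.items():
            if sid not in known:
                raise ValueError(f"feature {f.feature_id} references unknown sample {sid!r}")
            data[i, col[sid]] = intensity
    values = pd.DataFrame(data, index=[f.feature_id for f in features], columns=sample_ids)
    return FeatureMatrix(features=features, samples=list(samples), values=values)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    """Write the matrix as delimited text (empty cell = missing)."""
    meta = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in matrix.features],
            "polarity": [f.polarity for f in matrix.features],
            "mz": [f"{f.mz:.6f}" for f in matrix.features],
            "rt_seconds": [f"{f.rt:.3f}" for f in matrix.features],
        }
    ).set_index("feature_id")
    out = meta.join(matrix.values)
    out.to_csv(path, float_format="%.4f")
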