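"""Shared test helpers: independent oracles and quick dataset builders.

The oracles here are deliberately written from scratch (regex formula parser
over a local atomic-mass table, union-find clustering, closed-form t-test)
so they never share code with the implementation paths they check.
"""
from __future__ import annotations

import re

import numpy as np
import pandas as pd

from lipidiff.model import ConsensusFeature, FeatureMatrix, SampleInfo
from lipidiff.preprocess import PairwiseDataset

# independent monoisotopic atomic masses (CODATA/NIST, most abundant isotope)
ATOMIC_MASS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

# independent adduct shifts (proton 1.00727646688; NH4+ = N + 4H - e;
# formate = HCOOH - H+)
_PROTON = 1.00727646688
_ELECTRON = 0.00054857990
ORACLE_ADDUCT_SHIFT = {
    "[M+H]+": _PROTON,
    "[M+NH4]+": ATOMIC_MASS["N"] + 4 * ATOMIC_MASS["H"] - _ELECTRON,
    "[M-H]-": -_PROTON,
    "[M+FA-H]-": ATOMIC_MASS["C"]
    + 2 * ATOMIC_MASS["O"]
    + 2 * ATOMIC_MASS["H"]
    - _PROTON,
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def oracle_mass(formula: str) -> float:
    """Independent exact-mass calculator used to check monoisotopic_mass."""
    total = 0.0
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        total += ATOMIC_MASS[m.group(1)] * int(m.group(2) or 1)
        consumed += len(m.group(0))
    assert consumed == len(formula), f"unparsed characters in {formula!r}"
    return total


def oracle_adduct_mz(neutral_mass: float, adduct: str) -> float:
    return neutral_mass + ORACLE_ADDUCT_SHIFT[adduct]


def brute_force_align(observations, ppm_tol: float, rt_tol: float):
    """All-pairs connected-components clustering with the same gates.

    Returns a partition of observation indices as a set of frozensets.
    """
    n = len(observations)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = observations[i], observations[j]
            if (
                abs(a.mz - b.mz) / min(a.mz, b.mz) * 1e6 <= ppm_tol
                and abs(a.rt - b.rt) <= rt_tol
            ):
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def make_matrix(
    values: np.ndarray,
    strains: tuple[str, ...] = ("A", "B"),
    replicates: int = 6,
    polarity: str = "positive",
) -> FeatureMatrix:
    """Wrap a features x samples array (NaN = missing) into a FeatureMatrix."""
    n_feat, n_samp = values.shape
    samples = [
        SampleInfo(f"{s}_r{i}", s, i)
        for s in strains
        for i in range(1, replicates + 1)
    ]
    assert len(samples) == n_samp
    feats = [
        ConsensusFeature(f"f{i:04d}", polarity, 100.0 + i * 0.5, 60.0 + i, {})
        for i in range(n_feat)
    ]
    df = pd.DataFrame(
        values, index=[f.feature_id for f in feats], columns=[s.sample_id for s in samples]
    )
    return FeatureMatrix(feats, samples, df)


def make_pair(
    values: np.ndarray,
    strain_a: str = "A",
    strain_b: str = "B",
    replicates: int = 6,
    stage: str = "normalized",
) -> PairwiseDataset:
    """Build a two-strain PairwiseDataset directly at a given stage."""
    matrix = make_matrix(values, (strain_a, strain_b), replicates)
    return PairwiseDataset(strain_a=strain_a, strain_b=strain_b, matrix=matrix, stage=stage)
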