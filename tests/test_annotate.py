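"""Annotation: mass matching, cross-polarity confirmation, isomer labels,
composition, and recovery of planted identities on synthetic data."""
import numpy as np
import pytest

from lipidiff.annotate import (
    cross_polarity_confirm,
    label_isomers,
    match_library,
    qc_internal_standards,
    strain_composition,
)
from lipidiff.align import align_runs, build_matrix
from lipidiff.library import default_library
from lipidiff.masses import adduct_mz
from lipidiff.model import (
    DEFAULT_ADDUCT_RULES,
    ConsensusFeature,
    LipidRecord,
    SampleInfo,
)
from lipidiff.simulate import (
    SimConfig,
    design_samples,
    generate_ground_truth,
    simulate_observations,
)

from _util import make_matrix

FFA160 = LipidRecord("FFA 16:0", "FFA", "C16H32O2", 256.24023026536)
MGDG = LipidRecord("MGDG 34:1", "MGDG", "C43H80O10", 756.57520809344)
LPG = LipidRecord("LPG 34:1", "LPG", "C46H87N2O11P", 874.60475374)


def _feat(fid, polarity, mz, rt):
    return ConsensusFeature(fid, polarity, mz, rt, {})


class TestMatchLibrary:
    def test_candidate_within_five_ppm(self):
        feat = _feat("neg_1", "negative", 255.2340, 300.0)
        (cand,) = match_library([feat], [FFA160])
        assert cand.lipid.name == "FFA 16:0"
        assert cand.adduct == "[M-H]-"
        assert cand.ppm == pytest.approx(4.10, abs=0.05)
        assert not cand.confirmed

    def test_no_candidate_beyond_five_ppm(self):
        feat = _feat("neg_1", "negative", 255.2360, 300.0)
        assert match_library([feat], [FFA160]) == []

    def test_multiple_candidates_ppm_sorted(self):
        other = LipidRecord("FFA iso", "FFA", None, FFA160.monoisotopic_mass + 0.0008)
        feat = _feat("neg_1", "negative", 255.2334, 300.0)
        cands = match_library([feat], [other, FFA160])
        assert len(cands) == 2
        assert cands[0].ppm <= cands[1].ppm

    def test_polarity_rule_respected(self):
        # MGDG has no negative-mode adduct: a negative feature at the
        # ammonium-adduct mass must not match
        mz = adduct_mz(MGDG.monoisotopic_mass, "[M+NH4]+")
        assert match_library([_feat("neg_1", "negative", mz, 100.0)], [MGDG]) == []
        assert len(match_library([_feat("pos_1", "positive", mz, 100.0)], [MGDG])) == 1


class TestCrossPolarityConfirm:
    def _ffa_pair(self, rt_neg, rt_pos):
        neg = _feat("neg_1", "negative", adduct_mz(FFA160.monoisotopic_mass, "[M-H]-"), rt_neg)
        pos = _feat("pos_1", "positive", adduct_mz(FFA160.monoisotopic_mass, "[M+NH4]+"), rt_pos)
        return match_library([neg, pos], [FFA160])

    def test_coeluting_pair_confirmed_and_linked(self):
        out = cross_polarity_confirm(self._ffa_pair(300.0, 310.0))
        assert all(a.confirmed for a in out)
        partners = {a.feature_id: a.partner_feature_id for a in out}
        assert partners == {"neg_1": "pos_1", "pos_1": "neg_1"}

    def test_separated_pair_not_confirmed(self):
        out = cross_polarity_confirm(self._ffa_pair(300.0, 345.0))
        assert not any(a.confirmed for a in out)

    def test_boundary_thirty_seconds_exclusive(self):
        assert not any(a.confirmed for a in cross_polarity_confirm(self._ffa_pair(300.0, 330.0)))
        assert all(a.confirmed for a in cross_polarity_confirm(self._ffa_pair(300.0, 329.9)))

    def test_single_polarity_subclasses_confirmed_alone(self):
        pos = _feat("pos_1", "positive", adduct_mz(MGDG.monoisotopic_mass, "[M+NH4]+"), 100.0)
        neg = _feat("neg_1", "negative", adduct_mz(LPG.monoisotopic_mass, "[M-H]-"), 200.0)
        out = cross_polarity_confirm(match_library([pos, neg], [MGDG, LPG]))
        assert all(a.confirmed for a in out)
        assert all(a.partner_feature_id is None for a in out)

    def test_unpaired_dual_polarity_candidate_unconfirmed(self):
        neg = _feat("neg_1", "negative", adduct_mz(FFA160.monoisotopic_mass, "[M-H]-"), 300.0)
        out = cross_polarity_confirm(match_library([neg], [FFA160]))
        assert not out[0].confirmed


class TestIsomerLabels:
    def _confirmed(self, rts, mzs=None):
        mz0 = adduct_mz(FFA160.monoisotopic_mass, "[M-H]-")
        mzs = mzs or [mz0] * len(rts)
        feats = [_feat(f"neg_{i}", "negative", m, rt) for i, (m, rt) in enumerate(zip(mzs, rts))]
        pos = [
            _feat(f"pos_{i}", "positive", adduct_mz(FFA160.monoisotopic_mass, "[M+NH4]+"), rt)
            for i, rt in enumerate(rts)
        ]
        return [a for a in cross_polarity_confirm(match_library(feats + pos, [FFA160]))
                if a.confirmed]

    def test_two_isomers_labeled_by_rt(self):
        out = label_isomers(self._confirmed([300.0, 500.0]))
        labels = {a.feature_id: a.isomer_label for a in out if a.polarity == "negative"}
        assert labels == {"neg_0": "a", "neg_1": "b"}

    def test_single_match_unlabeled(self):
        out = label_isomers(self._confirmed([300.0]))
        assert all(a.isomer_label == "" for a in out)

    def test_rt_tie_broken_by_mz(self):
        mz0 = adduct_mz(FFA160.monoisotopic_mass, "[M-H]-")
        out = label_isomers(self._confirmed([300.0, 300.0], [mz0 + 0.0005, mz0]))
        labels = {a.feature_id: a.isomer_label for a in out if a.polarity == "negative"}
        assert labels == {"neg_1": "a", "neg_0": "b"}

    def test_unconfirmed_input_rejected(self):
        cand = match_library(
            [_feat("neg_1", "negative", adduct_mz(FFA160.monoisotopic_mass, "[M-H]-"), 1.0)],
            [FFA160],
        )
        with pytest.raises(ValueError, match="confirmed"):
            label_isomers(cand)


class TestStrainComposition:
    def test_presence_rule_arithmetic(self):
        # 2 FFA at 6/6, one PE at 5/6, one PC at 3/6 -> FFA 2, PE 1, PC excluded
        rows = np.array(
            [
                [1.0] * 6 + [np.nan] * 6,
                [1.0] * 6 + [np.nan] * 6,
                [1.0] * 5 + [np.nan] * 7,
                [1.0] * 3 + [np.nan] * 9,
            ]
        )
        matrix = make_matrix(rows, ("A", "B"), 6, polarity="negative")
        lipids = [
            LipidRecord("FFA 16:0", "FFA", None, 256.24023),
            LipidRecord("FFA 18:0", "FFA", None, 284.27153),
            LipidRecord("PE 34:1", "PE", None, 717.53089),
            LipidRecord("PC 34:1", "PC", None, 759.57785),
        ]
        from lipidiff.annotate import Annotation

        confirmed = [
            Annotation(f"f{i:04d}", "negative", 100.0, 60.0, lip, "[M-H]-", 1.0, confirmed=True)
            for i, lip in enumerate(lipids)
        ]
        summaries = strain_composition(matrix, confirmed)
        a = summaries["A"]
        assert a.counts == {"FFA": 2, "PE": 1}
        assert a.proportions["FFA"] == pytest.approx(2 / 3)
        assert a.proportions["PE"] == pytest.approx(1 / 3)

    def test_all_below_threshold_warns_empty(self):
        rows = np.array([[1.0] * 2 + [np.nan] * 10])
        matrix = make_matrix(rows, ("A", "B"), 6)
        from lipidiff.annotate import Annotation

        confirmed = [
            Annotation("f0000", "positive", 100.0, 60.0, FFA160, "[M+NH4]+", 1.0, confirmed=True)
        ]
        with pytest.warns(RuntimeWarning, match="presence"):
            summaries = strain_composition(matrix, confirmed)
        assert summaries["A"].counts == {}


class TestSyntheticRecovery:
    def _run(self, cfg):
        truth = generate_ground_truth(cfg)
        obs = simulate_observations(truth, cfg)
        by_pol = {"positive": [], "negative": []}
        for o in obs:
            by_pol[o.polarity].append(o)
        consensus = {pol: align_runs(v) for pol, v in by_pol.items()}
        matrix = build_matrix(consensus["positive"], consensus["negative"], design_samples(cfg))
        candidates = match_library(matrix.features, default_library())
        confirmed = [a for a in cross_polarity_confirm(candidates) if a.confirmed]
        return truth, matrix, confirmed

    def test_noiseless_identities_recovered_exactly(self):
        """On a noiseless fixture annotation attains 100% precision and
        recall for library lipids; unknown features stay unannotated."""
        cfg = SimConfig(
            seed=17, n_lipids=40, noise_cv=0.0, ppm_noise_sd=0.0, rt_jitter_sd=0.0,
            dropout_prob=0.0, unknown_feature_rate=0.2, n_differential=0,
            spike_standards=False,
        )
        truth, matrix, confirmed = self._run(cfg)
        truth_names = {t.lipid.name for t in truth if not t.is_unknown}
        recovered = {a.lipid.name for a in confirmed}
        assert recovered == truth_names
        # unknown features: no annotation at all (candidates included)
        unknown_mz = {round(mz, 4) for t in truth if t.is_unknown for _, _, mz in t.ions}
        annotated_mz = {round(a.mz, 4) for a in confirmed}
        assert unknown_mz.isdisjoint(annotated_mz)

    def test_polarity_constraints_never_violated(self):
        cfg = SimConfig(seed=19, n_lipids=60)
        _, _, confirmed = self._run(cfg)
        for a in confirmed:
            rule = DEFAULT_ADDUCT_RULES[a.lipid.subclass]
            assert rule.adduct_for(a.polarity) == a.adduct
            if a.lipid.subclass in ("MGDG", "DGDG"):
                assert a.polarity == "positive"
            if a.lipid.subclass == "LPG":
                assert a.polarity == "negative"

    def test_noisy_recall_of_planted_library_lipids(self):
        """At the study noise level (ppm sd <= 5/3, RT jitter <= 5 s) recall
        of planted library lipids stays >= 0.95 across seeds."""
        recalls = []
        for seed in range(5):
            cfg = SimConfig(
                seed=seed, n_lipids=50, ppm_noise_sd=5.0 / 3.0, rt_jitter_sd=5.0,
                dropout_prob=0.0, unknown_feature_rate=0.0, spike_standards=False,
            )
            truth, _, confirmed = self._run(cfg)
            names = {t.lipid.name for t in truth}
            recalls.append(len({a.lipid.name for a in confirmed} & names) / len(names))
        assert np.mean(recalls) >= 0.95

    def test_op50_like_strain_has_no_glycolipids_in_composition(self):
        cfg = SimConfig(seed=23, n_lipids=150)
        truth, matrix, confirmed = self._run(cfg)
        confirmed = label_isomers(confirmed)
        summaries = strain_composition(matrix, confirmed)
        op50 = summaries["OP50"]
        assert op50.counts.get("MGDG", 0) == 0
        assert op50.counts.get("DGDG", 0) == 0
        assert summaries["HA-114"].counts.get("MGDG", 0) > 0
        for s, summ in summaries.items():
            if summ.proportions:
                assert sum(summ.proportions.values()) == pytest.approx(1.0)


def test_internal_standard_qc_detects_spiked_standards():
    cfg = SimConfig(seed=29, n_lipids=30)
    truth = generate_ground_truth(cfg)
    obs = simulate_observations(truth, cfg)
    by_pol = {"positive": [], "negative": []}
    for o in obs:
        by_pol[o.polarity].append(o)
    consensus = {pol: align_runs(v) for pol, v in by_pol.items()}
    records = qc_internal_standards(consensus["positive"], consensus["negative"])
    assert len(records) == 12  # 6 standards x 2 polarity probes
    assert all(r["detected"] for r in records)
    assert all(r["ppm"] is not None and r["ppm"] <= 5.0 for r in records)
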