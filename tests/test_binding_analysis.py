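import numpy as np
import pandas as pd
import pytest

from camstates.binding_analysis import (
    DEFAULT_RESIDUE_TYPES,
    ContactVector,
    classify_binding_modes,
    contact_residue_types,
    contact_vector,
    matching_scores,
)
from camstates.state_features import relative_exposure, solvent_exposure
from camstates.structure_io import AtomRecord, Ensemble, Topology
from camstates.synthetic_data import (
    SyntheticConfig,
    WaterShellConfig,
    default_state_plan,
    generate_complex,
    generate_ensemble,
    generate_water_shell,
)


def _two_chain_ensemble(cam_xyz, pep_xyz, n_models=1, pep_offsets=None):
    """CaM chain A (one CA per residue) + peptide chain B."""
    atoms, serial = [], 1
    for i in range(len(cam_xyz)):
        atoms.append(AtomRecord(serial, "CA", "C", "ALA", i + 1, "A"))
        serial += 1
    for j in range(len(pep_xyz)):
        atoms.append(AtomRecord(serial, "CA", "C", "GLY", j + 1, "B"))
        serial += 1
    coords = np.zeros((n_models, len(atoms), 3))
    for f in range(n_models):
        coords[f, : len(cam_xyz)] = cam_xyz
        shift = 0.0 if pep_offsets is None else pep_offsets[f]
        coords[f, len(cam_xyz) :] = np.asarray(pep_xyz) + shift
    return Ensemble(Topology(atoms), coords)


class TestContactVector:
    def test_single_model_cutoff(self):
        cam = [[0, 0, 0], [10, 0, 0], [20, 0, 0]]
        pep = [[4.0, 0, 0]]  # 4.0 from residue 1, 6.0 from residue 2
        ens = _two_chain_ensemble(cam, pep)
        cv = contact_vector(ens, "A", "B")
        assert cv.m.tolist() == [1, 0, 0]

    def test_ensemble_fraction_boundary(self):
        cam = [[0, 0, 0], [30, 0, 0]]
        pep = [[3.0, 0, 0]]
        # contact in 7 of 10 models -> in; 6 of 10 -> out
        off7 = [np.zeros(3)] * 7 + [np.array([20.0, 0, 0])] * 3
        ens7 = _two_chain_ensemble(cam, pep, n_models=10, pep_offsets=off7)
        assert contact_vector(ens7, "A", "B").m[0] == 1
        off6 = [np.zeros(3)] * 6 + [np.array([20.0, 0, 0])] * 4
        ens6 = _two_chain_ensemble(cam, pep, n_models=10, pep_offsets=off6)
        assert contact_vector(ens6, "A", "B").m[0] == 0

    def test_residue_map(self):
        cam = [[0, 0, 0], [10, 0, 0]]
        ens = _two_chain_ensemble(cam, [[2.0, 0, 0]])
        cv = contact_vector(ens, "A", "B", residue_map={1: 101, 2: 102})
        assert cv.contact_seqs.tolist() == [101]
        with pytest.raises(ValueError, match="unmappable"):
            contact_vector(ens, "A", "B", residue_map={1: 101})

    def test_missing_chain_rejected(self):
        ens = _two_chain_ensemble([[0, 0, 0]], [[3, 0, 0]])
        with pytest.raises(ValueError, match="chain"):
            contact_vector(ens, "X", "B")

    def test_planted_contacts_recovered(self, frozen_config):
        ens, _ = generate_ensemble(frozen_config)
        comp = generate_complex(ens.frame(0), [4, 7, 10], 5, 1.0, seed=3)
        cv = contact_vector(comp, "A", "B", complex_id="toy")
        assert sorted(cv.contact_seqs.tolist()) == [4, 7, 10]


class TestMatchingScores:
    def _contacts(self, seqs, names, m):
        return ContactVector(
            complex_id="c",
            residue_seqs=np.asarray(seqs),
            residue_names=np.asarray(names),
            m=np.asarray(m),
        )

    def test_stated_arithmetic(self):
        s = pd.DataFrame([[1.2, 0.8, 1.0]], index=[0], columns=[1, 2, 3])
        s = pd.concat([s, s * 0 + 1.0])  # second state all ones
        cv = self._contacts([1, 2, 3], ["ALA"] * 3, [1, 0, 1])
        dist = matching_scores(s, cv)
        assert dist.raw[0] == pytest.approx(2.2)
        assert dist.raw[1] == pytest.approx(2.0)

    def test_normalization(self):
        s = pd.DataFrame(
            [[2.0], [1.0], [1.0]], index=[0, 1, 2], columns=[1]
        )
        cv = self._contacts([1], ["ALA"], [1])
        dist = matching_scores(s, cv)
        assert np.allclose(dist.normalized, [0.5, 0.25, 0.25])
        assert dist.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_exposure_gives_uniform_distribution(self):
        s = pd.DataFrame(np.ones((4, 6)), columns=range(1, 7))
        cv = self._contacts(list(range(1, 7)), ["ALA"] * 6, [1, 1, 0, 0, 1, 0])
        dist = matching_scores(s, cv)
        assert np.allclose(dist.normalized, 0.25)

    def test_monotonicity_in_exposure(self):
        rng = np.random.default_rng(0)
        s = pd.DataFrame(rng.uniform(0.5, 1.5, (3, 4)), columns=range(1, 5))
        cv = self._contacts([1, 2, 3, 4], ["ALA"] * 4, [1, 0, 0, 0])
        base = matching_scores(s, cv)
        s2 = s.copy()
        s2.iloc[1, 0] += 0.5  # raise state 1's exposure of contact residue 1
        bumped = matching_scores(s2, cv)
        assert bumped.raw[1] > base.raw[1]
        assert bumped.normalized[1] > base.normalized[1]

    def test_all_zero_rejected(self):
        s = pd.DataFrame(np.zeros((2, 2)), columns=[1, 2])
        cv = self._contacts([1, 2], ["ALA"] * 2, [1, 1])
        with pytest.raises(ValueError, match="zero"):
            matching_scores(s, cv)


class TestClassification:
    def _dist(self, vec, cid):
        from camstates.binding_analysis import MatchingDistribution

        vec = np.asarray(vec, dtype=float)
        return MatchingDistribution(
            complex_id=cid, raw=vec, normalized=vec / vec.sum(), states=np.arange(len(vec))
        )

    def test_two_template_recovery(self):
        rng = np.random.default_rng(0)
        p = np.array([0.7, 0.1, 0.1, 0.1])
        q = np.array([0.1, 0.1, 0.1, 0.7])
        dists = []
        for i in range(4):
            dists.append(self._dist(p + rng.uniform(0, 0.01, 4), f"p{i}"))
        for i in range(4):
            dists.append(self._dist(q + rng.uniform(0, 0.01, 4), f"q{i}"))
        model = classify_binding_modes(dists, k=2, seed=0)
        labels = model.labels
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]
        assert np.allclose(model.class_mean.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_distributions_single_class(self):
        dists = [self._dist([1.0, 1.0], f"c{i}") for i in range(4)]
        model = classify_binding_modes(dists, k=None, seed=0)
        assert model.k == 1
        assert len(set(model.labels.tolist())) == 1

    def test_too_few_complexes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            classify_binding_modes([self._dist([1.0], "a")])

    def test_k_exceeding_complexes_rejected(self):
        dists = [self._dist([1.0, 2.0], f"c{i}") for i in range(3)]
        with pytest.raises(ValueError, match="exceeds"):
            classify_binding_modes(dists, k=5)


class TestResidueTypes:
    def test_stated_fractions(self):
        cv = ContactVector(
            complex_id="c",
            residue_seqs=np.arange(1, 5),
            residue_names=np.array(["LYS", "LYS", "LEU", "SER"]),
            m=np.ones(4, dtype=int),
        )
        fracs = contact_residue_types(cv)
        assert np.allclose(fracs, [0.25, 0.25, 0.5])  # apolar, polar, charged

    def test_all_apolar(self):
        cv = ContactVector(
            complex_id="c",
            residue_seqs=np.arange(1, 4),
            residue_names=np.array(["LEU"] * 3),
            m=np.ones(3, dtype=int),
        )
        assert np.allclose(contact_residue_types(cv), [1.0, 0.0, 0.0])

    def test_empty_contacts_rejected(self):
        cv = ContactVector(
            complex_id="c",
            residue_seqs=np.arange(1, 4),
            residue_names=np.array(["LEU"] * 3),
            m=np.zeros(3, dtype=int),
        )
        with pytest.raises(ValueError, match="empty"):
            contact_residue_types(cv)

    def test_unknown_residue_rejected(self):
        cv = ContactVector(
            complex_id="c",
            residue_seqs=np.array([1]),
            residue_names=np.array(["XYZ"]),
            m=np.array([1]),
        )
        with pytest.raises(ValueError, match="no type mapping"):
            contact_residue_types(cv)

    def test_table_covers_standard_residues(self):
        assert len(DEFAULT_RESIDUE_TYPES) == 20
        assert set(DEFAULT_RESIDUE_TYPES.values()) == {"apolar", "polar", "charged"}


class TestConformationalSelectionEndToEnd:
    def test_complex_scores_peak_at_exposing_state(self):
        # three states exposing disjoint residue windows; complexes
        # contacting window i must score maximal at state i
        burial = {
            s: np.r_[
                np.full(10 * s, 0.15),
                np.ones(10),
                np.full(88 - 10 * (s + 1), 0.15),
            ]
            for s in range(3)
        }
        cfg = SyntheticConfig(
            n_frames=90,
            seed=13,
            planted_states=default_state_plan(3),
            water_shell=WaterShellConfig(burial_mask=burial),
        )
        ens, truth = generate_ensemble(cfg)
        wet = generate_water_shell(ens, cfg, frame_state=truth.frame_state)
        prof = solvent_exposure(wet, labels=truth.frame_state)
        rel = relative_exposure(prof)

        import dataclasses

        from camstates.synthetic_data import feasible_contact_residues

        ref_cfg = dataclasses.replace(
            cfg,
            n_frames=1,
            coord_noise_sd=0.0,
            lobe_wobble_deg=0.0,
            planted_states=[cfg.planted_states[0]],
        )
        ref = generate_ensemble(ref_cfg)[0].frame(0)
        for s in range(3):
            window = list(range(10 * s + 1, 10 * s + 11))
            contacts = feasible_contact_residues(ref, window, seed=1)[:3]
            assert len(contacts) >= 2
            comp = generate_complex(ref, contacts, 3, 1.0, seed=50 + s)
            cv = contact_vector(comp, "A", "B", complex_id=f"w{s}")
            dist = matching_scores(rel, cv)
            assert int(np.argmax(dist.normalized)) == s
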