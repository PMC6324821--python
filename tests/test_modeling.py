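import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from chromotrace import modeling, synth
from chromotrace.modeling import BeadModel, RestraintSet


class TestBeadModel:
    def test_intervals_follow_bin_size(self):
        m = BeadModel(np.zeros((5, 3)), bin_size=10_000, chrom="chr19",
                      start=7_400_000)
        iv = m.bead_intervals()
        assert list(iv["start"]) == [7_400_000 + k * 10_000 for k in range(5)]
        assert (iv["end"] - iv["start"] == 10_000).all()

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            BeadModel(np.array([[0.0, np.nan, 0.0]]))
        with pytest.raises(ValueError):
            BeadModel(np.zeros((3, 3)), radius=0.0)

    def test_transform_is_rigid(self, rng):
        m = BeadModel(rng.normal(size=(20, 3)) * 100)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=0).as_matrix()
        t = np.array([10.0, -5.0, 3.0])
        out = m.transformed(R, t)
        np.testing.assert_allclose(pdist(out.coords), pdist(m.coords), atol=1e-9)


class TestRestraintsFromContacts:
    def test_uniform_matrix_yields_bonds_only(self):
        n = 20
        mat = np.full((n, n), 0.3)
        np.fill_diagonal(mat, 1.0)
        rs = modeling.restraints_from_contacts(mat)
        assert set(rs.pairs["kind"]) == {"bond"}
        assert len(rs.of_kind("bond")) == n - 1
        assert (rs.of_kind("bond")["d0_nm"] == 2 * rs.bead_radius).all()

    def test_single_enriched_pair_gets_upper_bound(self, rng):
        n = 30
        # heterogeneous background so strata have genuine spread
        base = rng.uniform(0.05, 0.4, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 1.0)
        i, j = 4, 22
        mat[i, j] = mat[j, i] = 50.0
        rs = modeling.restraints_from_contacts(mat, z_cutoff=2.5)
        ub = rs.of_kind("ub")
        assert len(ub) == 1
        assert (int(ub["i"].iloc[0]), int(ub["j"].iloc[0])) == (i, j)

    def test_stronger_enrichment_shortens_d0(self, rng):
        n = 40
        base = rng.uniform(0.05, 0.4, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 1.0)
        mat[2, 20] = mat[20, 2] = 5.0
        mat[5, 23] = mat[23, 5] = 500.0   # same stratum, stronger
        rs = modeling.restraints_from_contacts(mat, z_cutoff=1.0)
        ub = rs.of_kind("ub").set_index(["i", "j"])
        if (2, 20) in ub.index and (5, 23) in ub.index:
            assert ub.loc[(5, 23), "d0_nm"] <= ub.loc[(2, 20), "d0_nm"]

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="square"):
            modeling.restraints_from_contacts(np.ones((3, 4)))
        bad = np.ones((4, 4))
        bad[0, 1] = 2.0
        with pytest.raises(ValueError, match="symmetric"):
            modeling.restraints_from_contacts(bad)

    def test_bead_count_mismatch_with_coords(self):
        rs = modeling.restraints_from_contacts(np.eye(5) + 0.1)
        with pytest.raises(ValueError):
            modeling.restraint_energy(np.zeros((7, 3)), rs)


class TestRestraintEnergy:
    @staticmethod
    def single_pair(kind, d0, k=1.0, n=2):
        pairs = pd.DataFrame([(0, 1, kind, d0, k)],
                             columns=["i", "j", "kind", "d0_nm", "k"])
        return RestraintSet(pairs=pairs, n_beads=n, bead_radius=5.0, k_ev=0.0)

    def test_lower_bound_harmonic_value(self):
        rs = self.single_pair("lb", d0=100.0)
        coords = np.array([[0.0, 0, 0], [80.0, 0, 0]])
        assert modeling.restraint_energy(coords, rs)["lb"] == pytest.approx(400.0)
        coords[1, 0] = 120.0  # beyond d0: lower bound inactive
        assert modeling.restraint_energy(coords, rs)["lb"] == 0.0

    def test_upper_bound_harmonic_value(self):
        rs = self.single_pair("ub", d0=100.0)
        coords = np.array([[0.0, 0, 0], [130.0, 0, 0]])
        assert modeling.restraint_energy(coords, rs)["ub"] == pytest.approx(900.0)
        coords[1, 0] = 90.0
        assert modeling.restraint_energy(coords, rs)["ub"] == 0.0

    def test_excluded_volume_vanishes_beyond_contact(self, rng):
        pairs = pd.DataFrame(columns=["i", "j", "kind", "d0_nm", "k"])
        rs = RestraintSet(pairs=pairs, n_beads=4, bead_radius=10.0, k_ev=1.0)
        coords = np.array([[0, 0, 0], [25.0, 0, 0], [50.0, 0, 0], [100.0, 0, 0]])
        assert modeling.restraint_energy(coords, rs)["ev"] == 0.0
        coords[3] = [-10.0, 0, 0]  # bead 3 clashes with bead 0 only (d=10 < 20)
        assert modeling.restraint_energy(coords, rs)["ev"] == pytest.approx(100.0)

    def test_gradient_matches_finite_differences(self, rng):
        chain = synth.make_chain(10, bond_length=30, confinement_radius=200, seed=1)
        ens = synth.perturbed_ensemble(chain, 10, 15.0, seed=2)
        rs = modeling.restraints_from_contacts(
            synth.contacts_from_ensemble(ens, 90.0), bead_radius=chain.radius)
        x0 = chain.coords + rng.normal(scale=5, size=chain.coords.shape)
        _, g = modeling.restraint_energy(x0, rs, grad=True)
        eps = 1e-5
        for idx in [(0, 0), (4, 1), (9, 2)]:
            xp = x0.copy(); xp[idx] += eps
            xm = x0.copy(); xm[idx] -= eps
            num = (modeling.restraint_energy(xp, rs)["total"]
                   - modeling.restraint_energy(xm, rs)["total"]) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-5)

    def test_bond_must_join_adjacent_beads(self):
        pairs = pd.DataFrame([(0, 5, "bond", 30.0, 1.0)],
                             columns=["i", "j", "kind", "d0_nm", "k"])
        with pytest.raises(ValueError, match="adjacent"):
            RestraintSet(pairs=pairs, n_beads=6)


@pytest.fixture(scope="module")
def toy_restraints():
    chain = synth.make_chain(20, bond_length=40, confinement_radius=250, seed=7)
    ens = synth.perturbed_ensemble(chain, 20, 20.0, seed=8)
    rs = modeling.restraints_from_contacts(
        synth.contacts_from_ensemble(ens, 120.0), bead_radius=chain.radius)
    return chain, rs


class TestModelEnsemble:
    def test_retention_count_and_energy_ranking(self, toy_restraints):
        _, rs = toy_restraints
        models, energies = modeling.model_ensemble(rs, n_models=30, n_keep=10,
                                                   seed=0, maxiter=40)
        assert len(models) == 10
        assert (np.diff(energies) >= 0).all()
        # kept energies are no worse than any discarded model's energy
        _, all_e = modeling.model_ensemble(rs, n_models=30, n_keep=30,
                                           seed=0, maxiter=40)
        assert energies[-1] <= all_e[10:].min() + 1e-9

    def test_n_keep_validation(self, toy_restraints):
        _, rs = toy_restraints
        with pytest.raises(ValueError):
            modeling.model_ensemble(rs, n_models=5, n_keep=6)

    def test_deterministic_given_seed(self, toy_restraints):
        _, rs = toy_restraints
        m1, e1 = modeling.model_ensemble(rs, n_models=5, n_keep=2, seed=3, maxiter=20)
        m2, e2 = modeling.model_ensemble(rs, n_models=5, n_keep=2, seed=3, maxiter=20)
        np.testing.assert_array_equal(m1[0].coords, m2[0].coords)
        np.testing.assert_array_equal(e1, e2)

    def test_planted_distance_structure_recovered(self, toy_restraints):
        chain, rs = toy_restraints
        models, _ = modeling.model_ensemble(rs, n_models=40, n_keep=15,
                                            seed=1, maxiter=100)
        dm_mean = np.mean([pdist(m.coords) for m in models], axis=0)
        rho = spearmanr(pdist(chain.coords), dm_mean).statistic
        assert rho > 0.6
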