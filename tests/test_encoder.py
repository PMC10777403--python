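"""Encoder contracts: equivalence with a naive loop-based reference,
permutation invariance, readout activations, constraints, latents,
checkpoints, and gradient correctness."""

import numpy as np
import pytest
from rdkit import Chem

from dmpnn import featurization as F
from dmpnn.autodiff import Tensor
from dmpnn.encoder import (AtomBondModel, AtomBondTargets, EncoderConfig,
                           FFN, MPNNEncoder, PropertyModel, ReadoutSpec,
                           TargetSpec)


# ---------------------------------------------------------------------------
# Independent reference: explicit Python loops, no shared index machinery.
def naive_forward(graph: F.MolGraph, enc: MPNNEncoder,
                  activation=lambda x: np.maximum(x, 0.0)):
    """Loop-based forward pass of the message-passing stages.

    Rebuilds adjacency from (src, dst) pairs itself — it does not trust
    rev_index or any vectorized batching — and returns
    (atom embeddings, molecular mean embedding).
    """
    Wi = enc.W_i.W.data
    Wh = enc.W_h.W.data
    Wo = enc.W_o.W.data
    n_edges = graph.n_edges
    edges = [(int(graph.src[k]), int(graph.dst[k])) for k in range(n_edges)]

    def reverse_of(k):
        v, w = edges[k]
        for j, (a, b) in enumerate(edges):
            if (a, b) == (w, v) and j != k:
                return j
        raise AssertionError("no reverse twin found")

    h0 = [activation(graph.edge_features[k] @ Wi) for k in range(n_edges)]
    h = [x.copy() for x in h0]
    for _ in range(enc.config.depth - 1):
        new = []
        for k in range(n_edges):
            v, w = edges[k]
            msg = np.zeros(enc.config.hidden_size)
            for j in range(n_edges):
                if edges[j][1] == v and j != reverse_of(k):
                    msg += h[j]
            new.append(activation(h0[k] + msg @ Wh))
        h = new
    atom_embeds = []
    for v in range(graph.n_atoms):
        inc = np.zeros(enc.config.hidden_size)
        for j in range(n_edges):
            if edges[j][1] == v:
                inc += h[j]
        q = np.concatenate([graph.atom_features[v], inc])
        atom_embeds.append(activation(q @ Wo))
    atom_embeds = np.stack(atom_embeds)
    return atom_embeds, atom_embeds.mean(axis=0)


def small_encoder(seed=0, hidden=16, depth=3, **kw):
    cfg = EncoderConfig(hidden_size=hidden, depth=depth, **kw)
    return MPNNEncoder(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
class TestStages:
    def test_init_edge_states_hand_computed(self):
        enc = small_encoder(hidden=4)
        g = F.build_mol_graph("CC")
        h0 = enc.init_edge_states(F.batch_graphs([g]))
        want = np.maximum(g.edge_features @ enc.W_i.W.data, 0.0)
        np.testing.assert_allclose(h0.data, want, atol=1e-12)

    def test_zero_input_weight_gives_zero_states(self):
        enc = small_encoder(hidden=4)
        enc.W_i.W.data[:] = 0.0
        g = F.batch_graphs([F.build_mol_graph("CCO")])
        assert np.all(enc.init_edge_states(g).data == 0.0)

    def test_ethane_reverse_exclusion_empties_message(self):
        """In ethane each edge's only incoming edge is its own reverse, so
        the neighbor sum is empty and h1 = tau(h0 + W_h @ 0)."""
        enc = small_encoder(hidden=8)
        batch = F.batch_graphs([F.build_mol_graph("CC")])
        h0 = enc.init_edge_states(batch)
        h1 = enc.message_pass(batch, h0, h0)
        want = np.maximum(h0.data, 0.0)
        np.testing.assert_allclose(h1.data, want, atol=1e-12)

    def test_propane_center_edges_get_one_message(self):
        """Brute-force enumeration of N(v)\\w on the 4-edge path graph."""
        enc = small_encoder(hidden=8)
        g = F.build_mol_graph("CCC")
        batch = F.batch_graphs([g])
        h0 = enc.init_edge_states(batch)
        h1 = enc.message_pass(batch, h0, h0)
        for k in range(g.n_edges):
            v = g.src[k]
            msg = np.zeros(8)
            for j in range(g.n_edges):
                if g.dst[j] == v and j != g.rev_index[k]:
                    msg += h0.data[j]
            want = np.maximum(h0.data[k] + msg @ enc.W_h.W.data, 0.0)
            np.testing.assert_allclose(h1.data[k], want, atol=1e-12)

    def test_isolated_atom_embedding(self):
        enc = small_encoder(hidden=8)
        batch = F.batch_graphs([F.build_mol_graph("C")])
        _, atoms, mols = enc.forward(batch)
        q = np.concatenate([batch.atom_features[0], np.zeros(8)])
        want = np.maximum(q @ enc.W_o.W.data, 0.0)
        np.testing.assert_allclose(atoms.data[0], want, atol=1e-12)
        np.testing.assert_allclose(mols.data[0], want, atol=1e-12)

    def test_benzene_symmetry_identical_atom_embeddings(self):
        enc = small_encoder(hidden=16)
        batch = F.batch_graphs([F.build_mol_graph("c1ccccc1")])
        _, atoms, _ = enc.forward(batch)
        assert np.max(np.abs(atoms.data - atoms.data[0])) < 1e-10


class TestOracleEquivalence:
    @pytest.mark.parametrize("smiles", ["CC", "CCC", "CCO", "c1ccccc1",
                                        "CC(C)O", "C1CC1"])
    def test_matches_naive_reference(self, smiles):
        for seed in range(3):
            enc = small_encoder(seed=seed, hidden=12)
            g = F.build_mol_graph(smiles)
            _, atoms, mols = enc.forward(F.batch_graphs([g]))
            ref_atoms, ref_mol = naive_forward(g, enc)
            np.testing.assert_allclose(atoms.data, ref_atoms, atol=1e-6)
            np.testing.assert_allclose(mols.data[0], ref_mol, atol=1e-6)

    def test_batching_matches_per_molecule(self):
        enc = small_encoder(hidden=12)
        graphs = [F.build_mol_graph(s) for s in ["CCO", "c1ccccc1", "CC"]]
        _, _, mols = enc.forward(F.batch_graphs(graphs))
        for i, g in enumerate(graphs):
            _, _, single = enc.forward(F.batch_graphs([g]))
            np.testing.assert_allclose(mols.data[i], single.data[0], atol=1e-10)


class TestPermutationInvariance:
    def test_embeddings_stable_across_smiles_renderings(self, small_molecules):
        enc = small_encoder(hidden=16)
        rng = np.random.default_rng(0)
        for smi in small_molecules[:10]:
            mol = Chem.MolFromSmiles(smi)
            base = None
            for _ in range(4):
                alt = Chem.MolToSmiles(mol, canonical=False, doRandom=True)
                g = F.build_mol_graph(alt)
                _, _, m = enc.forward(F.batch_graphs([g]))
                if base is None:
                    base = m.data[0]
                else:
                    np.testing.assert_allclose(m.data[0], base, atol=1e-6)


class TestAggregation:
    def test_modes_on_benzene(self):
        g = F.build_mol_graph("c1ccccc1")
        for mode, scale in [("mean", 1.0), ("sum", 6.0), ("norm", 6.0 / 100.0)]:
            enc = small_encoder(hidden=8, aggregation=mode)
            batch = F.batch_graphs([g])
            _, atoms, mols = enc.forward(batch)
            np.testing.assert_allclose(mols.data[0], scale * atoms.data[0],
                                       atol=1e-10)

    def test_norm_with_scaler_n_equals_mean(self):
        g = F.build_mol_graph("c1ccccc1")
        enc_norm = small_encoder(hidden=8, aggregation="norm", norm_scaler=6.0)
        enc_mean = small_encoder(hidden=8, aggregation="mean")
        m1 = enc_norm.forward(F.batch_graphs([g]))[2].data
        m2 = enc_mean.forward(F.batch_graphs([g]))[2].data
        np.testing.assert_allclose(m1, m2, atol=1e-10)


class TestReadout:
    def test_multiclass_sums_to_one(self, rng):
        spec = TargetSpec("multiclass", n_tasks=2, n_classes=4)
        model = PropertyModel(spec, EncoderConfig(hidden_size=16), seed=3)
        batch = F.batch_graphs([F.build_mol_graph(s) for s in ["CC", "CCO"]])
        out = model.forward([batch])["output"].data
        for t in range(2):
            sums = out[:, t * 4:(t + 1) * 4].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_binary_outputs_in_open_unit_interval(self):
        spec = TargetSpec("binary", n_tasks=3)
        model = PropertyModel(spec, EncoderConfig(hidden_size=16), seed=4)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        out = model.forward([batch])["output"].data
        assert np.all((out > 0) & (out < 1))

    def test_zero_weight_multiclass_head_is_uniform(self):
        spec = TargetSpec("multiclass", n_tasks=1, n_classes=3)
        model = PropertyModel(spec, EncoderConfig(hidden_size=16), seed=5)
        model.ffn.layers[-1].W.data[:] = 0.0
        model.ffn.layers[-1].b.data[:] = 0.0
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        out = model.forward([batch])["output"].data
        np.testing.assert_allclose(out, 1.0 / 3.0, atol=1e-12)

    def test_spectra_output_normalized_and_positive(self):
        spec = TargetSpec("spectra", n_bins=10)
        model = PropertyModel(spec, EncoderConfig(hidden_size=16), seed=6)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        out = model.forward([batch])["output"].data
        assert np.all(out > 0)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestMultimolecule:
    def _two_col_model(self, shared):
        spec = TargetSpec("regression", 1)
        return PropertyModel(spec, EncoderConfig(hidden_size=12),
                             n_molecule_columns=2, mpn_shared=shared, seed=7)

    def test_shared_encoder_identical_halves(self):
        model = self._two_col_model(shared=True)
        b = F.batch_graphs([F.build_mol_graph("CCO")])
        emb = model.embed([b, b]).data
        np.testing.assert_allclose(emb[:, :12], emb[:, 12:], atol=1e-12)

    def test_column_order_changes_output(self):
        model = self._two_col_model(shared=False)
        b1 = F.batch_graphs([F.build_mol_graph("CCO")])
        b2 = F.batch_graphs([F.build_mol_graph("c1ccccc1")])
        y12 = model.forward([b1, b2])["output"].data
        y21 = model.forward([b2, b1])["output"].data
        assert not np.allclose(y12, y21)

    def test_reaction_solvent_composes_single_paths(self):
        """CGR through its own encoder + molecule through another equals the
        two single-column embeddings concatenated."""
        rxn = F.build_cgr("[CH3:1][CH3:2]>>[CH4:1].[CH4:2]")
        solv = F.build_mol_graph("O")
        spec = TargetSpec("regression", 1)
        model = PropertyModel(
            spec, EncoderConfig(hidden_size=12), n_molecule_columns=2,
            column_widths=[(rxn.atom_fdim, rxn.bond_fdim),
                           (solv.atom_fdim, solv.bond_fdim)], seed=8)
        emb = model.embed([F.batch_graphs([rxn]), F.batch_graphs([solv])]).data
        _, _, m0 = model.encoders[0].forward(F.batch_graphs([rxn]))
        _, _, m1 = model.encoders[1].forward(F.batch_graphs([solv]))
        np.testing.assert_allclose(
            emb, np.concatenate([m0.data, m1.data], axis=1), atol=1e-12)

    def test_column_count_mismatch_raises(self):
        model = self._two_col_model(shared=False)
        b = F.batch_graphs([F.build_mol_graph("CC")])
        with pytest.raises(ValueError, match="columns"):
            model.forward([b])


class TestAtomBondHeads:
    def test_constrained_sums_match_exactly(self, small_molecules, rng):
        model = AtomBondModel(
            AtomBondTargets(atom_targets=["charge"],
                            constraints={"charge": True}),
            EncoderConfig(hidden_size=12), seed=9)
        graphs = [F.build_mol_graph(s) for s in small_molecules[:6]]
        batch = F.batch_graphs(graphs)
        c = rng.normal(size=len(graphs)) * 3.0
        out = model.forward(batch, {"charge": c})["charge"].data[:, 0]
        for i, (start, n) in enumerate(batch.scopes):
            assert abs(out[start:start + n].sum() - c[i]) < 1e-6

    def test_single_atom_constraint_is_exact_value(self):
        model = AtomBondModel(
            AtomBondTargets(atom_targets=["q"], constraints={"q": True}),
            EncoderConfig(hidden_size=8), seed=10)
        batch = F.batch_graphs([F.build_mol_graph("C")])
        out = model.forward(batch, {"q": np.array([2.5])})["q"].data
        assert out[0, 0] == pytest.approx(2.5, abs=1e-9)

    def test_unconstrained_equals_raw_head(self):
        model = AtomBondModel(AtomBondTargets(atom_targets=["q"]),
                              EncoderConfig(hidden_size=8), seed=11)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        out = model.forward(batch)["q"]
        _, atoms, _ = model.encoder.forward(batch)
        raw, _ = model.heads["q"].forward(atoms)
        np.testing.assert_allclose(out.data, raw.data, atol=1e-12)

    def test_bond_heads_symmetrized_count(self):
        model = AtomBondModel(AtomBondTargets(bond_targets=["order"]),
                              EncoderConfig(hidden_size=8), seed=12)
        batch = F.batch_graphs([F.build_mol_graph("c1ccccc1")])
        out = model.forward(batch)["order"].data
        assert out.shape == (6, 1)  # one prediction per undirected bond

    def test_missing_constraint_value_raises(self):
        model = AtomBondModel(
            AtomBondTargets(atom_targets=["q"], constraints={"q": True}),
            EncoderConfig(hidden_size=8), seed=13)
        batch = F.batch_graphs([F.build_mol_graph("CC")])
        with pytest.raises(ValueError, match="constraint"):
            model.forward(batch)


class TestLatents:
    def test_fingerprint_width_and_determinism(self):
        model = PropertyModel(TargetSpec("regression", 1),
                              EncoderConfig(hidden_size=20), seed=14)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        fp1 = model.extract_latents([batch])
        fp2 = model.extract_latents([batch])
        assert fp1.shape == (1, 20)
        np.testing.assert_array_equal(fp1, fp2)

    def test_ffn_embedding_width(self):
        model = PropertyModel(TargetSpec("regression", 1),
                              EncoderConfig(hidden_size=20),
                              ReadoutSpec(n_layers=2, hidden_size=33), seed=15)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        emb = model.extract_latents([batch], kind="ffn_embedding")
        assert emb.shape == (1, 33)

    def test_fixed_embedding_bypass_uses_features_verbatim(self):
        feats = np.arange(8.0).reshape(2, 4)
        model = PropertyModel(TargetSpec("regression", 1),
                              features_size=4, features_only=True, seed=16)
        fp = model.extract_latents([], features=feats)
        np.testing.assert_array_equal(fp, feats)
        out = model.forward([], features=feats)["output"]
        assert out.data.shape == (2, 1)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = PropertyModel(TargetSpec("binary", 2),
                              EncoderConfig(hidden_size=12), seed=17)
        batch = F.batch_graphs([F.build_mol_graph("CCO")])
        before = model.forward([batch])["output"].data
        path = str(tmp_path / "ckpt.npz")
        model.save(path, extra={"note": "test"})
        loaded, extra = PropertyModel.load(path)
        after = loaded.forward([batch])["output"].data
        np.testing.assert_array_equal(before, after)
        assert extra["note"] == "test"


class TestGradients:
    def test_finite_difference_every_learnable_tensor(self):
        """Analytic gradients match central differences on a 2-molecule
        batch (tanh activation, sampled entries per tensor)."""
        spec = TargetSpec("regression", 1)
        model = PropertyModel(
            spec, EncoderConfig(hidden_size=6, activation="tanh"),
            ReadoutSpec(n_layers=2, hidden_size=5), seed=18)
        batch = F.batch_graphs([F.build_mol_graph("CCO"),
                                F.build_mol_graph("CC")])
        y = np.array([[1.0], [2.0]])

        def loss_value():
            out = model.forward([batch])["output"]
            return ((out - Tensor(y)) ** 2).sum()

        loss = loss_value()
        loss.backward()
        grads = {k: v.grad.copy() for k, v in model.parameters().items()}
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, tensor in model.parameters().items():
            flat = tensor.data.reshape(-1)
            gflat = grads[name].reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                dn = float(loss_value().data)
                flat[idx] = orig
                fd = (up - dn) / (2 * eps)
                denom = max(abs(fd), abs(gflat[idx]), 1e-8)
                assert abs(fd - gflat[idx]) / denom < 1e-4, name
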