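"""Optimization contracts: schedule endpoints, standardization round trip,
splits, early stopping, determinism, transfer freezing, and the random
hyperparameter search."""

import numpy as np
import pytest

from dmpnn import fixtures as fx
from dmpnn.encoder import EncoderConfig, PropertyModel, ReadoutSpec, TargetSpec
from dmpnn.featurization import build_mol_graph
from dmpnn.training import (Adam, MoleculeDataset, Scaler, TrainConfig,
                            config_hash, hyperparameter_search, lr_at_step,
                            predict, read_trial_log, split_data, train,
                            transfer, train_atom_bond)


def regression_dataset(n=60, seed=0, sigma=0.1) -> MoleculeDataset:
    mols = fx.make_molecule_set(n, seed=seed)
    fx.make_targets(mols, "atom_count", sigma=sigma)
    graphs = [[build_mol_graph(s)] for s in mols.smiles]
    return MoleculeDataset(graphs=graphs,
                           targets=mols.targets["atom_count"][:, None],
                           spec=TargetSpec("regression", 1),
                           smiles=[[s] for s in mols.smiles])


def tiny_factory(hidden=32, depth=3, ffn_hidden=32):
    def factory(seed):
        return PropertyModel(TargetSpec("regression", 1),
                             EncoderConfig(hidden_size=hidden, depth=depth),
                             ReadoutSpec(n_layers=2, hidden_size=ffn_hidden),
                             seed=seed)
    return factory


class TestSchedule:
    def test_endpoints(self):
        cfg = TrainConfig()
        spe = 10
        total = cfg.epochs * spe
        warm = int(cfg.warmup_epochs * spe)
        assert lr_at_step(0, spe, cfg) == pytest.approx(1e-4)
        assert lr_at_step(warm, spe, cfg) == pytest.approx(1e-3)
        assert lr_at_step(total - 1, spe, cfg) == pytest.approx(1e-4)

    def test_continuity_at_warmup_boundary(self):
        cfg = TrainConfig()
        spe = 25
        warm = int(cfg.warmup_epochs * spe)
        gap = abs(lr_at_step(warm, spe, cfg) - lr_at_step(warm - 1, spe, cfg))
        assert gap <= (cfg.max_lr - cfg.init_lr) / warm + 1e-12

    def test_monotone_shape(self):
        cfg = TrainConfig(epochs=5)
        spe = 20
        lrs = [lr_at_step(s, spe, cfg) for s in range(cfg.epochs * spe)]
        warm = int(cfg.warmup_epochs * spe)
        assert all(a <= b + 1e-15 for a, b in zip(lrs[:warm], lrs[1:warm + 1]))
        assert all(a >= b - 1e-15 for a, b in zip(lrs[warm:], lrs[warm + 1:]))

    def test_invalid_endpoints_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(init_lr=1e-2, max_lr=1e-3)
        with pytest.raises(ValueError):
            TrainConfig(warmup_epochs=30, epochs=30)


class TestScaler:
    def test_round_trip_identity(self, rng):
        y = rng.normal(loc=5.0, scale=3.0, size=(40, 2))
        s = Scaler.fit(y)
        np.testing.assert_allclose(s.inverse(s.transform(y)), y, atol=1e-10)
        z = s.transform(y)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_serialization(self, rng):
        s = Scaler.fit(rng.normal(size=(20, 1)))
        s2 = Scaler.from_dict(s.to_dict())
        np.testing.assert_allclose(s2.means, s.means)


class TestSplits:
    def test_seed_reproducible_and_exhaustive(self):
        a = split_data(100, "random", (0.8, 0.1, 0.1), seed=5)
        b = split_data(100, "random", (0.8, 0.1, 0.1), seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert tuple(map(len, a)) == (80, 10, 10)
        allidx = np.sort(np.concatenate(a))
        np.testing.assert_array_equal(allidx, np.arange(100))

    def test_different_seeds_differ(self):
        a = split_data(100, "random", seed=1)[0]
        b = split_data(100, "random", seed=2)[0]
        assert not np.array_equal(a, b)

    def test_scaffold_split_keeps_scaffolds_together(self, small_molecules):
        from rdkit.Chem.Scaffolds import MurckoScaffold
        tr, va, te = split_data(small_molecules, "scaffold",
                                (0.6, 0.2, 0.2), seed=0)
        part = {}
        for name, idx in [("tr", tr), ("va", va), ("te", te)]:
            for i in idx:
                scaf = MurckoScaffold.MurckoScaffoldSmiles(
                    smiles=small_molecules[i])
                assert part.setdefault(scaf, name) == name

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_data(10, "random", (0.5, 0.2, 0.2))


class TestTrainLoop:
    def test_loss_decreases_over_first_epochs(self):
        """The trainer makes progress on the atom-count task for nearly
        every seed (19/20)."""
        ds = regression_dataset(50, seed=1)
        wins = 0
        for seed in range(20):
            cfg = TrainConfig(epochs=5, batch_size=25, seed=seed)
            res = train(ds, None, tiny_factory(hidden=24), cfg)
            tl = [h["train_loss"] for h in res.history]
            wins += tl[-1] < tl[0]
        assert wins >= 19

    def test_deterministic_under_fixed_seed(self):
        ds = regression_dataset(30, seed=2)
        cfg = TrainConfig(epochs=3, batch_size=16, seed=9)
        r1 = train(ds, None, tiny_factory(), cfg)
        r2 = train(ds, None, tiny_factory(), cfg)
        for (k, a), (_, b) in zip(r1.models[0].parameters().items(),
                                  r2.models[0].parameters().items()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_two_seeds_different_weights_same_config_hash(self):
        ds = regression_dataset(30, seed=2)
        cfg1 = TrainConfig(epochs=3, seed=1)
        cfg2 = TrainConfig(epochs=3, seed=1)
        r1 = train(ds, None, tiny_factory(), cfg1)
        r2 = train(ds, None, tiny_factory(), TrainConfig(epochs=3, seed=2))
        assert config_hash(cfg1) == config_hash(cfg2)
        w1 = r1.models[0].parameters()["mpnn0.W_i.W"].data
        w2 = r2.models[0].parameters()["mpnn0.W_i.W"].data
        assert not np.array_equal(w1, w2)

    def test_early_stopping_contract(self):
        """With a learning rate of ~zero the validation score never
        improves after the first epoch, so training stops after exactly
        patience+1 further epochs."""
        ds = regression_dataset(30, seed=3)
        cfg = TrainConfig(epochs=30, seed=0, patience=3,
                          init_lr=0.0, max_lr=0.0, final_lr=0.0)
        res = train(ds.subset(range(20)), ds.subset(range(20, 30)),
                    tiny_factory(), cfg)
        assert len(res.history) <= 1 + cfg.patience + 1

    def test_ensemble_prediction_is_member_mean(self):
        ds = regression_dataset(30, seed=4)
        cfg = TrainConfig(epochs=3, ensemble_size=2, seed=0)
        res = train(ds, None, tiny_factory(), cfg)
        full = predict(res.models, ds, res.scaler)
        singles = [predict(m, ds, res.scaler) for m in res.models]
        np.testing.assert_allclose(full, np.mean(singles, axis=0), atol=1e-12)
        assert not np.allclose(singles[0], singles[1])

    def test_predictions_in_original_units(self):
        ds = regression_dataset(80, seed=5, sigma=0.0)
        cfg = TrainConfig(epochs=25, batch_size=40, seed=0)
        res = train(ds, None, tiny_factory(hidden=48), cfg)
        preds = predict(res.models, ds, res.scaler)
        # targets are heavy-atom counts in [1, 12]; predictions must live
        # on that scale, not the standardized one
        assert 1.0 <= preds.mean() <= 12.0
        assert np.corrcoef(preds.ravel(), ds.targets.ravel())[0, 1] > 0.9

    def test_empty_split_rejected(self):
        ds = regression_dataset(10, seed=6)
        with pytest.raises(ValueError, match="empty"):
            train(ds.subset([]), None, tiny_factory(), TrainConfig(epochs=3))

    def test_nonfinite_loss_aborts_with_diagnostic(self):
        ds = regression_dataset(10, seed=7)
        ds.targets[0, 0] = np.inf
        with pytest.raises(RuntimeError, match="non-finite"):
            train(ds, None, tiny_factory(), TrainConfig(epochs=3))

    def test_run_dir_artifacts(self, tmp_path):
        ds = regression_dataset(20, seed=8)
        run = tmp_path / "run"
        train(ds.subset(range(15)), ds.subset(range(15, 20)),
              tiny_factory(), TrainConfig(epochs=3), run_dir=str(run))
        assert (run / "model_0.npz").exists()
        assert (run / "metrics.tsv").exists()
        assert (run / "manifest.json").exists()


class TestTransfer:
    def _pretrain(self, tmp_path, epochs=3):
        ds = regression_dataset(30, seed=9)
        res = train(ds, None, tiny_factory(), TrainConfig(epochs=epochs))
        path = str(tmp_path / "pre.npz")
        res.models[0].save(path, extra={"scaler": res.scaler.to_dict()})
        return ds, path

    def test_frozen_mpnn_bit_identical(self, tmp_path):
        ds, path = self._pretrain(tmp_path)
        model, cfg, scaler = transfer(path, freeze="mpnn",
                                      config=TrainConfig(epochs=3))
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        train(ds, None, config=cfg, models=[model])
        after = model.parameters()
        for k in before:
            if k.startswith("mpnn"):
                np.testing.assert_array_equal(before[k], after[k].data)
            else:
                assert not np.array_equal(before[k], after[k].data), k

    def test_freeze_all_but_last_ffn_layer(self, tmp_path):
        ds, path = self._pretrain(tmp_path)
        model, cfg, _ = transfer(path, freeze="mpnn+ffn", freeze_ffn_layers=1,
                                 config=TrainConfig(epochs=3))
        before = {k: v.data.copy() for k, v in model.parameters().items()}
        train(ds, None, config=cfg, models=[model])
        for k, v in model.parameters().items():
            if k.startswith("mpnn") or k.startswith("ffn.0"):
                np.testing.assert_array_equal(before[k], v.data)
            else:
                assert not np.array_equal(before[k], v.data), k

    def test_warm_start_continuity(self, tmp_path):
        """Resuming from a converged checkpoint starts near its final
        loss, far below a fresh model's first-epoch loss."""
        ds = regression_dataset(40, seed=10)
        res = train(ds, None, tiny_factory(), TrainConfig(epochs=25))
        path = str(tmp_path / "pre.npz")
        res.models[0].save(path, extra={"scaler": res.scaler.to_dict()})
        model, cfg, _ = transfer(path, freeze=None,
                                 config=TrainConfig(epochs=1, warmup_epochs=0.5))
        warm = train(ds, None, config=cfg, models=[model])
        fresh = train(ds, None, tiny_factory(),
                      TrainConfig(epochs=1, warmup_epochs=0.5, seed=99))
        assert warm.history[0]["train_loss"] < fresh.history[0]["train_loss"]

    def test_incompatible_checkpoint_rejected(self, tmp_path):
        _, path = self._pretrain(tmp_path)
        model, _ = PropertyModel.load(path)
        other = PropertyModel(TargetSpec("regression", 1),
                              EncoderConfig(hidden_size=16), seed=0)
        other.save(str(tmp_path / "other.npz"))
        import json
        import numpy as _np
        with _np.load(str(tmp_path / "other.npz")) as d:
            meta = json.loads(str(d["__meta__"]))
            arrays = {k: d[k] for k in d.files if k != "__meta__"}
        meta["config"]["encoder_config"]["hidden_size"] = 32
        _np.savez(str(tmp_path / "bad.npz"),
                  __meta__=_np.array(json.dumps(meta)), **arrays)
        with pytest.raises(ValueError, match="incompatib"):
            PropertyModel.load(str(tmp_path / "bad.npz"))


class TestHyperparameterSearch:
    def test_single_trial_returned(self):
        best, log = hyperparameter_search(
            {"depth": [2, 3]}, lambda p: p["depth"], n_trials=1, seed=0)
        assert best in log and len(log) == 1

    def test_best_of_log_monotone(self):
        space = {"x": list(range(10))}
        scores = []
        for n in (1, 3, 6, 10):
            best, _ = hyperparameter_search(space, lambda p: p["x"],
                                            n_trials=n, seed=4)
            scores.append(best["score"])
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_parallel_append_log(self, tmp_path):
        log = str(tmp_path / "trials.jsonl")
        hyperparameter_search({"x": [1, 2]}, lambda p: p["x"], 4, seed=0,
                              log_path=log)
        hyperparameter_search({"x": [1, 2]}, lambda p: p["x"], 3, seed=1,
                              log_path=log)
        records = read_trial_log(log)
        assert len(records) == 7
        assert all("score" in r for r in records)

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            hyperparameter_search({}, lambda p: 0.0, 1)

    def test_pluggable_sampler_consulted(self):
        calls = []

        def sampler(space, trials, rng):
            calls.append(len(trials))
            return {"x": 0}

        hyperparameter_search({"x": [0, 1]}, lambda p: p["x"], 3, seed=0,
                              sampler=sampler)
        assert calls == [1, 2]


class TestAtomBondTraining:
    def test_constrained_degree_training_improves(self):
        from dmpnn.encoder import AtomBondModel, AtomBondTargets
        mols = fx.make_molecule_set(40, seed=12)
        fx.make_targets(mols, "per_atom_degree")
        graphs = [build_mol_graph(s) for s in mols.smiles]
        model = AtomBondModel(
            AtomBondTargets(atom_targets=["degree"],
                            constraints={"degree": True}),
            EncoderConfig(hidden_size=24), seed=0)
        cons = {"degree": mols.targets["per_atom_degree_constraint"]}
        log = train_atom_bond(model, graphs,
                              {"degree": mols.targets["per_atom_degree"]},
                              constraints=cons,
                              config=TrainConfig(epochs=8, batch_size=20))
        assert log[-1] < log[0]


class TestCrossValidation:
    def test_folds_resplit_independently(self):
        from dmpnn.training import cross_validate
        ds = regression_dataset(40, seed=13)
        cfg = TrainConfig(epochs=3, folds=2, seed=0)
        results = cross_validate(ds, tiny_factory(), cfg)
        assert len(results) == 2
        assert all(np.isfinite(r.best_val) for r in results)
        assert results[0].best_val != results[1].best_val
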