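"""The directed message-passing encoder and readout networks.

The encoder maps a featurized directed graph to atomic and molecular
embeddings:

1. every directed edge state is initialized as ``h0_vw = tau(W_i @ e_vw)``
   where ``e_vw = cat(x_v, bond features)``;
2. states are refined by message passing in which edge ``v -> w`` sums the
   states of edges incoming to ``v`` *excluding its own reverse twin*
   ``w -> v``, then ``h_{t+1} = tau(h0 + W_h @ message)`` (a skip connection
   to the initial state at every step);
3. per-atom embeddings are ``h_v = tau(W_o @ cat(x_v, sum of incoming edge
   states))``;
4. molecular embeddings aggregate atoms by mean (default), sum, or a
   sum scaled by a fixed norm.

Depth ``T`` counts the initialization as the first step, so ``T - 1``
refinement updates are applied.  MPNN layers carry no bias by default;
feed-forward readout layers do.  Readout activation depends on the task:
identity for regression, sigmoid for binary targets, per-task softmax for
multiclass, and a positive activation followed by normalization for
spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat
from .featurization import ATOM_FDIM, BOND_FDIM, BatchedGraph

ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "leakyrelu": lambda t: t.leaky_relu(),
    "tanh": lambda t: t.tanh(),
}

AGGREGATIONS = ("mean", "sum", "norm")

_VAR_FLOOR = 1e-8


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear:
    """Dense layer ``y = x @ W (+ b)`` with named learnable tensors."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 bias: bool = True, name: str = "linear"):
        self.name = name
        self.W = Tensor(xavier_uniform(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def parameters(self) -> dict[str, Tensor]:
        out = {f"{self.name}.W": self.W}
        if self.b is not None:
            out[f"{self.name}.b"] = self.b
        return out


# ---------------------------------------------------------------------------
@dataclass
class EncoderConfig:
    hidden_size: int = 300
    depth: int = 3
    activation: str = "relu"
    bias: bool = False
    aggregation: str = "mean"
    norm_scaler: float = 100.0
    dropout: float = 0.0
    atom_fdim: int = ATOM_FDIM
    bond_fdim: int = BOND_FDIM

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("message-passing depth must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


class MPNNEncoder:
    """Directed-edge message passing producing atomic and molecular embeddings."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator,
                 name: str = "mpnn"):
        self.config = config
        self.name = name
        h = config.hidden_size
        edge_fdim = config.atom_fdim + config.bond_fdim
        self.W_i = Linear(rng, edge_fdim, h, bias=config.bias, name=f"{name}.W_i")
        self.W_h = Linear(rng, h, h, bias=config.bias, name=f"{name}.W_h")
        self.W_o = Linear(rng, config.atom_fdim + h, h, bias=config.bias,
                          name=f"{name}.W_o")

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for layer in (self.W_i, self.W_h, self.W_o):
            out.update(layer.parameters())
        return out

    # -- stages ---------------------------------------------------------
    def init_edge_states(self, batch: BatchedGraph) -> Tensor:
        if batch.edge_fdim != self.config.atom_fdim + self.config.bond_fdim:
            raise ValueError(
                f"edge feature width {batch.edge_fdim} does not match encoder "
                f"input width {self.config.atom_fdim + self.config.bond_fdim}")
        act = ACTIVATIONS[self.config.activation]
        return act(self.W_i(Tensor(batch.edge_features)))

    def message_pass(self, batch: BatchedGraph, h0: Tensor, h: Tensor,
                     rng: np.random.Generator | None = None) -> Tensor:
        """One update: sum incoming states excluding the reverse twin."""
        act = ACTIVATIONS[self.config.activation]
        atom_sums = h.segment_sum(batch.dst, batch.n_atoms)
        msg = atom_sums.gather_rows(batch.src) - h.gather_rows(batch.rev_index)
        out = act(h0 + self.W_h(msg))
        return out.dropout(self.config.dropout, rng)

    def atom_embed(self, batch: BatchedGraph, h_edges: Tensor,
                   rng: np.random.Generator | None = None) -> Tensor:
        act = ACTIVATIONS[self.config.activation]
        incoming = h_edges.segment_sum(batch.dst, batch.n_atoms)
        q = concat([Tensor(batch.atom_features), incoming], axis=1)
        return act(self.W_o(q)).dropout(self.config.dropout, rng)

    def aggregate(self, atom_embeds: Tensor, batch: BatchedGraph) -> Tensor:
        mol_index = np.zeros(batch.n_atoms, dtype=np.intp)
        counts = np.empty(batch.n_mols)
        for i, (start, n) in enumerate(batch.scopes):
            if n == 0:
                raise ValueError("cannot aggregate an empty molecule")
            mol_index[start:start + n] = i
            counts[i] = n
        sums = atom_embeds.segment_sum(mol_index, batch.n_mols)
        mode = self.config.aggregation
        if mode == "sum":
            return sums
        if mode == "norm":
            return sums * (1.0 / self.config.norm_scaler)
        return sums * Tensor(1.0 / counts[:, None])

    def forward(self, batch: BatchedGraph,
                rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Return (edge states h^T, atomic embeddings h_v, molecular h_m)."""
        if batch.n_edges:
            h0 = self.init_edge_states(batch)
            h = h0.dropout(self.config.dropout, rng)
            for _ in range(self.config.depth - 1):
                h = self.message_pass(batch, h0, h, rng)
        else:  # batch of isolated atoms: no edges to pass messages along
            h = Tensor(np.zeros((0, self.config.hidden_size)))
        atoms = self.atom_embed(batch, h, rng)
        mols = self.aggregate(atoms, batch)
        return h, atoms, mols


# ---------------------------------------------------------------------------
@dataclass
class ReadoutSpec:
    """Shape and activation of the feed-forward readout network."""

    n_layers: int = 2
    hidden_size: int = 300
    output_size: int = 1
    dropout: float = 0.0
    activation: str = "relu"


class FFN:
    """Feed-forward readout; ``n_layers`` linear layers, bias on, dropout
    after each hidden activation.  ``n_layers=1`` is a single linear map."""

    def __init__(self, spec: ReadoutSpec, n_in: int, rng: np.random.Generator,
                 name: str = "ffn"):
        self.spec = spec
        self.name = name
        self.layers: list[Linear] = []
        sizes = [n_in] + [spec.hidden_size] * (spec.n_layers - 1) + [spec.output_size]
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            self.layers.append(Linear(rng, a, b, bias=True, name=f"{name}.{i}"))

    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for layer in self.layers:
            out.update(layer.parameters())
        return out

    def forward(self, x: Tensor, rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        """Return (final linear output, last hidden activation)."""
        act = ACTIVATIONS[self.spec.activation]
        hidden = x
        for layer in self.layers[:-1]:
            hidden = act(layer(hidden)).dropout(self.spec.dropout, rng)
        return self.layers[-1](hidden), hidden


# ---------------------------------------------------------------------------
TASK_TYPES = ("regression", "binary", "multiclass", "spectra")
REGRESSION_LOSSES = ("mse", "bounded_mse", "mve", "evidential")
BINARY_LOSSES = ("bce", "mcc", "dirichlet")
MULTICLASS_LOSSES = ("cross_entropy", "mcc")
SPECTRA_LOSSES = ("sid", "wasserstein")


@dataclass
class TargetSpec:
    """What the model predicts and which loss trains it."""

    task: str = "regression"
    n_tasks: int = 1
    loss: str | None = None
    n_classes: int = 3          # multiclass only
    n_bins: int = 0             # spectra only

    def __post_init__(self):
        if self.task not in TASK_TYPES:
            raise ValueError(f"unknown task {self.task!r}")
        defaults = {"regression": "mse", "binary": "bce",
                    "multiclass": "cross_entropy", "spectra": "sid"}
        if self.loss is None:
            self.loss = defaults[self.task]
        allowed = {"regression": REGRESSION_LOSSES, "binary": BINARY_LOSSES,
                   "multiclass": MULTICLASS_LOSSES, "spectra": SPECTRA_LOSSES}
        if self.loss not in allowed[self.task]:
            raise ValueError(
                f"loss {self.loss!r} is not valid for task {self.task!r}")
        if self.task == "spectra" and self.n_bins < 2:
            raise ValueError("spectra task needs n_bins >= 2")

    @property
    def raw_output_size(self) -> int:
        if self.task == "regression":
            return self.n_tasks * {"mse": 1, "bounded_mse": 1,
                                   "mve": 2, "evidential": 4}[self.loss]
        if self.task == "binary":
            return self.n_tasks * (2 if self.loss == "dirichlet" else 1)
        if self.task == "multiclass":
            return self.n_tasks * self.n_classes
        return self.n_bins


# ---------------------------------------------------------------------------
class PropertyModel:
    """Molecule-level property model: one or more encoders plus one FFN.

    With several molecule columns (e.g. solute + solvent) each column gets
    its own encoder unless ``mpn_shared``; embeddings are concatenated in
    column order before the readout, so column order matters by design.
    A reaction column runs its (wider) CGR features through its own
    encoder.  ``features_only`` bypasses the graph encoders entirely and
    feeds the supplied molecule-level feature vector to the FFN.
    """

    def __init__(self, spec: TargetSpec,
                 encoder_config: EncoderConfig | None = None,
                 readout: ReadoutSpec | None = None,
                 n_molecule_columns: int = 1,
                 column_widths: list[tuple[int, int]] | None = None,
                 mpn_shared: bool = False,
                 features_size: int = 0,
                 features_only: bool = False,
                 seed: int = 0):
        if features_only and features_size == 0:
            raise ValueError("features_only requires molecule-level features")
        if mpn_shared and n_molecule_columns < 2:
            raise ValueError("mpn_shared requires at least two molecule columns")
        self.spec = spec
        self.encoder_config = encoder_config or EncoderConfig()
        self.n_molecule_columns = n_molecule_columns
        self.mpn_shared = mpn_shared
        self.features_size = features_size
        self.features_only = features_only
        self.seed = seed
        rng = np.random.default_rng(seed)

        if column_widths is None:
            column_widths = [(self.encoder_config.atom_fdim,
                              self.encoder_config.bond_fdim)] * n_molecule_columns
        if len(column_widths) != n_molecule_columns:
            raise ValueError("one (atom, bond) width pair per molecule column")
        self.column_widths = column_widths
        if mpn_shared and len(set(column_widths)) != 1:
            raise ValueError("mpn_shared requires identical feature widths")

        self.encoders: list[MPNNEncoder] = []
        if not features_only:
            n_enc = 1 if mpn_shared else n_molecule_columns
            for i in range(n_enc):
                cfg_i = EncoderConfig(**{**asdict(self.encoder_config),
                                         "atom_fdim": column_widths[i][0],
                                         "bond_fdim": column_widths[i][1]})
                self.encoders.append(MPNNEncoder(cfg_i, rng, name=f"mpnn{i}"))

        embed_size = (0 if features_only
                      else self.encoder_config.hidden_size * n_molecule_columns)
        embed_size += features_size
        self.readout_spec = readout or ReadoutSpec()
        self.readout_spec.output_size = spec.raw_output_size
        self.readout_spec.activation = self.encoder_config.activation
        self.ffn = FFN(self.readout_spec, embed_size, rng)

    # ------------------------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        out = {}
        for enc in self.encoders:
            out.update(enc.parameters())
        out.update(self.ffn.parameters())
        return out

    def encoder_for_column(self, i: int) -> MPNNEncoder:
        return self.encoders[0] if self.mpn_shared else self.encoders[i]

    def embed(self, batches: list[BatchedGraph],
              features: np.ndarray | None = None,
              rng: np.random.Generator | None = None) -> Tensor:
        """The learned fingerprint: concatenated molecular embeddings (+x_m)."""
        parts: list[Tensor] = []
        if not self.features_only:
            if len(batches) != self.n_molecule_columns:
                raise ValueError(
                    f"expected {self.n_molecule_columns} molecule columns, "
                    f"got {len(batches)}")
            for i, batch in enumerate(batches):
                _, _, mols = self.encoder_for_column(i).forward(batch, rng)
                parts.append(mols)
        if self.features_size:
            if features is None:
                raise ValueError("model was built with molecule-level features")
            parts.append(Tensor(np.atleast_2d(features)))
        return concat(parts, axis=1) if len(parts) > 1 else parts[0]

    def forward(self, batches: list[BatchedGraph],
                features: np.ndarray | None = None,
                rng: np.random.Generator | None = None,
                spectra_mask: np.ndarray | None = None) -> dict[str, Tensor]:
        embedding = self.embed(batches, features, rng)
        raw, ffn_hidden = self.ffn.forward(embedding, rng)
        return {
            "embedding": embedding,
            "ffn_hidden": ffn_hidden,
            "raw": raw,
            "output": self.apply_output_activation(raw, spectra_mask),
        }

    def apply_output_activation(self, raw: Tensor,
                                spectra_mask: np.ndarray | None = None) -> Tensor:
        spec = self.spec
        if spec.task == "regression":
            if spec.loss == "mve":
                n = spec.n_tasks
                mean = raw[:, :n]
                var = raw[:, n:].softplus() + _VAR_FLOOR
                return concat([mean, var], axis=1)
            if spec.loss == "evidential":
                n = spec.n_tasks
                gamma = raw[:, :n]
                nu = raw[:, n:2 * n].softplus() + _VAR_FLOOR
                alpha = raw[:, 2 * n:3 * n].softplus() + 1.0 + _VAR_FLOOR
                beta = raw[:, 3 * n:].softplus() + _VAR_FLOOR
                return concat([gamma, nu, alpha, beta], axis=1)
            return raw
        if spec.task == "binary":
            if spec.loss == "dirichlet":
                return raw.softplus() + 1.0  # two Dirichlet concentrations/task
            return raw.sigmoid()
        if spec.task == "multiclass":
            n, c = spec.n_tasks, spec.n_classes
            blocks = [raw[:, i * c:(i + 1) * c].softmax(axis=1) for i in range(n)]
            return concat(blocks, axis=1) if n > 1 else blocks[0]
        # spectra: positive then normalized to unit sum over valid bins
        pos = raw.softplus() + _VAR_FLOOR
        if spectra_mask is not None:
            pos = pos * Tensor(np.asarray(spectra_mask, dtype=np.float64))
        return pos / pos.sum(axis=1, keepdims=True)

    # -- latents --------------------------------------------------------
    def extract_latents(self, batches: list[BatchedGraph],
                        features: np.ndarray | None = None,
                        kind: str = "fingerprint") -> np.ndarray:
        """Latent representations: post-aggregation ``fingerprint`` (width
        h x n_columns + |x_m|) or last-hidden ``ffn_embedding``."""
        if kind == "fingerprint":
            return self.embed(batches, features).data.copy()
        if kind == "ffn_embedding":
            out = self.forward(batches, features)
            return out["ffn_hidden"].data.copy()
        raise ValueError(f"unknown latent kind {kind!r}")

    # -- persistence ----------------------------------------------------
    def config_dict(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "encoder_config": asdict(self.encoder_config),
            "readout": asdict(self.readout_spec),
            "n_molecule_columns": self.n_molecule_columns,
            "column_widths": [list(w) for w in self.column_widths],
            "mpn_shared": self.mpn_shared,
            "features_size": self.features_size,
            "features_only": self.features_only,
            "seed": self.seed,
            "format_version": 1,
        }

    def save(self, path: str, extra: dict | None = None) -> None:
        arrays = {k: v.data for k, v in self.parameters().items()}
        meta = {"config": self.config_dict(), "extra": extra or {}}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> tuple["PropertyModel", dict]:
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz",
                     allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            model = cls(
                spec=TargetSpec(**cfg["spec"]),
                encoder_config=EncoderConfig(**cfg["encoder_config"]),
                readout=ReadoutSpec(**cfg["readout"]),
                n_molecule_columns=cfg["n_molecule_columns"],
                column_widths=[tuple(w) for w in cfg["column_widths"]],
                mpn_shared=cfg["mpn_shared"],
                features_size=cfg["features_size"],
                features_only=cfg["features_only"],
                seed=cfg["seed"],
            )
            params = model.parameters()
            for name, tensor in params.items():
                stored = data[name]
                if stored.shape != tensor.data.shape:
                    raise ValueError(
                        f"checkpoint incompatibility: {name} has shape "
                        f"{stored.shape}, model expects {tensor.data.shape}")
                tensor.data = stored.astype(np.float64)
        return model, meta["extra"]


# ---------------------------------------------------------------------------
@dataclass
class AtomBondTargets:
    """Declaration of per-atom / per-bond properties to predict."""

    atom_targets: list[str] = field(default_factory=list)
    bond_targets: list[str] = field(default_factory=list)
    constraints: dict[str, bool] = field(default_factory=dict)  # name -> constrained


class AtomBondModel:
    """Multitask atom/bond-level model: one shared encoder, one FFN per
    property (properties do not share readouts), and an optional
    attention-based constraint that redistributes the residual between the
    raw per-atom sum and a supplied molecular net value so the predictions
    sum to that value exactly."""

    def __init__(self, targets: AtomBondTargets,
                 encoder_config: EncoderConfig | None = None,
                 readout: ReadoutSpec | None = None,
                 seed: int = 0):
        if not targets.atom_targets and not targets.bond_targets:
            raise ValueError("declare at least one atom or bond target")
        self.targets = targets
        self.encoder_config = encoder_config or EncoderConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.encoder = MPNNEncoder(self.encoder_config, rng)
        base = readout or ReadoutSpec()
        h = self.encoder_config.hidden_size
        self.heads: dict[str, FFN] = {}
        self.attn_heads: dict[str, Linear] = {}
        for name in targets.atom_targets + targets.bond_targets:
            spec = ReadoutSpec(n_layers=base.n_layers, hidden_size=base.hidden_size,
                               output_size=1, dropout=base.dropout,
                               activation=self.encoder_config.activation)
            self.heads[name] = FFN(spec, h, rng, name=f"head.{name}")
            if targets.constraints.get(name, False):
                self.attn_heads[name] = Linear(rng, h, 1, name=f"attn.{name}")

    def parameters(self) -> dict[str, Tensor]:
        out = self.encoder.parameters()
        for head in self.heads.values():
            out.update(head.parameters())
        for lin in self.attn_heads.values():
            out.update(lin.parameters())
        return out

    @staticmethod
    def _segment_softmax(scores: Tensor, index: np.ndarray, n_seg: int) -> Tensor:
        shift = np.zeros(n_seg)
        np.maximum.at(shift, index, scores.data[:, 0])
        e = (scores - Tensor(shift[index][:, None])).exp()
        denom = e.segment_sum(index, n_seg)
        return e / denom.gather_rows(index)

    def _constrain(self, raw: Tensor, scores: Tensor, index: np.ndarray,
                   n_seg: int, constraint: np.ndarray) -> Tensor:
        weights = self._segment_softmax(scores, index, n_seg)
        raw_sums = raw.segment_sum(index, n_seg)
        residual = Tensor(np.asarray(constraint, dtype=np.float64)[:, None]) - raw_sums
        return raw + weights * residual.gather_rows(index)

    def forward(self, batch: BatchedGraph,
                constraints: dict[str, np.ndarray] | None = None,
                rng: np.random.Generator | None = None) -> dict[str, Tensor]:
        """Per-atom/bond predictions keyed by property name.

        ``constraints[name]`` gives one molecular net value per molecule in
        the batch; the per-entity outputs of a constrained property then
        sum to that value exactly.  Bond states are symmetrized sums of the
        two directed edge states.
        """
        constraints = constraints or {}
        for name in constraints:
            if name not in self.attn_heads:
                raise ValueError(
                    f"property {name!r} was not configured as constrained")
        for name, lin in self.attn_heads.items():
            if name not in constraints:
                raise ValueError(
                    f"constrained property {name!r} needs a constraint value")
        h_edges, atoms, _ = self.encoder.forward(batch, rng)

        atom_mol = np.zeros(batch.n_atoms, dtype=np.intp)
        for i, (start, n) in enumerate(batch.scopes):
            atom_mol[start:start + n] = i

        out: dict[str, Tensor] = {}
        for name in self.targets.atom_targets:
            raw, _ = self.heads[name].forward(atoms, rng)
            if name in constraints:
                scores = self.attn_heads[name](atoms)
                raw = self._constrain(raw, scores, atom_mol, batch.n_mols,
                                      constraints[name])
            out[name] = raw

        if self.targets.bond_targets:
            fwd = np.flatnonzero(np.arange(batch.n_edges) < batch.rev_index)
            bond_states = h_edges.gather_rows(fwd) + h_edges.gather_rows(
                batch.rev_index[fwd])
            bond_mol = atom_mol[batch.src[fwd]]
            for name in self.targets.bond_targets:
                raw, _ = self.heads[name].forward(bond_states, rng)
                if name in constraints:
                    scores = self.attn_heads[name](bond_states)
                    raw = self._constrain(raw, scores, bond_mol, batch.n_mols,
                                          constraints[name])
                out[name] = raw
        return out
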