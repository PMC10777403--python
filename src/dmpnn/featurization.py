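"""SMILES / reaction-SMILES featurization into directed molecular graphs.

A molecule is represented as a directed multigraph over its heavy atoms:
every bond contributes two directed edges, one per direction.  Atom feature
vectors are ordered blocks of one-hot encodings (atomic number, degree,
formal charge, chirality tag, hydrogen count, hybridization) followed by an
aromaticity bit and the atomic mass divided by 100.  Bond feature vectors
carry a leading null-bond bit (used by condensed reaction graphs for bonds
present on only one side), a bond-type one-hot, conjugation and ring bits,
and a stereo-tag one-hot.  Each one-hot block ends with an "other" slot so
out-of-vocabulary values never raise.

Directed-edge features are the concatenation of the source atom's feature
vector with the undirected bond features, so the two directed twins of a
bond differ only in which endpoint contributes the atom block.

Reactions are supplied as atom-mapped ``reactants>>products`` SMILES and
condensed into a single pseudomolecule (the condensed graph of reaction,
CGR): the vertex and edge sets are the unions over both sides, and features
combine the reactant-side and product-side encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# ---------------------------------------------------------------------------
# one-hot vocabularies; each block gains one trailing "other" slot
ATOM_FEATURES = {
    "atomic_num": list(range(1, 101)),
    "degree": [0, 1, 2, 3, 4, 5],
    "formal_charge": [-2, -1, 0, 1, 2],
    "chiral_tag": [0, 1, 2, 3],
    "num_Hs": [0, 1, 2, 3, 4],
    "hybridization": [
        Chem.rdchem.HybridizationType.SP,
        Chem.rdchem.HybridizationType.SP2,
        Chem.rdchem.HybridizationType.SP3,
        Chem.rdchem.HybridizationType.SP3D,
        Chem.rdchem.HybridizationType.SP3D2,
    ],
}

BOND_TYPES = [
    Chem.rdchem.BondType.SINGLE,
    Chem.rdchem.BondType.DOUBLE,
    Chem.rdchem.BondType.TRIPLE,
    Chem.rdchem.BondType.AROMATIC,
]
N_STEREO = 6  # rdkit BondStereo values 0..5

ATOM_FDIM = sum(len(v) + 1 for v in ATOM_FEATURES.values()) + 2  # +aromatic +mass
BOND_FDIM = 1 + (len(BOND_TYPES) + 1) + 2 + (N_STEREO + 1)  # null bit first

REACTION_SEPARATORS = ("≫", ">>")

CGR_MODES = ("reac_diff", "prod_diff", "reac_prod")


def _onehot(value, choices) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # "other" slot
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Feature vector for one RDKit atom (length ``ATOM_FDIM``)."""
    feats = (
        _onehot(atom.GetAtomicNum(), ATOM_FEATURES["atomic_num"])
        + _onehot(atom.GetTotalDegree(), ATOM_FEATURES["degree"])
        + _onehot(atom.GetFormalCharge(), ATOM_FEATURES["formal_charge"])
        + _onehot(int(atom.GetChiralTag()), ATOM_FEATURES["chiral_tag"])
        + _onehot(atom.GetTotalNumHs(), ATOM_FEATURES["num_Hs"])
        + _onehot(atom.GetHybridization(), ATOM_FEATURES["hybridization"])
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + [atom.GetMass() / 100.0]
    )
    return np.array(feats, dtype=np.float64)


def featurize_bond(bond: Chem.Bond | None) -> np.ndarray:
    """Feature vector for one RDKit bond; ``None`` yields the null-bond code."""
    if bond is None:
        vec = np.zeros(BOND_FDIM, dtype=np.float64)
        vec[0] = 1.0
        return vec
    feats = (
        [0.0]
        + _onehot(bond.GetBondType(), BOND_TYPES)
        + [1.0 if bond.GetIsConjugated() else 0.0,
           1.0 if bond.IsInRing() else 0.0]
        + _onehot(int(bond.GetStereo()), list(range(N_STEREO)))
    )
    return np.array(feats, dtype=np.float64)


# ---------------------------------------------------------------------------
@dataclass
class MolGraph:
    """Featurized directed multigraph of one molecule or one CGR.

    ``edge_features[k]`` is ``cat(atom_features[src[k]], bond_features)``:
    atom-block first, bond-block second.  ``rev_index`` maps each directed
    edge to its opposite-facing twin and is an involution.  ``incoming[v]``
    lists the directed edges whose target is ``v``.
    """

    n_atoms: int
    atom_features: np.ndarray          # (n_atoms, atom_fdim)
    src: np.ndarray                    # (n_edges,) source atom of each edge
    dst: np.ndarray                    # (n_edges,) target atom
    edge_features: np.ndarray          # (n_edges, atom_fdim + bond_fdim)
    rev_index: np.ndarray              # (n_edges,)
    atom_fdim: int
    bond_fdim: int
    smiles: str = ""
    scopes: list[tuple[int, int]] = field(default_factory=list)  # batching

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def edge_fdim(self) -> int:
        return self.atom_fdim + self.bond_fdim

    @property
    def incoming(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.dst == v) for v in range(self.n_atoms)]

    def validate(self) -> None:
        assert self.edge_features.shape == (self.n_edges, self.edge_fdim)
        if self.n_edges:
            rr = self.rev_index[self.rev_index]
            assert np.array_equal(rr, np.arange(self.n_edges))
            assert not np.any(self.rev_index == np.arange(self.n_edges))


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _graph_from_arrays(atom_feats: np.ndarray, bonds: list[tuple[int, int]],
                       bond_feats: list[np.ndarray], smiles: str = "") -> MolGraph:
    n_atoms = atom_feats.shape[0]
    atom_fdim = atom_feats.shape[1]
    bond_fdim = bond_feats[0].shape[0] if bond_feats else BOND_FDIM
    src, dst, efeats, rev = [], [], [], []
    for (a, b), bf in zip(bonds, bond_feats):
        k = len(src)
        src += [a, b]
        dst += [b, a]
        efeats.append(np.concatenate([atom_feats[a], bf]))
        efeats.append(np.concatenate([atom_feats[b], bf]))
        rev += [k + 1, k]
    g = MolGraph(
        n_atoms=n_atoms,
        atom_features=atom_feats,
        src=np.array(src, dtype=np.intp),
        dst=np.array(dst, dtype=np.intp),
        edge_features=(np.array(efeats) if efeats
                       else np.zeros((0, atom_fdim + bond_fdim))),
        rev_index=np.array(rev, dtype=np.intp),
        atom_fdim=atom_fdim,
        bond_fdim=bond_fdim,
        smiles=smiles,
        scopes=[(0, n_atoms)],
    )
    g.validate()
    return g


def build_mol_graph(smiles: str,
                    extra_atom_feats: np.ndarray | None = None,
                    extra_bond_feats: np.ndarray | None = None,
                    replace_defaults: bool = False) -> MolGraph:
    """Featurize one molecule SMILES into a :class:`MolGraph`.

    Extra per-atom / per-bond features are appended to (or, with
    ``replace_defaults``, substituted for) the default blocks; row counts
    must match the heavy-atom and bond counts.
    """
    mol = parse_smiles(smiles)
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        raise ValueError(f"no heavy atoms in SMILES: {smiles!r}")
    atom_feats = np.stack([featurize_atom(a) for a in mol.GetAtoms()])
    if extra_atom_feats is not None:
        extra_atom_feats = np.atleast_2d(np.asarray(extra_atom_feats, dtype=np.float64))
        if extra_atom_feats.shape[0] != n_atoms:
            raise ValueError(
                f"extra atom features have {extra_atom_feats.shape[0]} rows "
                f"but molecule {smiles!r} has {n_atoms} atoms")
        atom_feats = (extra_atom_feats if replace_defaults
                      else np.hstack([atom_feats, extra_atom_feats]))

    bonds, bond_feats = [], []
    for bond in mol.GetBonds():
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bond_feats.append(featurize_bond(bond))
    if extra_bond_feats is not None:
        extra_bond_feats = np.atleast_2d(np.asarray(extra_bond_feats, dtype=np.float64))
        if extra_bond_feats.shape[0] != len(bonds):
            raise ValueError(
                f"extra bond features have {extra_bond_feats.shape[0]} rows "
                f"but molecule {smiles!r} has {len(bonds)} bonds")
        bond_feats = [
            (eb if replace_defaults else np.concatenate([bf, eb]))
            for bf, eb in zip(bond_feats, extra_bond_feats)
        ]
    return _graph_from_arrays(atom_feats, bonds, bond_feats, smiles=smiles)


# ---------------------------------------------------------------------------
@dataclass
class ReactionInput:
    """An atom-mapped reaction, reactant and product sides."""

    reactant_smiles: str
    product_smiles: str
    mode: str = "reac_diff"

    @classmethod
    def from_string(cls, rxn: str, mode: str = "reac_diff") -> "ReactionInput":
        for sep in REACTION_SEPARATORS:
            if sep in rxn:
                parts = rxn.split(sep)
                if len(parts) != 2:
                    raise ValueError(f"reaction must have exactly one separator: {rxn!r}")
                return cls(parts[0].strip(), parts[1].strip(), mode=mode)
        raise ValueError(f"no reaction separator ('>>' or '≫') in {rxn!r}")


def _map_numbers(mol: Chem.Mol, side: str, smiles: str,
                 lenient: bool) -> dict[int, int]:
    """map-number -> rdkit atom index; duplicates raise, unmapped per policy."""
    mapping: dict[int, int] = {}
    unmapped = []
    for atom in mol.GetAtoms():
        num = atom.GetAtomMapNum()
        if num == 0:
            unmapped.append(atom.GetIdx())
        elif num in mapping:
            raise ValueError(
                f"duplicate atom map number {num} on {side} side of {smiles!r}")
        else:
            mapping[num] = atom.GetIdx()
    if unmapped:
        if not lenient:
            raise ValueError(
                f"{len(unmapped)} unmapped atom(s) on {side} side of {smiles!r}; "
                "map all atoms or pass lenient=True")
        nxt = max(mapping, default=0) + 1
        for idx in unmapped:
            mapping[nxt] = idx
            nxt += 1
    return mapping


def build_cgr(reaction: ReactionInput | str, mode: str | None = None,
              lenient: bool = False) -> MolGraph:
    """Condense an atom-mapped reaction into a single featurized graph.

    Vertices are the union of reactant and product atoms keyed by map
    number; edges are the union of both bond sets.  Per the configured
    mode the features combine the two sides:

    - ``reac_diff`` (default): reactant features ⊕ (product − reactant)
    - ``prod_diff``: product features ⊕ (reactant − product)
    - ``reac_prod``: reactant features ⊕ product features

    Atoms present on one side only impute the missing side from the
    present side (so identity reactions have all-zero difference blocks);
    bonds present on one side only use the null-bond encoding there.
    """
    if isinstance(reaction, ReactionInput):
        rxn = reaction
        mode = mode or reaction.mode
    else:
        rxn = ReactionInput.from_string(reaction, mode=mode or "reac_diff")
        mode = rxn.mode
    if mode not in CGR_MODES:
        raise ValueError(f"unknown CGR mode {mode!r}; choose from {CGR_MODES}")

    rmol = parse_smiles(rxn.reactant_smiles)
    pmol = parse_smiles(rxn.product_smiles)
    rmap = _map_numbers(rmol, "reactant", rxn.reactant_smiles, lenient)
    pmap = _map_numbers(pmol, "product", rxn.product_smiles, lenient)

    map_nums = sorted(set(rmap) | set(pmap))
    vidx = {m: i for i, m in enumerate(map_nums)}

    # per-side atom features, imputed from the other side when absent
    r_atoms, p_atoms = [], []
    for m in map_nums:
        fr = featurize_atom(rmol.GetAtomWithIdx(rmap[m])) if m in rmap else None
        fp = featurize_atom(pmol.GetAtomWithIdx(pmap[m])) if m in pmap else None
        r_atoms.append(fr if fr is not None else fp)
        p_atoms.append(fp if fp is not None else fr)
    r_atoms = np.stack(r_atoms)
    p_atoms = np.stack(p_atoms)

    def bond_set(mol, mapping):
        inv = {v: k for k, v in mapping.items()}
        out = {}
        for bond in mol.GetBonds():
            a = inv[bond.GetBeginAtomIdx()]
            b = inv[bond.GetEndAtomIdx()]
            out[frozenset((a, b))] = bond
        return out

    r_bonds = bond_set(rmol, rmap)
    p_bonds = bond_set(pmol, pmap)
    null = featurize_bond(None)

    bonds, r_bf, p_bf = [], [], []
    for key in sorted(r_bonds.keys() | p_bonds.keys(),
                      key=lambda k: tuple(sorted(k))):
        a, b = sorted(key)
        bonds.append((vidx[a], vidx[b]))
        r_bf.append(featurize_bond(r_bonds[key]) if key in r_bonds else null)
        p_bf.append(featurize_bond(p_bonds[key]) if key in p_bonds else null)

    if mode == "reac_diff":
        atom_feats = np.hstack([r_atoms, p_atoms - r_atoms])
        bond_feats = [np.concatenate([r, p - r]) for r, p in zip(r_bf, p_bf)]
    elif mode == "prod_diff":
        atom_feats = np.hstack([p_atoms, r_atoms - p_atoms])
        bond_feats = [np.concatenate([p, r - p]) for r, p in zip(r_bf, p_bf)]
    else:  # reac_prod
        atom_feats = np.hstack([r_atoms, p_atoms])
        bond_feats = [np.concatenate([r, p]) for r, p in zip(r_bf, p_bf)]

    smiles = f"{rxn.reactant_smiles}>>{rxn.product_smiles}"
    return _graph_from_arrays(atom_feats, bonds, bond_feats, smiles=smiles)


def cgr_bond_change_counts(reaction: ReactionInput | str,
                           lenient: bool = False) -> dict[str, int]:
    """Counts of union bonds by side membership (diagnostic for reactions)."""
    if not isinstance(reaction, ReactionInput):
        reaction = ReactionInput.from_string(reaction)
    rmol = parse_smiles(reaction.reactant_smiles)
    pmol = parse_smiles(reaction.product_smiles)
    rmap = _map_numbers(rmol, "reactant", reaction.reactant_smiles, lenient)
    pmap = _map_numbers(pmol, "product", reaction.product_smiles, lenient)

    def keys_types(mol, mapping):
        inv = {v: k for k, v in mapping.items()}
        return {
            frozenset((inv[b.GetBeginAtomIdx()], inv[b.GetEndAtomIdx()])):
            b.GetBondType()
            for b in mol.GetBonds()
        }

    r = keys_types(rmol, rmap)
    p = keys_types(pmol, pmap)
    both = r.keys() & p.keys()
    return {
        "n_atoms": len(set(rmap) | set(pmap)),
        "n_bonds_union": len(r.keys() | p.keys()),
        "reactant_only": len(r.keys() - p.keys()),
        "product_only": len(p.keys() - r.keys()),
        "order_changed": sum(1 for k in both if r[k] != p[k]),
    }


# ---------------------------------------------------------------------------
@dataclass
class BatchedGraph:
    """Several molecule graphs packed into one index-shifted graph."""

    n_atoms: int
    atom_features: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    edge_features: np.ndarray
    rev_index: np.ndarray
    atom_fdim: int
    bond_fdim: int
    scopes: list[tuple[int, int]]      # (start atom, n atoms) per molecule

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def edge_fdim(self) -> int:
        return self.atom_fdim + self.bond_fdim

    @property
    def n_mols(self) -> int:
        return len(self.scopes)


def batch_graphs(graphs: list[MolGraph]) -> BatchedGraph:
    """Pack graphs into one disjoint-union graph, recording atom scopes."""
    if not graphs:
        raise ValueError("cannot batch an empty list of graphs")
    widths = {(g.atom_fdim, g.bond_fdim) for g in graphs}
    if len(widths) != 1:
        raise ValueError(f"mixed feature widths in batch: {sorted(widths)}")
    scopes, srcs, dsts, revs = [], [], [], []
    a_off = e_off = 0
    for g in graphs:
        scopes.append((a_off, g.n_atoms))
        srcs.append(g.src + a_off)
        dsts.append(g.dst + a_off)
        revs.append(g.rev_index + e_off)
        a_off += g.n_atoms
        e_off += g.n_edges
    return BatchedGraph(
        n_atoms=a_off,
        atom_features=np.concatenate([g.atom_features for g in graphs]),
        src=np.concatenate(srcs),
        dst=np.concatenate(dsts),
        edge_features=np.concatenate([g.edge_features for g in graphs]),
        rev_index=np.concatenate(revs),
        atom_fdim=graphs[0].atom_fdim,
        bond_fdim=graphs[0].bond_fdim,
        scopes=scopes,
    )


def unbatch_graphs(batch: BatchedGraph) -> list[MolGraph]:
    """Recover the individual graphs from a batch (inverse of batching)."""
    out = []
    e_off = 0
    for start, n in batch.scopes:
        emask = (batch.src >= start) & (batch.src < start + n)
        idx = np.flatnonzero(emask)
        g = MolGraph(
            n_atoms=n,
            atom_features=batch.atom_features[start:start + n],
            src=batch.src[idx] - start,
            dst=batch.dst[idx] - start,
            edge_features=batch.edge_features[idx],
            rev_index=batch.rev_index[idx] - e_off,
            atom_fdim=batch.atom_fdim,
            bond_fdim=batch.bond_fdim,
            scopes=[(0, n)],
        )
        e_off += len(idx)
        out.append(g)
    return out
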