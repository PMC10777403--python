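"""Deterministic synthetic molecules, reactions and targets.

Every input kind the toolkit accepts can be generated here with targets
computable from the molecule by a stated closed-form rule, so all modules
are testable without external datasets.  Molecules are sampled from a
small grammar — random acyclic C/O/N trees plus substituted benzene and
pyridine rings — capped at 12 heavy atoms.  All randomness flows through
one named generator; regeneration under the same seed is byte-identical.

Target rules:

- ``atom_count``: heavy-atom count + N(0, sigma), sigma = 0.1 by default
  (small measurement noise, well below one atom).
- ``ring_flag``: 1 if the molecule contains a ring.
- ``element_class``: 0 = carbon only, 1 = contains oxygen, 2 = contains
  nitrogen (oxygen wins if both).
- ``gaussian_spectrum``: a normalized two-Gaussian mixture over fixed
  bins whose centers shift with the carbon and heteroatom counts.
- ``per_atom_degree``: each atom's heavy-atom bond count; the molecular
  sum is exactly twice the bond count, giving a natural constraint value.
- ``heteroscedastic_regression``: heavy-atom count with noise whose
  standard deviation grows linearly with molecule size (sigma =
  0.05 * heavy atoms), for uncertainty-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .featurization import parse_smiles

MAX_HEAVY_ATOMS = 12
DEFAULT_NOISE_SIGMA = 0.1
SPECTRUM_BINS = 50

TASKS = ("atom_count", "ring_flag", "element_class", "gaussian_spectrum",
         "per_atom_degree", "heteroscedastic_regression")

# A fully atom-mapped Diels-Alder reaction: butadiene + ethene -> cyclohexene.
# Union graph: 6 atoms, 6 bonds; 2 bonds exist only in the product (the two
# newly formed sigma bonds), none only in the reactants, and 4 bonds change
# order (hand enumeration of the two bond sets).
DIELS_ALDER = ("[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
               ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1")


@dataclass
class FixtureSet:
    """Synthetic molecules (or reactions) with generator provenance."""

    smiles: list[str]
    seed: int
    kind: str = "molecule"
    targets: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.smiles)


# ---------------------------------------------------------------------------
_RING_CORES = ("c1ccccc1", "c1ccncc1")
_SUBSTITUENTS = ("C", "CC", "CCC", "O", "OC", "N", "C(C)C", "CO")

_VALENCE = {"C": 4, "O": 2, "N": 3}


def _random_tree_smiles(rng: np.random.Generator) -> str:
    """A random acyclic molecule as a heavy-atom tree."""
    n = int(rng.integers(1, MAX_HEAVY_ATOMS + 1))
    symbols = rng.choice(["C", "O", "N"], size=n, p=[0.7, 0.18, 0.12])
    symbols[0] = "C"
    mol = Chem.RWMol()
    free = []  # remaining valence per atom
    mol.AddAtom(Chem.Atom(symbols[0]))
    free.append(_VALENCE[symbols[0]])
    for i in range(1, n):
        candidates = [j for j in range(len(free)) if free[j] > 0]
        if not candidates:
            break
        j = int(candidates[rng.integers(len(candidates))])
        a = mol.AddAtom(Chem.Atom(symbols[i]))
        mol.AddBond(j, a, Chem.BondType.SINGLE)
        free[j] -= 1
        free.append(_VALENCE[symbols[i]] - 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _random_ring_smiles(rng: np.random.Generator) -> str:
    core = _RING_CORES[rng.integers(len(_RING_CORES))]
    n_sub = int(rng.integers(0, 3))
    subs = [_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
            for _ in range(n_sub)]
    if not subs:
        smi = core
    elif len(subs) == 1:
        smi = subs[0] + core
    else:
        smi = subs[0] + core[:-2] + "(" + subs[1] + ")" + core[-2:]
    mol = Chem.MolFromSmiles(smi)
    if mol is None or mol.GetNumAtoms() > MAX_HEAVY_ATOMS:
        return _RING_CORES[0]
    return Chem.MolToSmiles(mol)


def make_molecule_set(n: int, seed: int = 0,
                      ring_fraction: float = 0.4) -> FixtureSet:
    """``n`` unique, parseable SMILES; about ``ring_fraction`` aromatic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError(
                f"molecule grammar capacity exceeded at n={n} "
                f"(generated {len(out)} unique molecules)")
        smi = (_random_ring_smiles(rng) if rng.random() < ring_fraction
               else _random_tree_smiles(rng))
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return FixtureSet(smiles=out, seed=seed, kind="molecule")


# ---------------------------------------------------------------------------
def _mol_stats(smiles: str) -> dict:
    mol = parse_smiles(smiles)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    return {
        "n_heavy": mol.GetNumAtoms(),
        "n_bonds": mol.GetNumBonds(),
        "has_ring": int(mol.GetRingInfo().NumRings() > 0),
        "n_C": symbols.count("C") + symbols.count("c"),
        "n_O": symbols.count("O") + symbols.count("o"),
        "n_N": symbols.count("N") + symbols.count("n"),
        "degrees": [a.GetDegree() for a in mol.GetAtoms()],
    }


def gaussian_spectrum(smiles: str, n_bins: int = SPECTRUM_BINS) -> np.ndarray:
    """Closed-form synthetic spectrum: two Gaussians whose centers are set
    by the carbon fraction and heteroatom fraction; normalized to sum 1."""
    s = _mol_stats(smiles)
    x = (np.arange(n_bins) + 0.5) / n_bins
    c1 = 0.15 + 0.6 * s["n_C"] / MAX_HEAVY_ATOMS
    c2 = 0.85 - 0.5 * (s["n_O"] + s["n_N"]) / max(s["n_heavy"], 1)
    y = (np.exp(-0.5 * ((x - c1) / 0.06) ** 2)
         + 0.6 * np.exp(-0.5 * ((x - c2) / 0.08) ** 2))
    return y / y.sum()


def make_targets(fixture: FixtureSet, task: str,
                 sigma: float = DEFAULT_NOISE_SIGMA,
                 seed: int | None = None) -> FixtureSet:
    """Attach targets for ``task``; stored under ``fixture.targets[task]``."""
    if task not in TASKS:
        raise ValueError(f"unknown fixture task {task!r}; choose from {TASKS}")
    rng = np.random.default_rng(fixture.seed + 1 if seed is None else seed)
    stats = [_mol_stats(s) for s in fixture.smiles]
    if task == "atom_count":
        vals = np.array([s["n_heavy"] for s in stats], dtype=float)
        if sigma > 0:
            vals = vals + rng.normal(0.0, sigma, size=len(vals))
        fixture.targets[task] = vals
    elif task == "ring_flag":
        fixture.targets[task] = np.array([s["has_ring"] for s in stats],
                                         dtype=float)
    elif task == "element_class":
        cls = [1 if s["n_O"] > 0 else 2 if s["n_N"] > 0 else 0 for s in stats]
        fixture.targets[task] = np.array(cls, dtype=float)
    elif task == "gaussian_spectrum":
        fixture.targets[task] = np.stack(
            [gaussian_spectrum(s) for s in fixture.smiles])
    elif task == "per_atom_degree":
        fixture.targets[task] = [np.array(s["degrees"], dtype=float)
                                 for s in stats]
        fixture.targets["per_atom_degree_constraint"] = np.array(
            [2.0 * s["n_bonds"] for s in stats])
    elif task == "heteroscedastic_regression":
        base = np.array([s["n_heavy"] for s in stats], dtype=float)
        true_sigma = 0.05 * base
        fixture.targets[task] = base + rng.normal(0.0, 1.0, len(base)) * true_sigma
        fixture.targets["heteroscedastic_sigma"] = true_sigma
    return fixture


# ---------------------------------------------------------------------------
def _mapped_smiles(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    for i, atom in enumerate(m.GetAtoms()):
        atom.SetAtomMapNum(i + 1)
    return Chem.MolToSmiles(m)


def make_reaction_set(n: int, seed: int = 0,
                      identity_fraction: float = 0.3) -> FixtureSet:
    """Atom-mapped toy reactions with target = number of changed bonds.

    About ``identity_fraction`` are identity reactions (target 0, the
    zero-change controls); the rest break one randomly chosen acyclic
    bond (target 1).  The mapped Diels-Alder fixture is always included
    as the first entry (target 6 = 2 formed + 4 order-changed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mols = make_molecule_set(max(2 * n, 20), seed=seed + 7,
                             ring_fraction=0.2)
    rxns: list[str] = []
    targets: list[float] = []
    rxns.append(DIELS_ALDER)
    targets.append(6.0)
    i = 0
    while len(rxns) < n and i < len(mols.smiles):
        smi = mols.smiles[i]
        i += 1
        mol = Chem.MolFromSmiles(smi)
        if mol.GetNumBonds() == 0:
            continue
        mapped = _mapped_smiles(mol)
        if rng.random() < identity_fraction:
            rxns.append(f"{mapped}>>{mapped}")
            targets.append(0.0)
            continue
        acyclic = [b.GetIdx() for b in mol.GetBonds() if not b.IsInRing()]
        if not acyclic:
            rxns.append(f"{mapped}>>{mapped}")
            targets.append(0.0)
            continue
        bidx = int(acyclic[rng.integers(len(acyclic))])
        rw = Chem.RWMol(mol)
        for a, atom in enumerate(rw.GetAtoms()):
            atom.SetAtomMapNum(a + 1)
        bond = rw.GetBondWithIdx(bidx)
        rw.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        prod = rw.GetMol()
        Chem.SanitizeMol(prod)
        reac = Chem.Mol(mol)
        for a, atom in enumerate(reac.GetAtoms()):
            atom.SetAtomMapNum(a + 1)
        rxns.append(f"{Chem.MolToSmiles(reac)}>>{Chem.MolToSmiles(prod)}")
        targets.append(1.0)
    if len(rxns) < n:
        raise ValueError("could not generate enough reactions")
    fixture = FixtureSet(smiles=rxns[:n], seed=seed, kind="reaction")
    fixture.targets["changed_bonds"] = np.array(targets[:n])
    return fixture


# ---------------------------------------------------------------------------
def fixture_frame(fixture: FixtureSet, task: str) -> pd.DataFrame:
    """A CSV-ready table in the exact format the data readers expect."""
    col = "rxn_smiles" if fixture.kind == "reaction" else "smiles"
    df = pd.DataFrame({col: fixture.smiles})
    values = fixture.targets[task]
    if task == "gaussian_spectrum":
        for b in range(values.shape[1]):
            df[f"bin_{b + 1:04d}"] = values[:, b]
    elif task == "per_atom_degree":
        df["atom_targets"] = [";".join(f"{v:g}" for v in row)
                              for row in values]
        df["constraint"] = fixture.targets["per_atom_degree_constraint"]
    else:
        df[task] = values
    return df


def write_fixture_dir(out_dir: str, n: int = 100, seed: int = 0,
                      tasks: tuple[str, ...] = ("atom_count", "ring_flag")) -> None:
    """Write ready-to-train CSVs, one per task, under ``out_dir``."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    mols = make_molecule_set(n, seed=seed)
    for task in tasks:
        make_targets(mols, task)
        fixture_frame(mols, task).to_csv(
            os.path.join(out_dir, f"{task}.csv"), index=False)
    rxn = make_reaction_set(min(n, 50), seed=seed)
    fixture_frame(rxn, "changed_bonds").to_csv(
        os.path.join(out_dir, "reactions.csv"), index=False)
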