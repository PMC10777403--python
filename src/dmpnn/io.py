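"""CSV readers and writers for datasets and predictions.

The expected input is a CSV with a header: one or more SMILES (or
atom-mapped ``reactants>>products``) columns followed by numeric target
columns.  Targets may be floats, class indices, inequality strings such
as ``">5.0"``, or a block of ``bin_0001...`` spectrum columns.  Empty
cells are missing targets: they are masked out of every loss and metric.
Malformed cells raise errors that name the offending row.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import TargetSpec
from .featurization import build_cgr, build_mol_graph, REACTION_SEPARATORS
from .losses import parse_bounded_target
from .training import MoleculeDataset

_SMILES_HINTS = ("smiles", "mol", "rxn", "reaction")
_NON_TARGET = ("weight", "constraint", "atom_targets", "bond_targets")


@dataclass
class DatasetTable:
    """A typed view of one input CSV."""

    frame: pd.DataFrame
    smiles_columns: list[str]
    target_columns: list[str]
    reaction_columns: list[str] = field(default_factory=list)
    task: str = "regression"
    n_classes: int = 3
    path: str | None = None

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def is_spectra(self) -> bool:
        return self.task == "spectra"


def _looks_like_reaction(series: pd.Series) -> bool:
    sample = series.dropna().astype(str).head(20)
    return bool(len(sample)) and all(
        any(sep in s for sep in REACTION_SEPARATORS) for s in sample)


def read_dataset(path: str,
                 smiles_columns: list[str] | None = None,
                 target_columns: list[str] | None = None,
                 reaction: bool | list[str] = False,
                 task: str | None = None,
                 n_classes: int = 3) -> DatasetTable:
    """Read and type a dataset CSV.

    Column roles are taken from the arguments when given, otherwise
    inferred: columns whose names mention smiles/mol/rxn hold molecules,
    ``bin_####`` blocks are spectra, and everything else is a target.
    ``reaction=True`` (the ``--reaction`` flag) marks every molecule
    column as atom-mapped reactions; a list names specific columns.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    cols = list(frame.columns)
    if smiles_columns is None:
        smiles_columns = [c for c in cols
                          if any(h in c.lower() for h in _SMILES_HINTS)]
        if not smiles_columns:
            smiles_columns = [cols[0]]
    missing = [c for c in smiles_columns if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing SMILES column(s) {missing}")

    bin_cols = [c for c in cols if c.startswith("bin_")]
    if target_columns is None:
        if bin_cols:
            target_columns = bin_cols
        else:
            target_columns = [c for c in cols if c not in smiles_columns
                              and c.lower() not in _NON_TARGET]
    if not target_columns:
        raise ValueError(f"{path}: no target columns found")

    if reaction is True:
        reaction_columns = list(smiles_columns)
    elif reaction:
        reaction_columns = list(reaction)
    else:
        reaction_columns = [c for c in smiles_columns
                            if _looks_like_reaction(frame[c])]

    if task is None:
        if bin_cols:
            task = "spectra"
        else:
            vals = frame[target_columns].to_numpy().ravel()
            vals = [v for v in vals if str(v).strip() != ""]
            if vals and all(str(v).strip() in ("0", "1", "0.0", "1.0")
                            for v in vals):
                task = "binary"
            else:
                task = "regression"
    return DatasetTable(frame=frame, smiles_columns=smiles_columns,
                        target_columns=target_columns,
                        reaction_columns=reaction_columns,
                        task=task, n_classes=n_classes, path=path)


def _parse_targets(table: DatasetTable
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(values, mask, relations) from the raw string cells."""
    n = table.n_rows
    t = len(table.target_columns)
    values = np.full((n, t), np.nan)
    mask = np.zeros((n, t), dtype=bool)
    relations = np.full((n, t), "=", dtype=object)
    any_rel = False
    for j, col in enumerate(table.target_columns):
        for i, cell in enumerate(table.frame[col]):
            s = str(cell).strip()
            if s == "" or s.lower() == "nan":
                continue
            try:
                v, rel = parse_bounded_target(s, row=i)
            except ValueError as err:
                raise ValueError(f"{table.path or 'dataset'} column "
                                 f"{col!r}: {err}") from None
            values[i, j] = v
            mask[i, j] = True
            relations[i, j] = rel
            any_rel = any_rel or rel != "="
    return values, mask, (relations if any_rel else None)


def to_molecule_dataset(table: DatasetTable,
                        loss: str | None = None,
                        features: np.ndarray | None = None,
                        lenient_mapping: bool = False) -> MoleculeDataset:
    """Featurize every row; parse errors name the row and column."""
    values, mask, relations = _parse_targets(table)
    if relations is not None and loss is None and table.task == "regression":
        loss = "bounded_mse"
    graphs = []
    smiles = []
    for i, row in table.frame.iterrows():
        row_graphs = []
        row_smiles = []
        for col in table.smiles_columns:
            s = str(row[col]).strip()
            if not s:
                raise ValueError(
                    f"row {i}: missing molecule in column {col!r}")
            try:
                if col in table.reaction_columns:
                    g = build_cgr(s, lenient=lenient_mapping)
                else:
                    g = build_mol_graph(s)
            except ValueError as err:
                raise ValueError(f"row {i}, column {col!r}: {err}") from None
            row_graphs.append(g)
            row_smiles.append(s)
        graphs.append(row_graphs)
        smiles.append(row_smiles)

    if table.task == "spectra":
        spec = TargetSpec(task="spectra", n_tasks=1, loss=loss,
                          n_bins=len(table.target_columns))
    elif table.task == "multiclass":
        spec = TargetSpec(task="multiclass", n_tasks=len(table.target_columns),
                          loss=loss, n_classes=table.n_classes)
    else:
        spec = TargetSpec(task=table.task, n_tasks=len(table.target_columns),
                          loss=loss)
    return MoleculeDataset(graphs=graphs, targets=values, spec=spec,
                           mask=mask, relations=relations,
                           features=features, smiles=smiles)


# ---------------------------------------------------------------------------
def write_predictions(table: DatasetTable, preds: np.ndarray, path: str,
                      unc: np.ndarray | None = None,
                      unc_suffix: str = "_unc") -> pd.DataFrame:
    """Write input columns plus prediction (and uncertainty) columns.

    Spectra predictions get one column per bin with masked bins blank;
    scalar tasks get one column per target, named after it.
    """
    out = table.frame[table.smiles_columns].copy()
    preds = np.atleast_2d(np.asarray(preds, dtype=np.float64))
    if table.is_spectra:
        for j, col in enumerate(table.target_columns):
            col_vals = preds[:, j].astype(object)
            blank = table.frame[col].astype(str).str.strip() == ""
            col_vals[blank.to_numpy()] = ""
            out[f"pred_{col}"] = col_vals
    else:
        for j, col in enumerate(table.target_columns):
            out[f"pred_{col}"] = preds[:, j]
            if unc is not None:
                out[f"pred_{col}{unc_suffix}"] = np.atleast_2d(unc)[:, j]
    out.to_csv(path, index=False, float_format="%.10g")
    return out


def write_latents(latents: np.ndarray, path: str) -> pd.DataFrame:
    """Latent CSV, one row per input, columns ``fp_0001...``."""
    latents = np.atleast_2d(latents)
    cols = [f"fp_{i + 1:04d}" for i in range(latents.shape[1])]
    df = pd.DataFrame(latents, columns=cols)
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
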