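"""Compound tables, SMILES validation and 2D descriptor / fingerprint matrices.

This module turns labeled compound lists (CSV or SDF) into clean numeric
feature tables. Featurization is purely two-dimensional: descriptors and
fingerprints are computed from the molecular graph, never from conformers.

Descriptor families are registered by name:

``rdkit_2d``
    The full RDKit 2D descriptor list (~210 physchem/topological
    descriptors: log P, TPSA, autocorrelations, E-state indices, ring and
    fragment counts, ...).
``maccs``, ``path``, ``atompair``, ``morgan``, ``estate``
    Substructure-key, path-based, atom-pair, circular and E-state
    fingerprint families.
``combined``
    Column-wise concatenation of every family above, for models that should
    see all available structural information at once.

Cleaning follows the column-deletion convention: any feature with at least
one missing or non-finite value is dropped for every compound, so the
surviving matrix is fully finite while no compound is lost.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState.Fingerprinter import FingerprintMol as _estate_fingerprint

from .errors import AlignmentError, RegistryError, SchemaError, SmilesError

# RDKit logs every parse failure to stderr; validation errors are raised
# explicitly instead, so silence the C++ logger.
RDLogger.DisableLog("rdApp.error")


# ---------------------------------------------------------------------------
# compound containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledCompound:
    """One compound with a canonical SMILES and a binary activity label."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label for {self.id!r} must be 0 or 1, got {self.label!r}")


@dataclass
class CompoundSet:
    """Ordered collection of labeled compounds for a single endpoint."""

    endpoint: str
    compounds: list[LabeledCompound]

    def __post_init__(self) -> None:
        if not self.compounds:
            raise SchemaError("no compounds")
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.compounds], dtype=int)

    @property
    def smiles(self) -> list[str]:
        return [c.smiles for c in self.compounds]


def validate_smiles(smiles: str) -> str:
    """Parse a SMILES string and return the canonical form.

    Two SMILES spellings of the same molecule map to the same canonical
    string. Raises :class:`SmilesError` for syntactically or chemically
    unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise SmilesError(f"invalid SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _coerce_label(value: object) -> int:
    """Coerce a raw table cell to a {0,1} label or raise ValueError."""
    if isinstance(value, str):
        value = value.strip()
    num = float(value)  # raises ValueError for non-numeric text
    if num not in (0.0, 1.0):
        raise ValueError(f"label {value!r} not in {{0,1}}")
    return int(num)


def read_compound_table(
    path: str | Path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
    activity_tag: str = "activity",
    endpoint: str = "user",
) -> CompoundSet:
    """Read a labeled compound table from CSV or SDF.

    Parameters
    ----------
    path
        Input file. CSV needs a header row with id/smiles/label columns
        (names remappable via ``column_map``); SDF reads the activity from
        the named property tag and the id from the molecule title.
    column_map
        Maps the logical names ``id``, ``smiles``, ``label`` to the actual
        CSV column names.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    if format == "csv":
        rows = _read_csv_rows(path, column_map)
    elif format == "sdf":
        rows = _read_sdf_rows(path, activity_tag)
    else:
        raise RegistryError(f"unknown compound table format {format!r} (use 'csv' or 'sdf')")

    compounds: list[LabeledCompound] = []
    bad_labels: list[str] = []
    bad_smiles: list[str] = []
    for cid, smi, raw_label in rows:
        try:
            label = _coerce_label(raw_label)
        except (ValueError, TypeError):
            bad_labels.append(cid)
            continue
        try:
            canonical = validate_smiles(smi)
        except SmilesError:
            bad_smiles.append(cid)
            continue
        compounds.append(LabeledCompound(cid, canonical, label))
    if bad_labels:
        raise SchemaError(f"unparseable activity labels for rows: {bad_labels}")
    if bad_smiles:
        raise SmilesError(f"invalid SMILES for rows: {bad_smiles}")
    if not compounds:
        raise SchemaError("no compounds")
    return CompoundSet(endpoint=endpoint, compounds=compounds)


def _read_csv_rows(
    path: Path, column_map: Mapping[str, str] | None
) -> list[tuple[str, str, object]]:
    cmap = {"id": "id", "smiles": "smiles", "label": "label"}
    if column_map:
        cmap.update(column_map)
    try:
        table = pd.read_csv(path, dtype={cmap["id"]: str, cmap["smiles"]: str})
    except pd.errors.EmptyDataError:
        raise SchemaError("no compounds") from None
    missing = [name for name in cmap.values() if name not in table.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}; found {list(table.columns)}")
    if table.empty:
        raise SchemaError("no compounds")
    return [
        (str(r[cmap["id"]]), str(r[cmap["smiles"]]), r[cmap["label"]])
        for _, r in table.iterrows()
    ]


def _read_sdf_rows(path: Path, activity_tag: str) -> list[tuple[str, str, object]]:
    rows: list[tuple[str, str, object]] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise SmilesError(f"unparseable molecule at SDF record {i}")
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf{i}"
        if not mol.HasProp(activity_tag):
            raise SchemaError(f"SDF record {cid!r} lacks activity tag {activity_tag!r}")
        rows.append((cid, Chem.MolToSmiles(mol), mol.GetProp(activity_tag)))
    if not rows:
        raise SchemaError("no compounds")
    return rows


def write_compound_table(cs: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet as the standard id,smiles,label CSV."""
    frame = pd.DataFrame({"id": cs.ids, "smiles": cs.smiles, "label": cs.labels})
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptor matrix
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """n x p numeric feature table with named columns and compound ids."""

    values: np.ndarray
    feature_names: list[str]
    compound_ids: list[str]
    descriptor_set: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if len(self.compound_ids) != n:
            raise ValueError(f"{len(self.compound_ids)} ids for {n} rows")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, features: Sequence[str]) -> "DescriptorMatrix":
        """Column-subset (and reorder) by feature name."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        missing = [f for f in features if f not in index]
        if missing:
            raise AlignmentError(f"features not in matrix: {missing}")
        cols = [index[f] for f in features]
        return DescriptorMatrix(
            self.values[:, cols], list(features), list(self.compound_ids), self.descriptor_set
        )

    def take_rows(self, indices: Sequence[int]) -> "DescriptorMatrix":
        idx = np.asarray(indices, dtype=int)
        return DescriptorMatrix(
            self.values[idx],
            list(self.feature_names),
            [self.compound_ids[i] for i in idx],
            self.descriptor_set,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "id"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, descriptor_set: str = "csv") -> "DescriptorMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(
            frame.to_numpy(dtype=float),
            [str(c) for c in frame.columns],
            [str(i) for i in frame.index],
            descriptor_set,
        )


# ---------------------------------------------------------------------------
# descriptor families
# ---------------------------------------------------------------------------

_RDKIT_2D_NAMES = [name for name, _ in Descriptors.descList]


def _rdkit_2d(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    vals = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
    return _RDKIT_2D_NAMES, np.array([vals[n] for n in _RDKIT_2D_NAMES], dtype=float)


def _maccs(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    bits = MACCSkeys.GenMACCSKeys(mol)
    names = [f"maccs_{i}" for i in range(len(bits))]
    return names, np.array(bits, dtype=float)


def _bit_family(prefix: str, fp) -> tuple[list[str], np.ndarray]:
    names = [f"{prefix}_{i}" for i in range(len(fp))]
    return names, np.array(fp, dtype=float)


_AP_GEN = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=512)
_MORGAN_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=512)


def _path_fp(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    return _bit_family("path", Chem.RDKFingerprint(mol, fpSize=512))


def _atompair_fp(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    return _bit_family("ap", _AP_GEN.GetFingerprint(mol))


def _morgan_fp(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    return _bit_family("mrg", _MORGAN_GEN.GetFingerprint(mol))


def _estate_fp(mol: Chem.Mol) -> tuple[list[str], np.ndarray]:
    counts, sums = _estate_fingerprint(mol)
    names = [f"estate_cnt_{i}" for i in range(len(counts))] + [
        f"estate_sum_{i}" for i in range(len(sums))
    ]
    return names, np.concatenate([np.asarray(counts, float), np.asarray(sums, float)])


DESCRIPTOR_SETS: dict[str, Callable[[Chem.Mol], tuple[list[str], np.ndarray]]] = {
    "rdkit_2d": _rdkit_2d,
    "maccs": _maccs,
    "path": _path_fp,
    "atompair": _atompair_fp,
    "morgan": _morgan_fp,
    "estate": _estate_fp,
}

#: families concatenated by the "combined" set, in this order
COMBINED_FAMILIES = ("rdkit_2d", "maccs", "path", "atompair", "morgan", "estate")


def _featurize_mol(mol: Chem.Mol, families: Iterable[str]) -> tuple[list[str], np.ndarray]:
    all_names: list[str] = []
    parts: list[np.ndarray] = []
    for fam in families:
        func = DESCRIPTOR_SETS[fam]
        try:
            names, vals = func(mol)
        except Exception:
            # a family that fails wholesale for this molecule contributes
            # missing values; clean_matrix will drop the affected columns
            names = _family_names(fam)
            vals = np.full(len(names), np.nan)
        all_names.extend(names)
        parts.append(vals)
    return all_names, np.concatenate(parts)


def _family_names(family: str) -> list[str]:
    # names are molecule-independent for every registered family
    probe = Chem.MolFromSmiles("C")
    return DESCRIPTOR_SETS[family](probe)[0]


def compute_descriptors(cs: CompoundSet, descriptor_set: str = "rdkit_2d") -> DescriptorMatrix:
    """Compute a descriptor or fingerprint matrix for a compound set.

    Rows follow the input compound order; identical molecules (identical
    canonical SMILES) yield identical rows. Individual descriptor failures
    become NaN cells, left for :func:`clean_matrix` to remove column-wise.
    """
    if descriptor_set == "combined":
        families: tuple[str, ...] = COMBINED_FAMILIES
    elif descriptor_set in DESCRIPTOR_SETS:
        families = (descriptor_set,)
    else:
        known = sorted(DESCRIPTOR_SETS) + ["combined"]
        raise RegistryError(f"unknown descriptor set {descriptor_set!r}; registered: {known}")

    cache: dict[str, np.ndarray] = {}
    names: list[str] | None = None
    rows: list[np.ndarray] = []
    for comp in cs.compounds:
        if comp.smiles in cache:
            rows.append(cache[comp.smiles])
            continue
        mol = Chem.MolFromSmiles(comp.smiles)
        if mol is None:  # pragma: no cover - compounds are pre-validated
            raise SmilesError(f"invalid SMILES: {comp.smiles!r}")
        row_names, row = _featurize_mol(mol, families)
        if names is None:
            names = row_names
        cache[comp.smiles] = row
        rows.append(row)
    assert names is not None
    return DescriptorMatrix(np.vstack(rows), names, cs.ids, descriptor_set)


def clean_matrix(m: DescriptorMatrix) -> DescriptorMatrix:
    """Drop every feature column containing a missing or non-finite value.

    Compounds (rows) are never removed; column order is preserved. Raises
    :class:`SchemaError` if no usable descriptor survives.
    """
    finite = np.isfinite(m.values).all(axis=0)
    if not finite.any():
        raise SchemaError("no usable descriptors: every column contains missing values")
    keep = [name for name, ok in zip(m.feature_names, finite) if ok]
    return DescriptorMatrix(
        m.values[:, finite], keep, list(m.compound_ids), m.descriptor_set
    )


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-feature training minima and maxima for min-max scaling."""

    x_min: np.ndarray
    x_max: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if not (self.x_min.shape == self.x_max.shape == (len(self.feature_names),)):
            raise ValueError("min/max vectors must align with feature names")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must be <= x_max elementwise")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.array(payload["x_min"]), np.array(payload["x_max"]), payload["feature_names"]
        )


def fit_normalizer(m: DescriptorMatrix) -> NormalizationParams:
    """Fit per-feature min and max over the rows of a clean matrix."""
    if m.n_compounds == 0 or m.n_features == 0:
        raise SchemaError("cannot fit a normalizer on an empty matrix")
    return NormalizationParams(
        m.values.min(axis=0), m.values.max(axis=0), list(m.feature_names)
    )


def apply_normalizer(params: NormalizationParams, m: DescriptorMatrix) -> DescriptorMatrix:
    """Min-max scale a matrix with training-set parameters.

    Values are mapped to (x - min) / (max - min). Constant training features
    map to 0. Query values outside the training range are deliberately NOT
    clamped, so out-of-range compounds land outside [0, 1] and acquire large
    applicability-domain distances.
    """
    if list(m.feature_names) != list(params.feature_names):
        raise AlignmentError(
            "feature names do not match the normalizer "
            f"(matrix has {len(m.feature_names)}, normalizer has {len(params.feature_names)})"
        )
    span = params.x_max - params.x_min
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (m.values - params.x_min) / span, 0.0)
    return DescriptorMatrix(
        scaled, list(m.feature_names), list(m.compound_ids), m.descriptor_set
    )
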