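"""Descriptor blocks, descriptor matrices and named descriptor subsets.

Five 2-D descriptor blocks are provided:

``Molprops``
    19 simple molecular properties and counts (lipophilicity estimate,
    molecular weight, atom/bond/ring/H-bonding/stereo counts).
``Chi``
    12 Kier–Hall molecular connectivity indices: simple connectivity chi of
    order 0, 1, 2, 3-path, 3-cluster and 4-path, plus the same six computed
    with valence deltas.
``Estate``
    161 electrotopological-state columns: per-atom-type sums and counts of
    atom E-state values over the standard 79-type alphabet, plus the total,
    maximum and minimum atom E-state of the molecule.
``ECFP6`` / ``FCFP4``
    Circular (Morgan) fingerprints of diameter 6 (standard atom invariants)
    and diameter 4 (functional-class invariants).  A fingerprint counts as
    *one* descriptor in subset-size accounting but expands to ``fold_width``
    folded count columns in a numeric descriptor matrix.

Subsets are unions of blocks; a subset's size is the sum of its blocks'
accounting sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.EState import EStateIndices, Fingerprinter
from rdkit.Chem.EState.AtomTypes import _rawD as _ESTATE_RAW_TYPES

from .prep import Dataset

DEFAULT_FOLD_WIDTH = 1024

# ---------------------------------------------------------------------------
# Molprops: 19 simple properties and counts
# ---------------------------------------------------------------------------

MOLPROPS_COLUMNS = (
    "ALogP",
    "Molecular_Weight",
    "Num_Atoms",
    "Num_Bonds",
    "Num_RotatableBonds",
    "Num_Rings",
    "Num_AromaticRings",
    "Num_AromaticBonds",
    "Num_H_Acceptors",
    "Num_H_Donors",
    "Num_H_Acceptors_Lipinski",
    "Num_H_Donors_Lipinski",
    "HBA_Count",
    "HBD_Count",
    "Num_StereoAtoms",
    "Num_StereoBonds",
    "Num_BridgeBonds",
    "Num_BridgeHeadAtoms",
    "Num_SpiroAtoms",
)


def compute_molprops(mol: Chem.Mol) -> np.ndarray:
    """The 19 Molprops values for one molecule, in fixed column order.

    Atom and bond counts are over the hydrogen-suppressed graph.
    """
    ri = mol.GetRingInfo()
    n_arom_bonds = sum(1 for b in mol.GetBonds() if b.GetIsAromatic())
    n_stereo_atoms = sum(
        1 for a in mol.GetAtoms() if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED
    )
    n_stereo_bonds = sum(
        1 for b in mol.GetBonds() if b.GetStereo() != Chem.BondStereo.STEREONONE
    )
    n_bridge_bonds = sum(
        1 for b in mol.GetBonds() if ri.NumBondRings(b.GetIdx()) >= 2
    )
    values = (
        Crippen.MolLogP(mol),
        Descriptors.MolWt(mol),
        mol.GetNumHeavyAtoms(),
        mol.GetNumBonds(),
        Lipinski.NumRotatableBonds(mol),
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        n_arom_bonds,
        Lipinski.NumHAcceptors(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NOCount(mol),
        Lipinski.NHOHCount(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        n_stereo_atoms,
        n_stereo_bonds,
        n_bridge_bonds,
        rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        rdMolDescriptors.CalcNumSpiroAtoms(mol),
    )
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# Chi: Kier–Hall connectivity indices
# ---------------------------------------------------------------------------

CHI_COLUMNS = (
    "Chi0", "Chi1", "Chi2", "Chi3p", "Chi3c", "Chi4p",
    "Chi0v", "Chi1v", "Chi2v", "Chi3pv", "Chi3cv", "Chi4pv",
)

_PT = Chem.GetPeriodicTable()


def _simple_deltas(mol: Chem.Mol) -> list[float]:
    return [float(a.GetDegree()) for a in mol.GetAtoms()]


def _valence_deltas(mol: Chem.Mol) -> list[float]:
    """Kier–Hall valence delta: (Zv − h) for second-row atoms, else
    (Zv − h)/(Z − Zv − 1)."""
    out = []
    for a in mol.GetAtoms():
        z = a.GetAtomicNum()
        zv = _PT.GetNOuterElecs(z)
        h = a.GetTotalNumHs()
        if z <= 10:
            dv = float(zv - h)
        else:
            dv = float(zv - h) / float(z - zv - 1)
        out.append(dv)
    return out


def _paths(mol: Chem.Mol, n_bonds: int) -> list[tuple[int, ...]]:
    """All simple paths of ``n_bonds`` bonds, each undirected path once."""
    adj = [[n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()]
    found: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        if len(path) == n_bonds + 1:
            if path[0] < path[-1]:
                found.append(tuple(path))
            return
        for nb in adj[path[-1]]:
            if nb not in path:
                path.append(nb)
                extend(path)
                path.pop()

    for start in range(mol.GetNumAtoms()):
        extend([start])
    return found


def _clusters3(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Star subgraphs: a centre plus three of its neighbours."""
    out = []
    for a in mol.GetAtoms():
        nbrs = [n.GetIdx() for n in a.GetNeighbors()]
        if len(nbrs) >= 3:
            for trio in combinations(sorted(nbrs), 3):
                out.append((a.GetIdx(), *trio))
    return out


def _chi_sum(subgraphs: Iterable[tuple[int, ...]], deltas: Sequence[float]) -> float:
    total = 0.0
    for sg in subgraphs:
        prod = 1.0
        ok = True
        for idx in sg:
            d = deltas[idx]
            if d <= 0:  # isolated atom or exotic valence: contributes nothing
                ok = False
                break
            prod *= d
        if ok:
            total += prod ** -0.5
    return total


def compute_chi(mol: Chem.Mol) -> np.ndarray:
    """The 12 connectivity chi indices for one molecule."""
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError("chi indices need at least one heavy atom")
    atoms = [(i,) for i in range(mol.GetNumAtoms())]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    p2 = _paths(mol, 2)
    p3 = _paths(mol, 3)
    p4 = _paths(mol, 4)
    c3 = _clusters3(mol)
    values = []
    for deltas in (_simple_deltas(mol), _valence_deltas(mol)):
        values.extend(
            _chi_sum(sg, deltas) for sg in (atoms, bonds, p2, p3, c3, p4)
        )
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# Estate: electrotopological state sums and counts
# ---------------------------------------------------------------------------

ESTATE_TYPE_NAMES = tuple(name for name, _ in _ESTATE_RAW_TYPES)
ESTATE_COLUMNS = (
    tuple(f"ES_Sum_{n}" for n in ESTATE_TYPE_NAMES)
    + tuple(f"ES_Count_{n}" for n in ESTATE_TYPE_NAMES)
    + ("ES_Total", "ES_Max", "ES_Min")
)


def atom_estate_values(mol: Chem.Mol) -> np.ndarray:
    """Per-atom E-state values S_i (intrinsic state plus 1/r² perturbations)."""
    return np.asarray(EStateIndices(mol), dtype=float)


def atom_intrinsic_states(mol: Chem.Mol) -> np.ndarray:
    """Per-atom intrinsic states I = ((2/N)²·δv + 1)/δ over the heavy-atom
    graph (N = principal quantum number).  ΣS equals ΣI because the pairwise
    perturbations are antisymmetric."""
    out = []
    for a in mol.GetAtoms():
        d = a.GetDegree()
        if d == 0:
            out.append(0.0)
            continue
        z = a.GetAtomicNum()
        zv = _PT.GetNOuterElecs(z)
        h = a.GetTotalNumHs()
        dv = float(zv - h)
        n_quantum = _principal_quantum_number(z)
        out.append(((2.0 / n_quantum) ** 2 * dv + 1.0) / d)
    return np.asarray(out, dtype=float)


def _principal_quantum_number(z: int) -> int:
    for n, upper in ((1, 2), (2, 10), (3, 18), (4, 36), (5, 54), (6, 86)):
        if z <= upper:
            return n
    return 7


def compute_estate(mol: Chem.Mol) -> np.ndarray:
    """161 E-state columns: 79 atom-type sums, 79 atom-type counts, and the
    total/max/min atom E-state of the molecule."""
    counts, sums = Fingerprinter.FingerprintMol(mol)
    s = atom_estate_values(mol)
    extras = (float(s.sum()), float(s.max()), float(s.min()))
    return np.concatenate([np.asarray(sums, float), np.asarray(counts, float), extras])


# ---------------------------------------------------------------------------
# Circular fingerprints
# ---------------------------------------------------------------------------

_FP_GENERATORS: dict[str, object] = {}


def _fp_generator(kind: str):
    if kind not in _FP_GENERATORS:
        if kind == "ECFP6":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=3)
        elif kind == "FCFP4":
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=2,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            )
        else:
            raise ValueError(f"unknown fingerprint kind {kind!r}")
        _FP_GENERATORS[kind] = gen
    return _FP_GENERATORS[kind]


def compute_fingerprint(
    mol: Chem.Mol, kind: str, fold_width: int = DEFAULT_FOLD_WIDTH
) -> tuple[dict[int, int], np.ndarray]:
    """Circular substructure identifiers and the folded count vector.

    Returns ``(sparse, folded)`` where ``sparse`` maps raw environment
    identifiers to occurrence counts and ``folded[i] = Σ counts of
    identifiers with id % fold_width == i``.
    """
    sparse = dict(_fp_generator(kind).GetSparseCountFingerprint(mol).GetNonzeroElements())
    folded = fold_fingerprint(sparse, fold_width)
    return sparse, folded


def fold_fingerprint(sparse: Mapping[int, int], fold_width: int) -> np.ndarray:
    folded = np.zeros(fold_width, dtype=float)
    for ident, count in sparse.items():
        folded[ident % fold_width] += count
    return folded


def radius0_identifiers(mol: Chem.Mol, kind: str = "ECFP6") -> set[int]:
    """The distinct initial (radius-0) atom-environment identifiers."""
    if kind == "ECFP6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=0)
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=0,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    return set(gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


# ---------------------------------------------------------------------------
# Blocks and subsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorBlock:
    """A named descriptor block.

    ``size`` is the subset-accounting size: number of numeric columns for
    numeric blocks, 1 for fingerprint blocks (which expand to ``fold_width``
    columns in a matrix).
    """

    name: str
    kind: str  # numeric | fingerprint
    columns: tuple[str, ...]
    size: int


BLOCKS: dict[str, DescriptorBlock] = {
    "Molprops": DescriptorBlock("Molprops", "numeric", MOLPROPS_COLUMNS, 19),
    "Chi": DescriptorBlock("Chi", "numeric", CHI_COLUMNS, 12),
    "Estate": DescriptorBlock("Estate", "numeric", ESTATE_COLUMNS, 161),
    "ECFP6": DescriptorBlock("ECFP6", "fingerprint", (), 1),
    "FCFP4": DescriptorBlock("FCFP4", "fingerprint", (), 1),
}

_NUMERIC_COMPUTERS = {
    "Molprops": compute_molprops,
    "Chi": compute_chi,
    "Estate": compute_estate,
}


@dataclass(frozen=True)
class DescriptorSubset:
    """A named set of descriptor blocks; combinations are unions of blocks."""

    label: str
    blocks: tuple[str, ...]

    @property
    def size(self) -> int:
        return sum(BLOCKS[b].size for b in self.blocks)


#: The standard ten subsets: the five base blocks, the four "+Molprops"
#: combinations, and the union of all five blocks (total accounting size 194).
DEFAULT_SUBSET_CONFIG: dict[str, list[str]] = {
    "Chi": ["Chi"],
    "ECFP6": ["ECFP6"],
    "Estate": ["Estate"],
    "FCFP4": ["FCFP4"],
    "Molprops": ["Molprops"],
    "Chi_Molprops": ["Chi", "Molprops"],
    "ECFP6_Molprops": ["ECFP6", "Molprops"],
    "Estate_Molprops": ["Estate", "Molprops"],
    "FCFP4_Molprops": ["FCFP4", "Molprops"],
    "Chi_ECFP6_Estate_FCFP4_Molprops": ["Chi", "ECFP6", "Estate", "FCFP4", "Molprops"],
}


def make_subsets(config: Mapping[str, Sequence[str]]) -> dict[str, DescriptorSubset]:
    """Instantiate named subsets from a {label: [block names]} config."""
    subsets: dict[str, DescriptorSubset] = {}
    for label, block_names in config.items():
        if label in subsets:
            raise ValueError(f"duplicate subset label {label!r}")
        unknown = [b for b in block_names if b not in BLOCKS]
        if unknown:
            raise ValueError(f"unknown descriptor blocks {unknown} in subset {label!r}")
        if len(set(block_names)) != len(block_names):
            raise ValueError(f"repeated block in subset {label!r}")
        subsets[label] = DescriptorSubset(label, tuple(block_names))
    return subsets


def default_subsets() -> dict[str, DescriptorSubset]:
    return make_subsets(DEFAULT_SUBSET_CONFIG)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Record-by-descriptor numeric matrix with provenance."""

    frame: pd.DataFrame  # index: record_id
    blocks: tuple[str, ...]
    fold_width: int
    failures: list[dict]

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index_label="record_id")
        meta = {
            "blocks": list(self.blocks),
            "fold_width": self.fold_width,
            "columns": self.columns,
            "failures": self.failures,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col="record_id")
        frame.index = frame.index.astype(str)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        return cls(frame, tuple(meta["blocks"]), meta["fold_width"], meta["failures"])


def _block_columns(block: DescriptorBlock, fold_width: int) -> list[str]:
    if block.kind == "numeric":
        return list(block.columns)
    return [f"{block.name}_{i:04d}" for i in range(fold_width)]


def compute_block_matrix(
    dataset: Dataset, block_name: str, fold_width: int = DEFAULT_FOLD_WIDTH
) -> DescriptorMatrix:
    """Compute one block for every record; failing records are excluded with
    a logged reason rather than aborting."""
    block = BLOCKS[block_name]
    cols = _block_columns(block, fold_width)
    rows, ids, failures = [], [], []
    for rec in dataset.records:
        smiles = rec.smiles_std if rec.smiles_std is not None else rec.smiles_raw
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            failures.append({"record_id": rec.record_id, "reason": "unparsable structure"})
            continue
        try:
            if block.kind == "numeric":
                vec = _NUMERIC_COMPUTERS[block_name](mol)
            else:
                _, vec = compute_fingerprint(mol, block_name, fold_width)
        except Exception as exc:  # noqa: BLE001 — failure is data, not control flow
            failures.append({"record_id": rec.record_id, "reason": str(exc)})
            continue
        if not np.all(np.isfinite(vec)):
            failures.append({"record_id": rec.record_id, "reason": "non-finite descriptor value"})
            continue
        rows.append(vec)
        ids.append(rec.record_id)
    frame = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(cols))),
                         index=pd.Index(ids, name="record_id"), columns=cols)
    return DescriptorMatrix(frame, (block_name,), fold_width, failures)


def assemble_subset_matrix(
    subset: DescriptorSubset, block_matrices: Mapping[str, DescriptorMatrix]
) -> DescriptorMatrix:
    """Join block matrices into the numeric matrix for one subset.

    Only records present in every member block are kept (a record that failed
    any block is excluded from the subset matrix).
    """
    frames = []
    failures: list[dict] = []
    fold_width = DEFAULT_FOLD_WIDTH
    for name in subset.blocks:
        bm = block_matrices[name]
        frames.append(bm.frame)
        failures.extend(bm.failures)
        fold_width = bm.fold_width
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    joined = pd.concat([f.loc[common] for f in frames], axis=1)
    return DescriptorMatrix(joined, tuple(subset.blocks), fold_width, failures)


def compute_matrices(
    dataset: Dataset,
    subsets: Mapping[str, DescriptorSubset],
    fold_width: int = DEFAULT_FOLD_WIDTH,
) -> dict[str, DescriptorMatrix]:
    """Compute each block once, then assemble every subset matrix."""
    needed = sorted({b for s in subsets.values() for b in s.blocks})
    block_matrices = {b: compute_block_matrix(dataset, b, fold_width) for b in needed}
    return {
        label: assemble_subset_matrix(subset, block_matrices)
        for label, subset in subsets.items()
    }
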