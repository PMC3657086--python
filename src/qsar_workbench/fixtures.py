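"""Synthetic structure–activity datasets with planted, tunable signal.

Molecules are assembled from a built-in fragment grammar (ring scaffolds ×
substituent prefixes), so every stage of the workbench — desalting,
clustering, descriptor computation, the full model matrix — is exercisable
without any external data.

Classification sets plant a carboxylic-acid substructure: a record is
positive iff the planted group is present, and labels are then flipped with
a configurable noise probability (noise 0.5 destroys the signal entirely;
noise 0 makes labels a deterministic function of structure).  Regression
sets compute the response as a linear combination of two molecular
properties (the Crippen lipophilicity estimate and the ring count) plus
Gaussian noise; the generating coefficients are recorded in the dataset's
``meta`` for recovery tests.

A configurable fraction of records is emitted as salt forms (counter-ion
appended), exercising desalting in-pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .prep import Dataset, MoleculeRecord

# scaffolds are format strings with three substitution points; substituents
# are SMILES prefixes valid at an aromatic or aliphatic ring position
SCAFFOLDS = (
    "{a}c1cc({b})cc({c})c1",
    "{a}c1ccc({b})c({c})c1",
    "{a}c1cc({b})cc({c})n1",
    "{a}c1cc({b})cnc1{c}",
    "{a}c1ccc2cc({b})c({c})cc2c1",
    "{a}C1CC({b})CC({c})C1",
    "{a}C1CCN(C({b})({c})C)CC1",
    "{a}c1cc({b})c(C)c({c})c1",
    "{a}c1ccc(C({b})({c})C)cc1",
    "{a}c1cc({b})c({c})s1",
    "{a}c1cc({b})c({c})o1",
    "{a}C1CC({b})C({c})O1",
)

#: Substituent pool for non-planted positions (no carboxylic acid).
SUBSTITUENTS = (
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "CCCC",
    "O", "OC", "OCC", "CO", "CCO",
    "N", "NC", "N(C)C", "CN", "CCN",
    "F", "Cl", "Br", "C(F)(F)F",
    "C#N", "C=C", "CC=C", "S", "SC", "C(=O)C", "C(=O)N", "CNC(=O)C",
)

#: The planted pharmacophore (carboxylic acid) attached at one site.
PHARMACOPHORE = "C(=O)O"
PHARMACOPHORE_SMARTS = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")

COUNTERIONS = (".Cl", ".Br", ".OS(=O)(=O)O")


@dataclass
class SyntheticSpec:
    """Specification for one synthetic dataset; identical specs give
    identical datasets."""

    n_records: int
    seed: int
    task: str  # classification | regression
    noise: float = 0.0  # label-flip probability or Gaussian sd
    class_balance: float = 0.5
    salt_fraction: float = 0.0
    coefficients: tuple[float, float] = (1.0, 0.75)  # (logP, ring count)


def _assemble(rng: np.random.Generator, planted: bool) -> str:
    scaffold = SCAFFOLDS[rng.integers(len(SCAFFOLDS))]
    subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(3)]
    if planted:
        subs[rng.integers(3)] = PHARMACOPHORE
    a, b, c = subs
    return scaffold.format(a=a, b=b, c=c)


def generate_molecules(n: int, seed: int, planted_flags=None,
                       salt_fraction: float = 0.0) -> list[str]:
    """Generate ``n`` valid SMILES from the fragment grammar.

    ``planted_flags`` optionally forces presence/absence of the planted
    pharmacophore per molecule.  Duplicates are allowed (the grammar is large
    enough that the duplicate rate stays below 5% for n ≤ 1000).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if planted_flags is None:
        planted_flags = [False] * n
    out: list[str] = []
    for i in range(n):
        for _ in range(50):
            smiles = _assemble(rng, bool(planted_flags[i]))
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            has = mol.HasSubstructMatch(PHARMACOPHORE_SMARTS)
            if has != bool(planted_flags[i]):
                continue
            break
        else:  # pragma: no cover — grammar always yields a valid structure
            raise RuntimeError("fragment grammar failed to produce a valid molecule")
        if salt_fraction > 0 and rng.random() < salt_fraction:
            smiles = smiles + COUNTERIONS[rng.integers(len(COUNTERIONS))]
        out.append(smiles)
    return out


def generate_classification_set(spec: SyntheticSpec) -> Dataset:
    """Binary classification set with a planted substructure signal.

    Exactly round(n·class_balance) records carry the pharmacophore (before
    noise), so the achieved positive fraction tracks the target; labels are
    then flipped independently with probability ``spec.noise``.
    """
    if spec.task != "classification":
        raise ValueError("spec.task must be 'classification'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_pos = int(round(n * spec.class_balance))
    if n_pos == 0 or n_pos == n:
        raise ValueError("class_balance leaves one class empty")
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_pos, replace=False)] = True
    smiles = generate_molecules(n, spec.seed + 1, planted_flags=flags,
                                salt_fraction=spec.salt_fraction)
    records = []
    for i, (smi, planted) in enumerate(zip(smiles, flags)):
        label = "active" if planted else "inactive"
        if spec.noise > 0 and rng.random() < spec.noise:
            label = "inactive" if label == "active" else "active"
        rec = MoleculeRecord(f"mol_{i:04d}", smi, response_raw=label)
        rec.response = label
        records.append(rec)
    return Dataset(
        records, endpoint_type="categorical", positive_class="active",
        label_set=["active", "inactive"],
        meta={"spec": spec.__dict__ | {"planted_fraction": float(flags.mean())}},
    )


def generate_regression_set(spec: SyntheticSpec) -> Dataset:
    """Continuous set: response = c1·logP + c2·ring_count + N(0, noise²)."""
    if spec.task != "regression":
        raise ValueError("spec.task must be 'regression'")
    rng = np.random.default_rng(spec.seed)
    smiles = generate_molecules(spec.n_records, spec.seed + 1,
                                salt_fraction=spec.salt_fraction)
    c1, c2 = spec.coefficients
    records = []
    signals = []
    for i, smi in enumerate(smiles):
        main = max(
            Chem.GetMolFrags(Chem.MolFromSmiles(smi), asMols=True),
            key=lambda m: m.GetNumHeavyAtoms(),
        )
        signal = c1 * Crippen.MolLogP(main) + c2 * rdMolDescriptors.CalcNumRings(main)
        signals.append(signal)
        value = signal + (rng.normal(0.0, spec.noise) if spec.noise > 0 else 0.0)
        rec = MoleculeRecord(f"mol_{i:04d}", smi, response_raw=float(value))
        rec.response = float(value)
        records.append(rec)
    return Dataset(
        records, endpoint_type="continuous",
        meta={
            "spec": spec.__dict__,
            "signal_sd": float(np.std(signals, ddof=1)),
        },
    )


def signal_sd(n: int, seed: int, coefficients=(1.0, 0.75)) -> float:
    """Sample standard deviation of the noise-free regression signal."""
    ds = generate_regression_set(
        SyntheticSpec(n, seed, "regression", noise=0.0, coefficients=coefficients)
    )
    return ds.meta["signal_sd"]


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a fixture as the id,smiles,response CSV the loader reads."""
    import pandas as pd

    pd.DataFrame(
        {
            "id": dataset.record_ids,
            "smiles": [r.smiles_raw for r in dataset.records],
            "response": [r.response_raw for r in dataset.records],
        }
    ).to_csv(path, index=False)
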