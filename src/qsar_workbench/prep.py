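"""Dataset loading, chemistry standardization and response preparation.

Every preparation step applied to a dataset is recorded, in order, in the
dataset's ``prep_spec``.  The spec is serialisable and can be replayed on raw
structures — this is what lets a published model apply *exactly* the same
preparation at prediction time (desalting, neutralisation, canonicalisation
and any response transform with its fitted constants).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

CHEMISTRY_STEPS = ("desalt", "neutralize", "canonicalize")
RESPONSE_STEPS = ("log_transform", "unit_variance_scale", "categorize")

#: SMARTS matching atoms whose formal charge can be removed by adding or
#: removing protons: anions not bonded to a cation (carboxylates, alkoxides,
#: thiolates...) and protonated cations (ammonium-type) not adjacent to an
#: anion.  Zwitterions such as amino acids are deliberately left untouched.
_NEUTRALIZE_SMARTS = "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
_NEUTRALIZE_PATTERN = Chem.MolFromSmarts(_NEUTRALIZE_SMARTS)


@dataclass
class MoleculeRecord:
    """One structure with its raw and standardized form and response values."""

    record_id: str
    smiles_raw: str
    response_raw: Any = None
    smiles_std: str | None = None
    response: Any = None
    prep_log: list[str] = field(default_factory=list)

    def copy(self) -> "MoleculeRecord":
        return replace(self, prep_log=list(self.prep_log))


@dataclass
class PrepStep:
    """A named preparation step with its (possibly fitted) parameters."""

    name: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "PrepStep":
        return cls(name=d["name"], params=dict(d.get("params", {})))


class Dataset:
    """Ordered collection of molecule records with one modelled endpoint.

    Parameters
    ----------
    records:
        The molecule records, in input order.
    endpoint_type:
        ``"continuous"`` or ``"categorical"``.
    positive_class:
        For binary categorical endpoints, the label treated as positive in
        sensitivity/specificity/ROC computations.
    """

    def __init__(
        self,
        records: Sequence[MoleculeRecord],
        endpoint_type: str,
        positive_class: str | None = None,
        prep_spec: Sequence[PrepStep] | None = None,
        label_set: Sequence[str] | None = None,
        load_report: dict | None = None,
        meta: dict | None = None,
    ):
        if endpoint_type not in ("continuous", "categorical"):
            raise ValueError(f"unknown endpoint_type {endpoint_type!r}")
        ids = [r.record_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")
        if positive_class is not None and endpoint_type != "categorical":
            raise ValueError("positive_class requires a categorical endpoint")
        self.records: list[MoleculeRecord] = list(records)
        self.endpoint_type = endpoint_type
        self.positive_class = positive_class
        self.prep_spec: list[PrepStep] = list(prep_spec or [])
        self.label_set: list[str] | None = list(label_set) if label_set else None
        self.load_report: dict = dict(load_report or {})
        self.meta: dict = dict(meta or {})
        if positive_class is not None and self.label_set is not None:
            if positive_class not in self.label_set:
                raise ValueError(
                    f"positive_class {positive_class!r} not in label set {self.label_set}"
                )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def record(self, record_id: str) -> MoleculeRecord:
        for r in self.records:
            if r.record_id == record_id:
                return r
        raise KeyError(record_id)

    def responses(self) -> pd.Series:
        return pd.Series(
            [r.response for r in self.records], index=self.record_ids, name="response"
        )

    def copy(self) -> "Dataset":
        return Dataset(
            [r.copy() for r in self.records],
            endpoint_type=self.endpoint_type,
            positive_class=self.positive_class,
            prep_spec=[PrepStep(s.name, dict(s.params)) for s in self.prep_spec],
            label_set=self.label_set,
            load_report=dict(self.load_report),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": self.record_ids,
                "smiles_raw": [r.smiles_raw for r in self.records],
                "smiles_std": [r.smiles_std for r in self.records],
                "response_raw": [r.response_raw for r in self.records],
                "response": [r.response for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    format: str,
    response_field: str,
    endpoint_type: str,
    *,
    id_field: str = "id",
    smiles_field: str = "smiles",
    positive_class: str | None = None,
) -> Dataset:
    """Read a structure–activity dataset from SMILES+CSV or SDF.

    Records whose structure fails to parse or whose response is missing are
    excluded and counted in ``dataset.load_report``; an empty result is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles_csv":
        rows = _read_smiles_csv(path, response_field, id_field, smiles_field)
    elif format == "sdf":
        rows = _read_sdf(path, response_field)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'smiles_csv' or 'sdf'")

    records: list[MoleculeRecord] = []
    excluded: list[dict] = []
    for rid, smiles, resp in rows:
        if resp is None or (isinstance(resp, float) and math.isnan(resp)) or (
            isinstance(resp, str) and not resp.strip()
        ):
            excluded.append({"record_id": rid, "reason": "missing response"})
            continue
        if smiles is None or Chem.MolFromSmiles(str(smiles)) is None:
            excluded.append({"record_id": rid, "reason": "unparsable structure"})
            continue
        if endpoint_type == "continuous":
            resp = float(resp)
        else:
            resp = str(resp)
        records.append(
            MoleculeRecord(record_id=str(rid), smiles_raw=str(smiles), response_raw=resp)
        )
    if not records:
        raise ValueError(f"zero parsable records in {path}")
    label_set = None
    if endpoint_type == "categorical":
        label_set = sorted({str(r.response_raw) for r in records})
    ds = Dataset(
        records,
        endpoint_type=endpoint_type,
        positive_class=positive_class,
        label_set=label_set,
        load_report={
            "n_loaded": len(records),
            "n_excluded": len(excluded),
            "excluded": excluded,
        },
    )
    for r in ds.records:
        r.response = r.response_raw
    return ds


def _read_smiles_csv(path, response_field, id_field, smiles_field):
    df = pd.read_csv(path)
    for col in (id_field, smiles_field, response_field):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    return [
        (row[id_field], row[smiles_field], row[response_field])
        for _, row in df.iterrows()
    ]


def _read_sdf(path, response_field):
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    rows = []
    for i, mol in enumerate(supplier):
        if mol is None:
            rows.append((f"sdf_{i}", None, None))
            continue
        rid = mol.GetProp("_Name") if mol.GetProp("_Name") else f"sdf_{i}"
        resp = mol.GetProp(response_field) if mol.HasProp(response_field) else None
        rows.append((rid, Chem.MolToSmiles(mol), resp))
    return rows


# ---------------------------------------------------------------------------
# Chemistry standardization
# ---------------------------------------------------------------------------

def desalt_mol(mol: Chem.Mol) -> Chem.Mol | None:
    """Keep the largest organic fragment.

    Carbon-free fragments (inorganic counter-ions, water, mineral acids) are
    discarded first; among the remaining fragments the one with the most
    heavy atoms is kept, ties broken by descending molecular weight, then by
    ascending canonical SMILES, so the result is independent of fragment
    order.  Returns None when no organic fragment remains (a pure salt
    vanishes entirely).
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags
               if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    if len(organic) == 1:
        return organic[0]
    return min(
        organic,
        key=lambda f: (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f)),
    )


def neutralize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Remove formal charges by protonating anions / deprotonating cations.

    Applies the fixed SMARTS rule :data:`_NEUTRALIZE_SMARTS`; charge-separated
    pairs (zwitterions, quaternary ammonium) are untouched.
    """
    mol = Chem.Mol(mol)
    matches = mol.GetSubstructMatches(_NEUTRALIZE_PATTERN)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(max(h_count - charge, 0))
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol


def standardize(dataset: Dataset, rules: Sequence[PrepStep | str]) -> Dataset:
    """Apply ordered chemistry rules, setting ``smiles_std`` on every record.

    A record whose structure vanishes under desalting (pure salt) is excluded
    with a logged reason.  ``canonicalize`` is always applied last even if not
    requested, since ``smiles_std`` must be a canonical string.
    """
    steps = [PrepStep(r) if isinstance(r, str) else r for r in rules]
    if not steps:
        raise ValueError("rules must be non-empty")
    for s in steps:
        if s.name not in CHEMISTRY_STEPS:
            raise ValueError(f"{s.name!r} is not a chemistry step")
    if steps[-1].name != "canonicalize":
        steps = steps + [PrepStep("canonicalize")]

    out = dataset.copy()
    kept: list[MoleculeRecord] = []
    excluded: list[dict] = []
    for rec in out.records:
        source = rec.smiles_std if rec.smiles_std is not None else rec.smiles_raw
        mol = Chem.MolFromSmiles(source)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            excluded.append({"record_id": rec.record_id, "reason": "unparsable structure"})
            continue
        ok = True
        for step in steps:
            if step.name == "desalt":
                mol = desalt_mol(mol)
                if mol is None:
                    excluded.append(
                        {"record_id": rec.record_id, "reason": "structure vanished under desalting"}
                    )
                    ok = False
                    break
            elif step.name == "neutralize":
                mol = neutralize_mol(mol)
            # canonicalize is the final serialisation below
        if not ok:
            continue
        rec.smiles_std = Chem.MolToSmiles(mol)
        rec.prep_log.extend(s.name for s in steps)
        kept.append(rec)
    if not kept:
        raise ValueError("standardization excluded every record")
    out.records = kept
    out.prep_spec.extend(PrepStep(s.name, dict(s.params)) for s in steps)
    report = out.load_report.setdefault("standardization", {})
    report["n_excluded"] = len(excluded)
    report["excluded"] = excluded
    return out


def apply_chemistry(prep_spec: Sequence[PrepStep], smiles: str) -> str | None:
    """Replay the chemistry steps of a prep spec on one raw SMILES.

    Returns the standardized canonical SMILES, or None if the structure is
    unparsable or vanishes.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return None
    for step in prep_spec:
        if step.name == "desalt":
            mol = desalt_mol(mol)
            if mol is None:
                return None
        elif step.name == "neutralize":
            mol = neutralize_mol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# Response preparation
# ---------------------------------------------------------------------------

def transform_response(dataset: Dataset, transform: str) -> Dataset:
    """Transform a continuous response: identity, log10 or unit variance.

    ``unit_variance`` centres on the mean and scales by the sample standard
    deviation (ddof=1); the fitted constants are stored in the prep spec so
    replay on new data reuses them.
    """
    if dataset.endpoint_type != "continuous":
        raise ValueError("response transforms require a continuous endpoint")
    out = dataset.copy()
    values = [float(r.response if r.response is not None else r.response_raw) for r in out.records]
    if transform == "identity":
        params: dict = {}
        new = values
    elif transform == "log10":
        for rec, v in zip(out.records, values):
            if v <= 0:
                raise ValueError(
                    f"log10 transform requires strictly positive responses; "
                    f"record {rec.record_id!r} has {v}"
                )
        params = {}
        new = [math.log10(v) for v in values]
    elif transform == "unit_variance":
        n = len(values)
        center = sum(values) / n
        if n < 2:
            raise ValueError("unit_variance requires at least 2 records")
        scale = math.sqrt(sum((v - center) ** 2 for v in values) / (n - 1))
        if scale == 0:
            raise ValueError("unit_variance on a constant response")
        params = {"center": center, "scale": scale}
        new = [(v - center) / scale for v in values]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    for rec, v in zip(out.records, new):
        rec.response = v
        rec.prep_log.append(_transform_step_name(transform))
    out.prep_spec.append(PrepStep(_transform_step_name(transform), {"transform": transform, **params}))
    return out


def _transform_step_name(transform: str) -> str:
    return {
        "identity": "identity",
        "log10": "log_transform",
        "unit_variance": "unit_variance_scale",
    }[transform]


def categorize_response(
    dataset: Dataset,
    mapping: dict | None = None,
    thresholds: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
    positive_class: str | None = None,
) -> Dataset:
    """Convert the response to categories via a label map or threshold list.

    With ``thresholds`` (strictly increasing), values fall into half-open
    bins that are lower-inclusive at the bottom: a value equal to a boundary
    goes to the *upper* class.  ``labels`` names the bins from lowest to
    highest (defaults ``class_0..class_k``).
    """
    out = dataset.copy()
    if (mapping is None) == (thresholds is None):
        raise ValueError("provide exactly one of mapping or thresholds")
    if mapping is not None:
        observed = {str(r.response if r.response is not None else r.response_raw) for r in out.records}
        unmapped = sorted(observed - {str(k) for k in mapping})
        if unmapped:
            raise ValueError(f"labels not covered by category map: {unmapped}")
        for rec in out.records:
            raw = str(rec.response if rec.response is not None else rec.response_raw)
            rec.response = str(mapping[raw] if raw in mapping else mapping[rec.response])
            rec.prep_log.append("categorize")
        params = {"mapping": {str(k): str(v) for k, v in mapping.items()}}
        label_set = sorted({str(v) for v in mapping.values()})
    else:
        thresholds = [float(t) for t in thresholds]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if labels is None:
            labels = [f"class_{i}" for i in range(len(thresholds) + 1)]
        if len(labels) != len(thresholds) + 1:
            raise ValueError("need len(thresholds)+1 labels")
        for rec in out.records:
            v = float(rec.response if rec.response is not None else rec.response_raw)
            k = sum(v >= t for t in thresholds)  # boundary goes to the upper class
            rec.response = str(labels[k])
            rec.prep_log.append("categorize")
        params = {"thresholds": thresholds, "labels": [str(l) for l in labels]}
        label_set = [str(l) for l in labels]
    out.endpoint_type = "categorical"
    out.label_set = label_set
    if positive_class is not None:
        if positive_class not in label_set:
            raise ValueError(f"positive_class {positive_class!r} not in {label_set}")
        out.positive_class = positive_class
    out.prep_spec.append(PrepStep("categorize", params))
    return out


def apply_response_steps(prep_spec: Sequence[PrepStep], value):
    """Replay response steps of a prep spec on one raw response value."""
    for step in prep_spec:
        if step.name == "log_transform":
            v = float(value)
            if v <= 0:
                raise ValueError(f"log10 replay on non-positive value {v}")
            value = math.log10(v)
        elif step.name == "unit_variance_scale":
            value = (float(value) - step.params["center"]) / step.params["scale"]
        elif step.name == "categorize":
            if "mapping" in step.params:
                m = step.params["mapping"]
                key = str(value)
                if key not in m:
                    raise ValueError(f"label {key!r} not in category map")
                value = m[key]
            else:
                th = step.params["thresholds"]
                labels = step.params["labels"]
                value = labels[sum(float(value) >= t for t in th)]
    return value


def replay_prep(prep_spec: Sequence[PrepStep], raw_dataset: Dataset) -> Dataset:
    """Replay a full prep spec on a raw dataset.

    Reproduces the prepared dataset bit-identically (fitted constants such as
    unit-variance centre/scale are taken from the spec, never refit).
    """
    chem_steps = [s for s in prep_spec if s.name in CHEMISTRY_STEPS]
    out = raw_dataset.copy()
    if chem_steps:
        out = standardize(out, [PrepStep(s.name, dict(s.params)) for s in chem_steps])
        # standardize() re-appends; keep the authoritative spec instead
        out.prep_spec = []
    for rec in out.records:
        value = rec.response_raw
        for step in prep_spec:
            if step.name in CHEMISTRY_STEPS:
                continue
            value = apply_response_steps([step], value)
        rec.response = value
    for step in prep_spec:
        if step.name == "categorize":
            out.endpoint_type = "categorical"
            if "mapping" in step.params:
                out.label_set = sorted(set(step.params["mapping"].values()))
            else:
                out.label_set = list(step.params["labels"])
    out.prep_spec = [PrepStep(s.name, dict(s.params)) for s in prep_spec]
    out.positive_class = raw_dataset.positive_class
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_prep_spec(prep_spec: Sequence[PrepStep], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"prep_spec": [s.to_dict() for s in prep_spec]}, sort_keys=False)
    )


def load_prep_spec(path: str | Path) -> list[PrepStep]:
    data = yaml.safe_load(Path(path).read_text())
    return [PrepStep.from_dict(d) for d in data["prep_spec"]]


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write the prepared dataset as CSV (prep spec saved separately)."""
    dataset.to_frame().to_csv(path, index=False)


def dataset_digest(dataset: Dataset) -> str:
    """Stable content digest over ids, standardized structures and responses."""
    import hashlib

    buf = io.StringIO()
    for r in dataset.records:
        buf.write(f"{r.record_id}\t{r.smiles_std or r.smiles_raw}\t{r.response}\n")
    return hashlib.sha1(buf.getvalue().encode()).hexdigest()[:16]
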