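"""Model publication: self-contained prediction bundles, reports, registry.

Publishing freezes a built model together with everything needed to apply it
to raw structures: the full ordered preparation spec (with fitted constants),
the descriptor configuration (blocks, fold width, exact column order), the
fitted estimator, the per-column training descriptor ranges and a generated
report.  ``predict`` replays the preparation and descriptor pipeline exactly,
so a salt form and its desalted parent give identical predictions, and the
bundle applied to its own training structures reproduces the stored training
predictions bit-identically.

Applicability is reported as simple per-column range warnings: a prediction
is flagged when any non-fingerprint descriptor falls outside the range seen
in training.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.pipeline import Pipeline

from .descriptors import BLOCKS, compute_fingerprint, _NUMERIC_COMPUTERS
from .model_matrix import ModelResult, Project, predict_with_scores
from .prep import apply_chemistry, load_prep_spec, save_prep_spec


@dataclass
class PublishedModel:
    """Handle to a published bundle directory."""

    bundle_id: str
    path: Path
    manifest: dict

    @property
    def content_digest(self) -> str:
        return self.manifest["content_digest"]


def _content_digest(bundle_dir: Path) -> str:
    """Digest over the bundle's reproducible content files."""
    h = hashlib.sha1()
    for name in sorted(("prep_spec.yaml", "descriptor_config.json",
                        "train_predictions.csv", "training_ranges.json",
                        "stats.json")):
        p = bundle_dir / name
        if p.exists():
            h.update(name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()[:16]


def publish(result: ModelResult, project: Project, registry_dir: str | Path | None = None,
            ) -> PublishedModel:
    """Freeze a built model into a self-contained bundle and register it.

    Two publishes of the same model get distinct bundle ids but identical
    content digests.
    """
    if result.status != "built":
        raise ValueError(f"cannot publish model {result.model_id}: status is "
                         f"{result.status!r} ({result.failure_reason})")
    registry_dir = Path(registry_dir) if registry_dir else project.root / "published"
    registry_dir.mkdir(parents=True, exist_ok=True)
    registry_path = registry_dir / "registry.json"
    registry = json.loads(registry_path.read_text()) if registry_path.exists() else []
    bundle_id = f"{result.model_id}-{len(registry):03d}"
    bundle_dir = registry_dir / bundle_id
    bundle_dir.mkdir(parents=True, exist_ok=True)

    ds = project.dataset
    subset = project.subsets[result.subset_label]
    matrix = project.matrices[result.subset_label]
    train_frame = matrix.frame.loc[result.train_predictions.index]

    save_prep_spec(ds.prep_spec, bundle_dir / "prep_spec.yaml")
    descriptor_config = {
        "blocks": list(subset.blocks),
        "fold_width": matrix.fold_width,
        "columns": list(matrix.frame.columns),
    }
    (bundle_dir / "descriptor_config.json").write_text(
        json.dumps(descriptor_config, indent=1))
    joblib.dump(result.fitted_model, bundle_dir / "model.joblib")

    # per-column training ranges for the applicability warning; fingerprint
    # columns are excluded (sparse counts are not a meaningful range check)
    numeric_cols = [c for b in subset.blocks if BLOCKS[b].kind == "numeric"
                    for c in BLOCKS[b].columns]
    ranges = {
        c: [float(train_frame[c].min()), float(train_frame[c].max())]
        for c in numeric_cols
    }
    (bundle_dir / "training_ranges.json").write_text(json.dumps(ranges, indent=1))

    result.train_predictions.rename("prediction").to_csv(
        bundle_dir / "train_predictions.csv", index_label="record_id")
    stats = {
        "train": result.train_stats.to_dict(include_curves=True),
        "test": result.test_stats.to_dict(include_curves=True),
    }
    (bundle_dir / "stats.json").write_text(json.dumps(stats, indent=1))

    manifest = {
        "bundle_id": bundle_id,
        "model_id": result.model_id,
        "provenance": {
            "split_label": result.split_label,
            "subset_label": result.subset_label,
            "learner_name": result.learner_name,
        },
        "endpoint_type": ds.endpoint_type,
        "positive_class": ds.positive_class,
        "dataset_digest": project.data_digest,
        "n_train": int(len(result.train_predictions)),
        "n_test": int(len(result.test_predictions)),
        "published_at": datetime.now(timezone.utc).isoformat(),
    }
    manifest["content_digest"] = _content_digest(bundle_dir)
    (bundle_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    report = generate_report(bundle_dir)
    (bundle_dir / "report.html").write_text(report)

    registry.append({
        "bundle_id": bundle_id,
        "endpoint_type": ds.endpoint_type,
        "provenance": manifest["provenance"],
        "published_at": manifest["published_at"],
        "content_digest": manifest["content_digest"],
    })
    registry_path.write_text(json.dumps(registry, indent=1))
    return PublishedModel(bundle_id, bundle_dir, manifest)


def load_bundle(path: str | Path) -> PublishedModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    return PublishedModel(manifest["bundle_id"], path, manifest)


def list_published(registry_dir: str | Path) -> list[dict]:
    """Machine-readable listing of published bundles."""
    registry_path = Path(registry_dir) / "registry.json"
    if not registry_path.exists():
        return []
    return json.loads(registry_path.read_text())


def _descriptor_row(smiles_std: str, config: dict) -> np.ndarray | None:
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        return None
    parts = []
    for block_name in config["blocks"]:
        block = BLOCKS[block_name]
        if block.kind == "numeric":
            parts.append(_NUMERIC_COMPUTERS[block_name](mol))
        else:
            _, folded = compute_fingerprint(mol, block_name, config["fold_width"])
            parts.append(folded)
    return np.concatenate(parts)


def predict(bundle: PublishedModel | str | Path, structures: Sequence[str],
            record_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Apply a published bundle to raw structures.

    Every structure goes through the bundle's own preparation (desalting,
    neutralisation, canonicalisation) and descriptor pipeline before scoring.
    Unparsable structures get a per-record error entry; out-of-range
    descriptors get per-record warnings; the batch always continues.
    """
    if not isinstance(bundle, PublishedModel):
        bundle = load_bundle(bundle)
    bdir = bundle.path
    prep_spec = load_prep_spec(bdir / "prep_spec.yaml")
    config = json.loads((bdir / "descriptor_config.json").read_text())
    ranges = json.loads((bdir / "training_ranges.json").read_text())
    model = joblib.load(bdir / "model.joblib")
    chem_steps = [s for s in prep_spec if s.name in ("desalt", "neutralize", "canonicalize")]
    pos = bundle.manifest.get("positive_class")

    if record_ids is None:
        record_ids = [f"query_{i}" for i in range(len(structures))]
    rows = []
    feature_rows = []
    ok_index = []
    for rid, smi in zip(record_ids, structures):
        std = apply_chemistry(chem_steps, smi)
        if std is None:
            rows.append({"record_id": rid, "input_smiles": smi, "prepared_smiles": None,
                         "prediction": None, "warnings": "",
                         "error": "unparsable or vanished structure"})
            continue
        vec = _descriptor_row(std, config)
        if vec is None or not np.all(np.isfinite(vec)):
            rows.append({"record_id": rid, "input_smiles": smi, "prepared_smiles": std,
                         "prediction": None, "warnings": "",
                         "error": "descriptor computation failed"})
            continue
        warnings = []
        col_index = {c: i for i, c in enumerate(config["columns"])}
        for col, (lo, hi) in ranges.items():
            v = vec[col_index[col]]
            if v < lo or v > hi:
                warnings.append(f"{col}={v:.4g} outside training range [{lo:.4g}, {hi:.4g}]")
        rows.append({"record_id": rid, "input_smiles": smi, "prepared_smiles": std,
                     "prediction": None, "warnings": "; ".join(warnings), "error": None})
        feature_rows.append(vec)
        ok_index.append(len(rows) - 1)

    if feature_rows:
        X = np.vstack(feature_rows)
        y_pred, scores = predict_with_scores(model, X, pos)
        for i, row_idx in enumerate(ok_index):
            rows[row_idx]["prediction"] = y_pred[i]
            if scores is not None:
                rows[row_idx]["score"] = float(scores[i])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def tree_descriptor_usage(model, feature_columns: Sequence[str]) -> pd.DataFrame:
    """Descriptor-usage frequency for tree learners: the number of questions
    (internal branch nodes) asking about each descriptor."""
    final = model[-1] if isinstance(model, Pipeline) else model
    counts = np.zeros(len(feature_columns), dtype=int)
    estimators = getattr(final, "estimators_", [final])
    for est in estimators:
        tree = est.tree_
        for f in tree.feature:
            if f >= 0:
                counts[f] += 1
    return (
        pd.DataFrame({"descriptor": list(feature_columns), "n_questions": counts})
        .sort_values(["n_questions", "descriptor"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def generate_report(bundle_dir: str | Path) -> str:
    """Deterministic HTML model report for a bundle.

    Sections: provenance and preparation steps, split definition, descriptor
    configuration, learner, train/test statistics (with confusion matrix for
    categorical endpoints), and — for tree learners — the descriptor-usage
    frequency table.  Regenerating from the same bundle is byte-identical
    (no timestamps inside the report body).
    """
    bdir = Path(bundle_dir)
    manifest = json.loads((bdir / "manifest.json").read_text())
    stats = json.loads((bdir / "stats.json").read_text())
    config = json.loads((bdir / "descriptor_config.json").read_text())
    prep_spec = load_prep_spec(bdir / "prep_spec.yaml")
    prov = manifest["provenance"]

    def esc(x):
        return html.escape(str(x))

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>Model report {esc(manifest['model_id'])}</title></head><body>",
        f"<h1>Model report: {esc(manifest['model_id'])}</h1>",
        "<h2>Provenance</h2><ul>",
        f"<li>Split: {esc(prov['split_label'])}</li>",
        f"<li>Descriptor subset: {esc(prov['subset_label'])}</li>",
        f"<li>Learner: {esc(prov['learner_name'])}</li>",
        f"<li>Endpoint: {esc(manifest['endpoint_type'])}"
        + (f" (positive class: {esc(manifest['positive_class'])})"
           if manifest.get("positive_class") else "") + "</li>",
        f"<li>Dataset digest: {esc(manifest['dataset_digest'])}</li>",
        f"<li>Training records: {manifest['n_train']}; test records: {manifest['n_test']}</li>",
        "</ul>",
        "<h2>Data preparation steps</h2><ol>",
        *[f"<li>{esc(s.name)} {esc(json.dumps(s.params, sort_keys=True))}</li>"
          for s in prep_spec],
        "</ol>",
        "<h2>Descriptor configuration</h2>",
        f"<p>Blocks: {esc(', '.join(config['blocks']))}; fold width "
        f"{config['fold_width']}; {len(config['columns'])} numeric columns.</p>",
        "<h2>Statistics</h2>",
    ]
    for side in ("train", "test"):
        st = stats[side]
        parts.append(f"<h3>{side.capitalize()} set</h3><table border='1'>")
        if manifest["endpoint_type"] == "categorical":
            parts.append(
                "<tr><th></th><th>pred +</th><th>pred −</th></tr>"
                f"<tr><th>true +</th><td>{st.get('tp')}</td><td>{st.get('fn')}</td></tr>"
                f"<tr><th>true −</th><td>{st.get('fp')}</td><td>{st.get('tn')}</td></tr>"
            )
            parts.append("</table><ul>")
            for key in ("sensitivity", "specificity", "accuracy", "roc_auc"):
                if key in st:
                    parts.append(f"<li>{key}: {st[key]:.4f}</li>")
            parts.append("</ul>")
        else:
            parts.append("</table><ul>")
            for key in ("r_squared", "rmse", "rec_area"):
                if key in st:
                    parts.append(f"<li>{key}: {st[key]:.4f}</li>")
            parts.append("</ul>")

    if prov["learner_name"] in ("rp_tree", "rp_forest"):
        model = joblib.load(bdir / "model.joblib")
        usage = tree_descriptor_usage(model, config["columns"])
        used = usage[usage["n_questions"] > 0]
        parts.append("<h2>Descriptor usage (number of questions)</h2><table border='1'>")
        parts.append("<tr><th>Descriptor</th><th>Number of questions</th></tr>")
        for _, row in used.iterrows():
            parts.append(f"<tr><td>{esc(row['descriptor'])}</td>"
                         f"<td>{int(row['n_questions'])}</td></tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "\n".join(parts)
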