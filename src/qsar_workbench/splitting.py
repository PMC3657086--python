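"""Train/test splitting algorithms and chemical-space split diagnostics.

Five split policies are provided:

- ``random`` — uniform sampling without replacement;
- ``stratified`` — random sampling within response quantile bins (or classes);
- ``independent_clusters_optimized`` — whole fingerprint clusters assigned to
  the test side so that the achieved test fraction is as close as possible to
  the target (exact subset-sum optimisation); the test chemistry is thereby
  deliberately dissimilar to the training chemistry;
- ``random_per_cluster`` — stratified sampling *within* each cluster, keeping
  test chemistry similar to training chemistry;
- ``predefined`` — an externally supplied record→{train,test} table.

``analyze_split`` embeds the molecules with classical metric MDS on Tanimoto
distances and summarises train/test overlap by each test record's nearest
training-set similarity — the diagnostic that reveals whether a split's test
statistics are flattered by train/test similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .prep import Dataset

DEFAULT_SIMILARITY_THRESHOLD = 0.7
DEFAULT_FINGERPRINT_KIND = "ECFP6"


@dataclass
class SplitSpec:
    label: str
    algorithm: str
    train_fraction: float | None = None
    seed: int | None = None
    cluster_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "algorithm": self.algorithm,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "cluster_params": self.cluster_params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitSpec":
        return cls(
            label=d["label"],
            algorithm=d["algorithm"],
            train_fraction=d.get("train_fraction"),
            seed=d.get("seed"),
            cluster_params=dict(d.get("cluster_params", {})),
        )


@dataclass
class SplitAssignment:
    """A named partition of record ids into train and test."""

    spec: SplitSpec
    train_ids: list[str]
    test_ids: list[str]
    cluster_of: dict[str, int] | None = None

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"ids on both sides of split: {sorted(overlap)[:5]}")

    @property
    def label(self) -> str:
        return self.spec.label

    def side_of(self, record_id: str) -> str:
        if record_id in set(self.train_ids):
            return "train"
        return "test"

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid in self.train_ids:
                fh.write(f"{rid}\ttrain\n")
            for rid in self.test_ids:
                fh.write(f"{rid}\ttest\n")


def _check_partition(dataset: Dataset, assignment: SplitAssignment) -> None:
    all_ids = set(dataset.record_ids)
    got = set(assignment.train_ids) | set(assignment.test_ids)
    if got != all_ids:
        raise ValueError("split does not partition the dataset id set")


# ---------------------------------------------------------------------------
# Random and stratified splits
# ---------------------------------------------------------------------------

def random_split(
    dataset: Dataset, train_fraction: float, seed: int, label: str | None = None
) -> SplitAssignment:
    """Uniform split: round(n·train_fraction) records to train."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("train_fraction leaves one side of the split empty")
    rng = np.random.default_rng(seed)
    ids = np.array(dataset.record_ids)
    perm = rng.permutation(n)
    spec = SplitSpec(label or f"Rand{int(train_fraction * 100)}", "random",
                     train_fraction, seed)
    return SplitAssignment(
        spec,
        train_ids=sorted(ids[perm[:n_train]].tolist()),
        test_ids=sorted(ids[perm[n_train:]].tolist()),
    )


def stratified_split(
    dataset: Dataset,
    train_fraction: float,
    seed: int,
    n_bins: int = 5,
    label: str | None = None,
) -> SplitAssignment:
    """Random split within response strata.

    Continuous endpoints are binned into ``n_bins`` quantile bins; categorical
    endpoints use the classes as bins.  A bin with fewer than 2 records is
    merged with its lower neighbour (with a warning).  Each bin's train count
    is round(bin size × fraction), so per-bin fractions deviate from the
    target by at most one record.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    ids = np.array(dataset.record_ids)
    resp = dataset.responses()
    if dataset.endpoint_type == "categorical":
        codes = pd.Categorical(resp.astype(str)).codes
    else:
        binned = pd.qcut(resp.astype(float), q=n_bins, duplicates="drop")
        codes = pd.Categorical(binned).codes
    codes = np.asarray(codes)

    # merge undersized bins downward
    for b in sorted(set(codes)):
        if (codes == b).sum() < 2:
            target = b - 1 if b > 0 else b + 1
            warnings.warn(f"stratum {b} has <2 records; merged with neighbour {target}")
            codes[codes == b] = target

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for b in sorted(set(codes)):
        members = ids[codes == b]
        k = int(round(len(members) * train_fraction))
        k = min(max(k, 0), len(members))
        perm = rng.permutation(len(members))
        train.extend(members[perm[:k]].tolist())
        test.extend(members[perm[k:]].tolist())
    if not train or not test:
        raise ValueError("stratified split left one side empty")
    spec = SplitSpec(label or f"Strat{int(train_fraction * 100)}", "stratified",
                     train_fraction, seed)
    return SplitAssignment(spec, sorted(train), sorted(test))


# ---------------------------------------------------------------------------
# Fingerprints, similarity, clustering
# ---------------------------------------------------------------------------

def _bit_fingerprints(dataset: Dataset, kind: str = DEFAULT_FINGERPRINT_KIND):
    if kind == "ECFP6":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
    elif kind == "FCFP4":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=2048,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    fps = []
    for rec in dataset.records:
        smiles = rec.smiles_std if rec.smiles_std is not None else rec.smiles_raw
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"cannot compute fingerprint for record {rec.record_id!r}")
        fps.append(gen.GetFingerprint(mol))
    return fps


def similarity_matrix(dataset: Dataset, kind: str = DEFAULT_FINGERPRINT_KIND) -> np.ndarray:
    """Pairwise Tanimoto similarity over the dataset, in record order."""
    fps = _bit_fingerprints(dataset, kind)
    n = len(fps)
    sim = np.eye(n)
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        sim[i, :i] = row
        sim[:i, i] = row
    return sim


def cluster_molecules(
    dataset: Dataset,
    fingerprint_kind: str = DEFAULT_FINGERPRINT_KIND,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    similarity: np.ndarray | None = None,
) -> dict[str, int]:
    """Sphere-exclusion (Butina-style) clustering on Tanimoto similarity.

    At each round the unassigned molecule with the most unassigned neighbours
    (similarity ≥ threshold) becomes a centroid and claims those neighbours;
    neighbour lists are recomputed over the remaining molecules each round.
    Ties are broken by input order, so the result is deterministic.  Returns
    record_id → cluster index (clusters numbered in creation order).
    """
    ids = dataset.record_ids
    sim = similarity if similarity is not None else similarity_matrix(dataset, fingerprint_kind)
    n = len(ids)
    neighbour = sim >= similarity_threshold
    np.fill_diagonal(neighbour, False)
    unassigned = np.ones(n, dtype=bool)
    cluster_of: dict[str, int] = {}
    cluster_idx = 0
    while unassigned.any():
        counts = (neighbour & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the first maximum: input-order tie-break
        members = np.where(unassigned & neighbour[centroid])[0].tolist()
        for m in [centroid] + members:
            cluster_of[ids[m]] = cluster_idx
            unassigned[m] = False
        cluster_idx += 1
    return cluster_of


def cluster_properties(
    dataset: Dataset,
    vectors: np.ndarray,
    distance_threshold: float,
) -> dict[str, int]:
    """Sphere-exclusion clustering on Euclidean distance over unit-scaled
    descriptor vectors (property-space analogue of fingerprint clustering)."""
    x = np.asarray(vectors, dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    sim = -d  # reuse the similarity machinery with a negated distance
    return cluster_molecules(dataset, similarity=sim, similarity_threshold=-distance_threshold)


# ---------------------------------------------------------------------------
# Cluster-based splits
# ---------------------------------------------------------------------------

def independent_cluster_split(
    dataset: Dataset,
    cluster_of: Mapping[str, int],
    train_fraction: float,
    seed: int,
    label: str | None = None,
) -> SplitAssignment:
    """Assign whole clusters to test so the achieved test fraction is as close
    as possible to (1 − train_fraction).

    The optimisation is exact: a subset-sum dynamic program over cluster sizes
    finds the achievable test-set size closest to the target (ties: the
    smaller test set), then reconstructs one optimal subset; the cluster order
    fed to the DP is seed-shuffled, so ties among optimal subsets are broken
    by the seed.  No cluster ever spans both sides.
    """
    clusters: dict[int, list[str]] = {}
    for rid in dataset.record_ids:
        clusters.setdefault(cluster_of[rid], []).append(rid)
    if len(clusters) < 2:
        raise ValueError("cannot form independent split from a single cluster")
    n = len(dataset)
    target = n * (1.0 - train_fraction)

    rng = np.random.default_rng(seed)
    keys = list(clusters)
    rng.shuffle(keys)
    sizes = [len(clusters[k]) for k in keys]

    # reachable[j][s] = True if some subset of the first j clusters sums to s
    m = len(sizes)
    reachable = np.zeros((m + 1, n + 1), dtype=bool)
    reachable[0, 0] = True
    for j, sz in enumerate(sizes, start=1):
        reachable[j] = reachable[j - 1].copy()
        if sz:
            reachable[j, sz:] |= reachable[j - 1, : n + 1 - sz]
    achievable = np.where(reachable[m])[0]
    # exclude the empty and full test set: both sides must be non-empty
    achievable = achievable[(achievable > 0) & (achievable < n)]
    if achievable.size == 0:
        raise ValueError("cannot form independent split with non-empty sides")
    best = int(achievable[np.lexsort((achievable, np.abs(achievable - target)))[0]])

    # reconstruct one subset achieving `best`; where both including and
    # excluding a cluster stay feasible, the (seeded) rng decides
    test_keys = []
    s = best
    for j in range(m, 0, -1):
        sz = sizes[j - 1]
        can_exclude = reachable[j - 1, s]
        can_include = sz <= s and reachable[j - 1, s - sz]
        include = can_include and (not can_exclude or rng.random() < 0.5)
        if include:
            test_keys.append(keys[j - 1])
            s -= sz
    assert s == 0
    test_ids = sorted(rid for k in test_keys for rid in clusters[k])
    train_ids = sorted(set(dataset.record_ids) - set(test_ids))
    spec = SplitSpec(
        label or f"IndOpt{int(train_fraction * 100)}",
        "independent_clusters_optimized",
        train_fraction,
        seed,
    )
    return SplitAssignment(spec, train_ids, test_ids, cluster_of=dict(cluster_of))


def random_per_cluster_split(
    dataset: Dataset,
    cluster_of: Mapping[str, int],
    train_fraction: float,
    seed: int,
    label: str | None = None,
) -> SplitAssignment:
    """Sample round(size·fraction) members of each cluster into train.

    Singleton clusters are assigned by an independent Bernoulli(train_fraction)
    draw, so the overall train fraction converges to the target as the number
    of singletons grows.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    clusters: dict[int, list[str]] = {}
    for rid in dataset.record_ids:
        clusters.setdefault(cluster_of[rid], []).append(rid)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for key in sorted(clusters):
        members = clusters[key]
        if len(members) == 1:
            (train if rng.random() < train_fraction else test).extend(members)
            continue
        k = int(round(len(members) * train_fraction))
        k = min(max(k, 0), len(members))
        perm = rng.permutation(len(members))
        arr = np.array(members)
        train.extend(arr[perm[:k]].tolist())
        test.extend(arr[perm[k:]].tolist())
    if not train or not test:
        raise ValueError("random-per-cluster split left one side empty")
    spec = SplitSpec(
        label or f"RPC{int(train_fraction * 100)}", "random_per_cluster",
        train_fraction, seed,
    )
    return SplitAssignment(spec, sorted(train), sorted(test), cluster_of=dict(cluster_of))


def load_predefined_split(
    dataset: Dataset, path: str | Path, label: str = "from_file"
) -> SplitAssignment:
    """Load a two-column (record_id, train|test) table covering every record."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", "\t").split("\t") if p.strip()]
        if len(parts) != 2:
            parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected two columns")
        rid, side = parts[0].strip(), parts[1].strip().lower()
        if side not in ("train", "test"):
            raise ValueError(f"{path}:{line_no}: side must be 'train' or 'test', got {side!r}")
        if rid in mapping:
            raise ValueError(f"{path}:{line_no}: duplicate record id {rid!r}")
        mapping[rid] = side
    ids = set(dataset.record_ids)
    missing = sorted(ids - set(mapping))
    extra = sorted(set(mapping) - ids)
    if missing or extra:
        raise ValueError(
            f"predefined split mismatch: missing ids {missing[:10]}, unknown ids {extra[:10]}"
        )
    train = sorted(r for r, s in mapping.items() if s == "train")
    test = sorted(r for r, s in mapping.items() if s == "test")
    n = len(dataset)
    spec = SplitSpec(label, "predefined", train_fraction=len(train) / n if n else None)
    return SplitAssignment(spec, train, test)


# ---------------------------------------------------------------------------
# Split diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SplitAnalysis:
    coordinates: pd.DataFrame  # index record_id, columns x, y, side
    stress: float
    overlap: dict  # mean/max/min nearest-train similarity of test records
    nearest_train_similarity: pd.Series


def classical_mds(distance: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) metric MDS via double centring.

    Returns coordinates (n × n_components) and a stress value
    (normalised residual between embedded and input distances).  The
    embedding is defined up to rotation/reflection.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval[:n_components], 0.0, None)
    coords = eigvec[:, :n_components] * np.sqrt(pos)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    denom = np.sqrt((d ** 2).sum())
    stress = float(np.sqrt(((emb - d) ** 2).sum()) / denom) if denom > 0 else 0.0
    return coords, stress


def analyze_split(
    dataset: Dataset,
    assignment: SplitAssignment,
    fingerprint_kind: str = DEFAULT_FINGERPRINT_KIND,
) -> SplitAnalysis:
    """2-D chemical-space embedding of a split plus a train/test overlap summary.

    Coordinates come from classical metric MDS on Tanimoto distance
    (1 − similarity).  The overlap summary reports, for each test record, its
    highest similarity to any training record; a low mean marks a deliberately
    hard (cluster-independent) test set.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 records to analyze a split")
    _check_partition(dataset, assignment)
    sim = similarity_matrix(dataset, fingerprint_kind)
    dist = 1.0 - sim
    if np.allclose(dist, 0.0):
        warnings.warn("all structures identical: degenerate embedding at the origin")
        coords = np.zeros((len(dataset), 2))
        stress = 0.0
    else:
        coords, stress = classical_mds(dist)
    ids = dataset.record_ids
    side = ["train" if rid in set(assignment.train_ids) else "test" for rid in ids]
    frame = pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], "side": side},
        index=pd.Index(ids, name="record_id"),
    )
    train_pos = [i for i, s in enumerate(side) if s == "train"]
    test_pos = [i for i, s in enumerate(side) if s == "test"]
    nn = pd.Series(
        sim[np.ix_(test_pos, train_pos)].max(axis=1),
        index=[ids[i] for i in test_pos],
        name="nearest_train_similarity",
    )
    overlap = {
        "mean_nearest_train_similarity": float(nn.mean()),
        "min_nearest_train_similarity": float(nn.min()),
        "max_nearest_train_similarity": float(nn.max()),
        "n_train": len(train_pos),
        "n_test": len(test_pos),
    }
    return SplitAnalysis(frame, stress, overlap, nn)


# ---------------------------------------------------------------------------
# Standard split batteries
# ---------------------------------------------------------------------------

def standard_splits(
    dataset: Dataset,
    seed: int,
    fractions: Sequence[float] = (0.5, 0.75),
    predefined_path: str | Path | None = None,
    fingerprint_kind: str = DEFAULT_FINGERPRINT_KIND,
    similarity_threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> dict[str, SplitAssignment]:
    """The standard battery: {random, independent-clusters, random-per-cluster}
    × the given fractions, plus an optional predefined split (seven splits in
    the default configuration)."""
    cluster_of = cluster_molecules(dataset, fingerprint_kind, similarity_threshold)
    out: dict[str, SplitAssignment] = {}
    for i, f in enumerate(fractions):
        pct = int(f * 100)
        out[f"Rand{pct}"] = random_split(dataset, f, seed + i, label=f"Rand{pct}")
        out[f"IndOpt{pct}"] = independent_cluster_split(
            dataset, cluster_of, f, seed + 10 + i, label=f"IndOpt{pct}"
        )
        out[f"RPC{pct}"] = random_per_cluster_split(
            dataset, cluster_of, f, seed + 20 + i, label=f"RPC{pct}"
        )
    if predefined_path is not None:
        out["FromFile"] = load_predefined_split(dataset, predefined_path, label="FromFile")
    return out
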