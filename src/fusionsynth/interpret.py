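"""Interpretability: PCA projection of unique vs. common feature clouds.

For every fusion block (MAFFB_1..3 in the fusion network, MAFFB_4..6 in the
generator) the per-sample feature maps are reduced to vectors by global
average pooling per channel, labelled by role — the two modalities' unique
features versus the block's fused common features — and projected to 2-D or
3-D by principal component analysis.  If the fusion works, the common-feature
cloud should sit between the two unique clouds; the ``centrality_diagnostic``
quantifies this (0 = exactly at the midpoint of the two unique centroids,
0.5 = coincident with one of them).  It is a descriptive diagnostic of a
particular trained model, not a correctness gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .gan import SynthesisModel
from .nn import Tensor

ROLES = ("unique-1", "unique-2", "common")
BLOCK_IDS = tuple(f"MAFFB_{i}" for i in range(1, 7))


@dataclass
class FeatureCloud:
    """Per-role point sets for one fusion block; rows are samples."""

    block_id: str
    vectors: dict[str, np.ndarray]      # role -> (n_samples, dim)

    def __post_init__(self):
        dims = {v.shape[1] for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"mixed vector dimensions in cloud: {dims}")

    @property
    def points(self) -> list[tuple[np.ndarray, str, str]]:
        return [(vec, role, self.block_id)
                for role in ROLES if role in self.vectors
                for vec in self.vectors[role]]

    def stacked(self) -> np.ndarray:
        return np.concatenate([self.vectors[r] for r in ROLES
                               if r in self.vectors], axis=0)


def _gap(t: Tensor) -> np.ndarray:
    """Global average pooling per channel: (N,C,H,W) -> (N,C)."""
    return t.data.mean(axis=(2, 3))


def collect_features(model: SynthesisModel,
                     pairs: list[tuple[np.ndarray, np.ndarray]],
                     block_ids: tuple[str, ...] = BLOCK_IDS
                     ) -> dict[str, FeatureCloud]:
    """Run the model over (x1, x2) sample pairs and harvest feature clouds.

    ``pairs`` holds (1,H,W) or (H,W) arrays in the scaled range.  Features
    are collected in eval mode, so re-collection with the same checkpoint
    is deterministic.
    """
    unknown = set(block_ids) - set(BLOCK_IDS)
    if unknown:
        raise ValueError(f"unknown block ids: {sorted(unknown)}")
    was_training = model.training
    model.eval()
    taps = model.fusion.tap_levels
    store: dict[str, dict[str, list[np.ndarray]]] = {
        b: {r: [] for r in ROLES} for b in block_ids}
    for x1, x2 in pairs:
        x1 = np.asarray(x1, dtype=np.float64).reshape(1, 1, *np.shape(x1)[-2:])
        x2 = np.asarray(x2, dtype=np.float64).reshape(1, 1, *np.shape(x2)[-2:])
        fs1 = model.backbone1.encode(Tensor(x1), "source1")
        fs2 = model.backbone2.encode(Tensor(x2), "source2")
        common = model.fusion(fs1, fs2)
        _, gen_common = model.generator.forward_collect(common, fs1, fs2)
        for b in block_ids:
            k = int(b.split("_")[1])
            # fusion blocks 1..3 run shallow->deep; generator blocks 4..6 deep->shallow
            lvl = taps[k - 1] if k <= 3 else list(reversed(taps))[k - 4]
            com = common[lvl] if k <= 3 else gen_common[b]
            store[b]["unique-1"].append(_gap(fs1[lvl])[0])
            store[b]["unique-2"].append(_gap(fs2[lvl])[0])
            store[b]["common"].append(_gap(com)[0])
    model.train(was_training)
    return {b: FeatureCloud(b, {r: np.stack(v) for r, v in roles.items()})
            for b, roles in store.items()}


@dataclass
class ProjectedCloud:
    block_id: str
    vectors: dict[str, np.ndarray]      # role -> (n_samples, dims)
    explained_variance_ratio: np.ndarray = field(
        default_factory=lambda: np.array([]))


def pca_project(cloud: FeatureCloud, dims: int = 2) -> ProjectedCloud:
    """Mean-centred maximum-variance projection of the whole cloud.

    The sign of each principal axis is fixed by requiring the largest-
    magnitude loading to be positive, so projections are reproducible.
    """
    X = cloud.stacked()
    if X.shape[0] < dims + 1:
        raise ValueError(f"need at least {dims + 1} points, got {X.shape[0]}")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate cloud: all points identical")
    pca = PCA(n_components=dims, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    projected = {role: (vecs - pca.mean_) @ comps.T
                 for role, vecs in cloud.vectors.items()}
    return ProjectedCloud(cloud.block_id, projected,
                          pca.explained_variance_ratio_.copy())


def centrality_diagnostic(cloud: FeatureCloud | ProjectedCloud) -> float:
    """Distance of the common centroid from the midpoint of the two unique
    centroids, normalised by the unique-centroid separation."""
    for role in ROLES:
        if role not in cloud.vectors:
            raise ValueError(f"cloud is missing role {role!r}")
    c1 = cloud.vectors["unique-1"].mean(axis=0)
    c2 = cloud.vectors["unique-2"].mean(axis=0)
    cc = cloud.vectors["common"].mean(axis=0)
    sep = np.linalg.norm(c1 - c2)
    if sep == 0:
        return float(np.linalg.norm(cc - c1))
    return float(np.linalg.norm(cc - 0.5 * (c1 + c2)) / sep)


def plot_clouds(projected: dict[str, ProjectedCloud],
                out_dir: str | Path, prefix: str = "features") -> list[Path]:
    """Scatter plots (one file per block) plus a CSV of coordinates."""
    import csv

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    colors = {"unique-1": "tab:red", "unique-2": "tab:green",
              "common": "tab:blue"}
    written = []
    csv_path = out_dir / f"{prefix}_coordinates.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["block", "role", "sample"]
                        + [f"pc{i + 1}" for i in range(3)])
        for block_id, cloud in projected.items():
            dims = next(iter(cloud.vectors.values())).shape[1]
            fig = plt.figure(figsize=(4, 4))
            ax = (fig.add_subplot(111, projection="3d") if dims == 3
                  else fig.add_subplot(111))
            for role, vecs in cloud.vectors.items():
                ax.scatter(*vecs.T[:dims], s=12, label=role, c=colors[role])
                for i, v in enumerate(vecs):
                    writer.writerow([block_id, role, i]
                                    + [f"{x:.6g}" for x in v]
                                    + [""] * (3 - dims))
            ax.set_title(block_id)
            ax.legend(fontsize=7)
            path = out_dir / f"{prefix}_{block_id}_{dims}d.png"
            fig.savefig(path, dpi=100, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    written.append(csv_path)
    return written
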