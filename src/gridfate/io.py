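"""Project container, file formats, and the end-to-end pipeline.

A :class:`ProjectContainer` bundles everything a run produces — embedding
block, lattice, pseudotime, per-lineage intensity maps, trajectories and a
run manifest — and round-trips losslessly through a single HDF5 file.
Inputs are accepted as AnnData ``.h5ad`` (embedding/latent under ``obsm``,
labels in ``obs``) or as delimited text with a ``cell_id,x,y`` header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .grid import Embedding2D, MappedGrid, build_grid
from .intensity import lineage_intensity, weighted_pseudotime
from .projection import build_cell_grid_map, grid_to_cells, project_labels_to_grid
from .pseudotime import PseudotimeField, compute_pseudotime, select_start

__all__ = [
    "ProjectContainer",
    "load_embedding_csv",
    "load_anndata",
    "run_pipeline",
]


def load_embedding_csv(path) -> Embedding2D:
    """Read a ``cell_id,x,y`` delimited table into an embedding."""
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"embedding table must have columns {sorted(required)}")
    return Embedding2D(
        coords=df[["x", "y"]].to_numpy(float), cell_ids=tuple(df["cell_id"].astype(str))
    )


def load_anndata(
    path,
    embedding_key: str = "X_umap",
    latent_key: str | None = None,
    labels_key: str | None = None,
):
    """Load (embedding, latent, labels) from an ``.h5ad`` file."""
    import anndata as ad

    adata = ad.read_h5ad(path)
    if embedding_key not in adata.obsm:
        raise KeyError(f"embedding slot {embedding_key!r} not in obsm")
    emb = Embedding2D(
        coords=np.asarray(adata.obsm[embedding_key])[:, :2],
        cell_ids=tuple(adata.obs_names),
    )
    latent = (
        np.asarray(adata.obsm[latent_key]) if latent_key and latent_key in adata.obsm
        else None
    )
    labels = (
        np.asarray(adata.obs[labels_key]).astype(object)
        if labels_key and labels_key in adata.obs.columns
        else None
    )
    return emb, latent, labels


@dataclass
class ProjectContainer:
    """All artifacts of a gridfate run.

    ``rl`` maps a result name (e.g. ``"branch_0_decision"``) to a dict with
    ``node_values``, ``cell_values``, ``mode`` and ``target``.
    """

    embedding: Embedding2D | None = None
    latent: np.ndarray | None = None
    labels: np.ndarray | None = None
    grid: MappedGrid | None = None
    node_labels: np.ndarray | None = None
    pseudotime: PseudotimeField | None = None
    cell_pseudotime: np.ndarray | None = None
    rl: dict = field(default_factory=dict)
    trajectories: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["manifest"] = json.dumps(self.manifest, sort_keys=True)
            if self.embedding is not None:
                g = f.create_group("embedding")
                g.create_dataset("coords", data=self.embedding.coords)
                g.create_dataset(
                    "cell_ids",
                    data=np.array(self.embedding.cell_ids, dtype="S"),
                )
                if self.labels is not None:
                    g.create_dataset(
                        "labels", data=np.array(self.labels, dtype="S")
                    )
                if self.latent is not None:
                    g.create_dataset("latent", data=self.latent)
            if self.grid is not None:
                g = f.create_group("grid")
                g.attrs["n"] = self.grid.n
                g.attrs["j"] = (
                    -1 if self.grid.observer_margin_j is None
                    else self.grid.observer_margin_j
                )
                g.create_dataset("node_coords", data=self.grid.node_coords)
                g.create_dataset("lattice_pos", data=self.grid.lattice_pos)
                g.create_dataset("mapped", data=self.grid.mapped)
                if self.grid.adjacency is not None:
                    coo = self.grid.adjacency.tocoo()
                    g.create_dataset(
                        "adjacency_triplets",
                        data=np.column_stack([coo.row, coo.col, coo.data]),
                    )
                if self.grid.boundary_nodes is not None:
                    g.create_dataset("boundary_nodes", data=self.grid.boundary_nodes)
                if self.node_labels is not None:
                    g.create_dataset(
                        "node_labels",
                        data=np.array(
                            ["" if v is None else str(v) for v in self.node_labels],
                            dtype="S",
                        ),
                    )
            if self.pseudotime is not None:
                g = f.create_group("pseudotime")
                g.create_dataset("psi", data=self.pseudotime.psi)
                g.create_dataset("raw_distance", data=self.pseudotime.raw_distance)
                g.create_dataset("component_id", data=self.pseudotime.component_id)
                g.attrs["offsets"] = json.dumps(
                    {str(k): v for k, v in self.pseudotime.offsets.items()}
                )
                if self.cell_pseudotime is not None:
                    g.create_dataset("cell_psi", data=self.cell_pseudotime)
            rl = f.create_group("rl")
            for name, rec in self.rl.items():
                g = rl.create_group(name)
                g.attrs["mode"] = rec["mode"]
                g.attrs["target"] = json.dumps(rec.get("target"))
                if "weighted_pseudotime" in rec:
                    g.attrs["weighted_pseudotime"] = rec["weighted_pseudotime"]
                g.create_dataset("node_values", data=rec["node_values"])
                g.create_dataset("cell_values", data=rec["cell_values"])
            tg = f.create_group("trajectories")
            for i, path_nodes in enumerate(self.trajectories):
                tg.create_dataset(str(i), data=np.asarray(path_nodes, dtype=int))

    @classmethod
    def load(cls, path) -> "ProjectContainer":
        out = cls()
        with h5py.File(path, "r") as f:
            out.manifest = json.loads(f.attrs["manifest"])
            if "embedding" in f:
                g = f["embedding"]
                out.embedding = Embedding2D(
                    coords=g["coords"][()],
                    cell_ids=tuple(s.decode() for s in g["cell_ids"][()]),
                )
                if "labels" in g:
                    out.labels = np.array([s.decode() for s in g["labels"][()]],
                                          dtype=object)
                if "latent" in g:
                    out.latent = g["latent"][()]
            if "grid" in f:
                g = f["grid"]
                j = int(g.attrs["j"])
                grid = MappedGrid(
                    n=int(g.attrs["n"]),
                    node_coords=g["node_coords"][()],
                    lattice_pos=g["lattice_pos"][()],
                    mapped=g["mapped"][()].astype(bool),
                    observer_margin_j=None if j < 0 else j,
                )
                if "adjacency_triplets" in g:
                    t = g["adjacency_triplets"][()]
                    n2 = grid.n_nodes
                    grid.adjacency = sp.csr_matrix(
                        (t[:, 2].astype(np.int8),
                         (t[:, 0].astype(int), t[:, 1].astype(int))),
                        shape=(n2, n2),
                    )
                if "boundary_nodes" in g:
                    grid.boundary_nodes = g["boundary_nodes"][()].astype(int)
                out.grid = grid
                if "node_labels" in g:
                    raw = [s.decode() for s in g["node_labels"][()]]
                    out.node_labels = np.array(
                        [None if s == "" else s for s in raw], dtype=object
                    )
            if "pseudotime" in f:
                g = f["pseudotime"]
                out.pseudotime = PseudotimeField(
                    psi=g["psi"][()],
                    raw_distance=g["raw_distance"][()],
                    component_id=g["component_id"][()],
                    offsets={int(k): v for k, v in
                             json.loads(g.attrs["offsets"]).items()},
                )
                if "cell_psi" in g:
                    out.cell_pseudotime = g["cell_psi"][()]
            if "rl" in f:
                for name in f["rl"]:
                    g = f["rl"][name]
                    out.rl[name] = {
                        "mode": g.attrs["mode"],
                        "target": json.loads(g.attrs["target"]),
                        "node_values": g["node_values"][()],
                        "cell_values": g["cell_values"][()],
                    }
                    if "weighted_pseudotime" in g.attrs:
                        out.rl[name]["weighted_pseudotime"] = float(
                            g.attrs["weighted_pseudotime"]
                        )
            if "trajectories" in f:
                keys = sorted(f["trajectories"], key=int)
                out.trajectories = [f["trajectories"][k][()].tolist() for k in keys]
        return out

    def results_digest(self) -> str:
        """SHA-256 over pseudotime and intensity outputs (determinism check)."""
        h = hashlib.sha256()
        if self.cell_pseudotime is not None:
            h.update(np.ascontiguousarray(self.cell_pseudotime).tobytes())
        for name in sorted(self.rl):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.rl[name]["cell_values"]).tobytes())
        return h.hexdigest()


DEFAULTS = dict(
    n=50,
    j=3,
    k_neighbors=15,
    n_sample=10,
    boundary_only=True,
    agent="q",
    episodes=1000,
    beta=1.0,
    mode="both",  # decision, contribution or both
    seed=0,
)


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(
    config: dict,
    embedding: Embedding2D | None = None,
    latent: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> ProjectContainer:
    """Execute grid -> pseudotime -> projection -> training -> intensity.

    ``config`` names the input file (``input`` / ``embedding_key`` /
    ``latent_key`` / ``labels_key``), the root cluster (``root``), the
    reward targets (``targets``: list of cluster labels) and the options of
    :data:`DEFAULTS`.  Inputs already in memory can be passed directly.
    Any stage failure aborts with the stage name and cause.
    """
    cfg = {**DEFAULTS, **config}
    seed = int(cfg["seed"])

    if embedding is None:
        path = str(cfg["input"])
        if path.endswith(".h5ad"):
            embedding, latent, labels = load_anndata(
                path,
                embedding_key=cfg.get("embedding_key", "X_umap"),
                latent_key=cfg.get("latent_key"),
                labels_key=cfg.get("labels_key"),
            )
        else:
            embedding = load_embedding_csv(path)
    if labels is None:
        raise ValueError("pipeline requires per-cell cluster labels")
    labels = np.asarray(labels, dtype=object)
    if latent is None:
        latent = embedding.coords  # fall back to the embedding itself

    known = set(labels.tolist())
    root = cfg["root"]
    if root not in known:
        raise ValueError(f"root cluster {root!r} not among labels {sorted(known)}")
    targets = cfg["targets"]
    missing = [t for t in targets if t not in known]
    if missing:
        raise ValueError(f"target clusters not among labels: {missing}")

    grid = _stage("grid")(build_grid)(embedding, n=cfg["n"], j=cfg["j"])
    node_labels = _stage("projection")(project_labels_to_grid)(
        labels, embedding, grid
    )
    starts = _stage("pseudotime")(select_start)(
        grid,
        embedding,
        root,
        labels=labels,
        n_sample=cfg["n_sample"],
        boundary_only=cfg["boundary_only"],
        node_labels=node_labels,
        seed=seed,
    )
    psi = _stage("pseudotime")(compute_pseudotime)(grid, starts)
    cgmap = _stage("projection")(build_cell_grid_map)(
        embedding, grid, k=cfg["k_neighbors"]
    )
    cell_psi = _stage("projection")(grid_to_cells)(psi.psi, cgmap)

    modes = (
        ("decision", "contribution") if cfg["mode"] == "both" else (cfg["mode"],)
    )
    container = ProjectContainer(
        embedding=embedding,
        latent=latent,
        labels=labels,
        grid=grid,
        node_labels=node_labels,
        pseudotime=psi,
        cell_pseudotime=cell_psi,
    )
    from .env import build_states

    states = _stage("training")(build_states)(
        grid, latent, embedding, k=min(cfg["k_neighbors"], embedding.n_cells)
    )
    for t_i, target in enumerate(targets):
        for mode in modes:
            imap = _stage("training")(lineage_intensity)(
                grid,
                psi,
                latent,
                embedding,
                cgmap,
                node_labels,
                target_clusters=target,
                start_clusters=root,
                mode=mode,
                agent_kind=cfg["agent"],
                episodes=cfg["episodes"],
                beta=cfg["beta"],
                seed=seed + 17 * t_i + (0 if mode == "decision" else 1),
                states=states,
            )
            container.rl[f"{target}_{mode}"] = {
                "mode": mode,
                "target": target,
                "node_values": imap.node_values,
                "cell_values": imap.cell_values,
                "weighted_pseudotime": weighted_pseudotime(
                    imap.cell_values, cell_psi
                ),
            }

    container.manifest = {
        "gridfate_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: v for k, v in cfg.items() if k != "input"},
        "seed": seed,
        "results_digest": container.results_digest(),
    }
    return container
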