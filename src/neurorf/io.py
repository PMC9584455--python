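"""Dataset and model I/O: HDF5, NPZ and CSV round trips, plus run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .covariance import CovarianceModel
from .grids import Grid1D, Grid2D
from .sampling import ReceptiveFieldSet
from .tasks import LabeledDataset

__all__ = [
    "save_rf_dataset",
    "load_rf_dataset",
    "save_covariance",
    "load_covariance",
    "save_labeled_dataset",
    "load_labeled_dataset",
    "write_manifest",
]


def _grid_meta(grid: Grid1D | Grid2D) -> dict:
    if isinstance(grid, Grid1D):
        return {"grid_type": "1d", "n_samples": grid.n_samples, "dt_ms": grid.dt_ms}
    return {"grid_type": "2d", "height": grid.height, "width": grid.width}


def _grid_from_meta(meta: dict) -> Grid1D | Grid2D:
    gtype = meta.get("grid_type")
    if gtype == "1d":
        return Grid1D(n_samples=int(meta["n_samples"]), dt_ms=float(meta["dt_ms"]))
    if gtype == "2d":
        return Grid2D(height=int(meta["height"]), width=int(meta["width"]))
    raise ValueError(f"malformed grid metadata: {meta!r}")


def _check_grid(W: np.ndarray, grid: Grid1D | Grid2D) -> None:
    if W.ndim != 2:
        raise ValueError(f"expected a 2-D field matrix, got shape {W.shape}")
    if W.shape[1] != grid.size:
        raise ValueError(
            f"field dimension {W.shape[1]} does not match grid size {grid.size}"
        )


def save_rf_dataset(rfs: ReceptiveFieldSet, path: str | Path) -> None:
    """Write a receptive-field set; format chosen by suffix (.h5/.hdf5, .npz, .csv)."""
    path = Path(path)
    meta = _grid_meta(rfs.grid)
    prov = json.dumps(rfs.provenance, default=_json_default)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=rfs.W)
            for k, v in meta.items():
                f.attrs[k] = v
            f.attrs["provenance"] = prov
    elif path.suffix == ".npz":
        np.savez(path, W=rfs.W, meta=json.dumps(meta), provenance=prov)
    elif path.suffix == ".csv":
        np.savetxt(path, rfs.W, delimiter=",")
    else:
        raise ValueError(f"unsupported format: {path.suffix}")


def load_rf_dataset(
    path: str | Path, grid: Grid1D | Grid2D | None = None
) -> ReceptiveFieldSet:
    """Load a receptive-field set saved by :func:`save_rf_dataset`.

    CSV files carry no metadata, so ``grid`` must be supplied; for HDF5/NPZ
    it is read from the file (an explicit ``grid`` must then agree).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prov: dict = {}
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            W = f["W"][:]
            meta = {k: f.attrs[k] for k in ("grid_type", "n_samples", "dt_ms",
                                            "height", "width") if k in f.attrs}
            prov = json.loads(f.attrs.get("provenance", "{}"))
        file_grid = _grid_from_meta(meta)
    elif path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        W = data["W"]
        file_grid = _grid_from_meta(json.loads(str(data["meta"])))
        prov = json.loads(str(data["provenance"]))
    elif path.suffix == ".csv":
        W = np.atleast_2d(np.loadtxt(path, delimiter=","))
        if grid is None:
            raise ValueError("CSV input requires an explicit grid")
        file_grid = grid
    else:
        raise ValueError(f"unsupported format: {path.suffix}")
    if grid is not None and grid != file_grid:
        raise ValueError(f"grid mismatch: file has {file_grid}, caller gave {grid}")
    _check_grid(W, file_grid)
    return ReceptiveFieldSet(W=W, grid=file_grid, provenance=prov)


def save_covariance(model: CovarianceModel, path: str | Path) -> None:
    """Write a covariance model (matrix, grid, params, eigensystem) to .npz or .h5."""
    path = Path(path)
    meta = _grid_meta(model.grid)
    params = json.dumps(model.params, default=_json_default)
    vals, vecs = model.eigenvalues, model.eigenvectors
    if path.suffix == ".npz":
        np.savez(
            path,
            C=model.C,
            eigenvalues=vals,
            eigenvectors=vecs,
            kind=model.kind,
            params=params,
            meta=json.dumps(meta),
        )
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("C", data=model.C)
            f.create_dataset("eigenvalues", data=vals)
            f.create_dataset("eigenvectors", data=vecs)
            f.attrs["kind"] = model.kind
            f.attrs["params"] = params
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        raise ValueError(f"unsupported format: {path.suffix}")


def load_covariance(path: str | Path) -> CovarianceModel:
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        grid = _grid_from_meta(json.loads(str(data["meta"])))
        model = CovarianceModel(
            C=data["C"],
            grid=grid,
            kind=str(data["kind"]),
            params=json.loads(str(data["params"])),
        )
        model._eigvals = data["eigenvalues"]
        model._eigvecs = data["eigenvectors"]
        return model
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            meta = {k: f.attrs[k] for k in ("grid_type", "n_samples", "dt_ms",
                                            "height", "width") if k in f.attrs}
            model = CovarianceModel(
                C=f["C"][:],
                grid=_grid_from_meta(meta),
                kind=str(f.attrs["kind"]),
                params=json.loads(f.attrs["params"]),
            )
            model._eigvals = f["eigenvalues"][:]
            model._eigvecs = f["eigenvectors"][:]
        return model
    raise ValueError(f"unsupported format: {path.suffix}")


def save_labeled_dataset(ds: LabeledDataset, path: str | Path) -> None:
    """Write a labeled dataset to .npz (stimuli, labels, subclass tags, metadata)."""
    path = Path(path)
    if path.suffix != ".npz":
        raise ValueError("labeled datasets are saved as .npz")
    arrays = {"X": ds.X, "y": ds.y, "meta": json.dumps(ds.meta, default=_json_default)}
    if ds.subclass is not None:
        arrays["subclass"] = ds.subclass.astype("U16")
    if ds.clean is not None:
        arrays["clean"] = ds.clean
    np.savez(path, **arrays)


def load_labeled_dataset(path: str | Path) -> LabeledDataset:
    data = np.load(Path(path), allow_pickle=False)
    return LabeledDataset(
        X=data["X"],
        y=data["y"],
        meta=json.loads(str(data["meta"])),
        subclass=data["subclass"] if "subclass" in data else None,
        clean=data["clean"] if "clean" in data else None,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> Path:
    """Write a run manifest (resolved config + package version + seed) as JSON."""
    from . import __version__

    path = Path(path)
    manifest = {
        "package": "neurorf",
        "version": __version__,
        "seed": seed,
        "config": config,
    }
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path
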