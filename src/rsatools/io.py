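"""File I/O: CSV for single objects, HDF5 for multi-RDM/multi-subject
containers, NIfTI for searchlight volumes.

All round trips are lossless for numeric payloads, and condition labels are
preserved in order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .ldt import Partition, PartitionedData
from .rdm import RDM, PatternSet, RDMCollection, squareform, vectorize
from .searchlight import Volume

__all__ = [
    "read_patterns_csv",
    "write_patterns_csv",
    "read_rdm_csv",
    "write_rdm_csv",
    "read_rdm_vector_csv",
    "write_rdm_vector_csv",
    "read_collection_h5",
    "write_collection_h5",
    "read_patternsets_h5",
    "write_patternsets_h5",
    "read_partitioned_h5",
    "write_partitioned_h5",
    "read_volume",
    "write_map_nifti",
]

PathLike = Union[str, Path]


def _check_exists(path: PathLike) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


# ---------------------------------------------------------------------------
# PatternSet CSV (rows = conditions, first column = label)


def write_patterns_csv(patterns: PatternSet, path: PathLike) -> None:
    df = pd.DataFrame(
        patterns.data,
        index=pd.Index(patterns.condition_labels, name="condition"),
        columns=[f"ch{i}" for i in range(patterns.n_channels)],
    )
    df.to_csv(path)


def read_patterns_csv(path: PathLike, name: str = "") -> PatternSet:
    p = _check_exists(path)
    df = pd.read_csv(p, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{p}: pattern file contains missing values")
    return PatternSet(tuple(df.index.astype(str)), df.to_numpy(float), name=name or p.stem)


# ---------------------------------------------------------------------------
# RDM CSV (square, labeled) and vector CSV + JSON sidecar


def write_rdm_csv(rdm: RDM, path: PathLike) -> None:
    labels = list(rdm.condition_labels)
    df = pd.DataFrame(rdm.matrix, index=labels, columns=labels)
    df.index.name = "condition"
    df.to_csv(path)


def read_rdm_csv(path: PathLike, measure: str = "other", name: str = "") -> RDM:
    p = _check_exists(path)
    df = pd.read_csv(p, index_col=0)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if row_labels != col_labels:
        raise ValueError(f"{p}: row labels do not match column labels")
    try:
        vec = vectorize(df.to_numpy(float))
    except ValueError as err:
        raise ValueError(f"{p}: {err}") from err
    return RDM(tuple(row_labels), vec, measure=measure, name=name or p.stem)


def write_rdm_vector_csv(rdm: RDM, path: PathLike) -> None:
    """Vectorized CSV plus a JSON sidecar recording labels, order, measure."""
    p = Path(path)
    pd.DataFrame({"dissimilarity": rdm.dissimilarities}).to_csv(p, index=False)
    sidecar = {
        "labels": list(rdm.condition_labels),
        "order": "utv-rowmajor",
        "measure": rdm.measure,
        "name": rdm.name,
    }
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_rdm_vector_csv(path: PathLike) -> RDM:
    p = _check_exists(path)
    sidecar_path = _check_exists(p.with_suffix(p.suffix + ".json"))
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("order") != "utv-rowmajor":
        raise ValueError(
            f"{sidecar_path}: unsupported vector order {sidecar.get('order')!r}"
        )
    vec = pd.read_csv(p)["dissimilarity"].to_numpy(float)
    return RDM(
        tuple(sidecar["labels"]),
        vec,
        measure=sidecar.get("measure", "other"),
        name=sidecar.get("name", p.stem),
    )


def read_rdm(path: PathLike, measure: str = "other") -> RDM:
    """Load an RDM from either dialect (vector CSV if a sidecar exists)."""
    p = _check_exists(path)
    if p.with_suffix(p.suffix + ".json").exists():
        return read_rdm_vector_csv(p)
    return read_rdm_csv(p, measure=measure)


# ---------------------------------------------------------------------------
# HDF5 containers


def write_collection_h5(collection: RDMCollection, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dissimilarities", data=collection.stack())
        f.create_dataset(
            "labels", data=np.array(collection.condition_labels, dtype="S")
        )
        f.create_dataset("roles", data=np.array(collection.roles, dtype="S"))
        f.create_dataset("names", data=np.array(collection.names, dtype="S"))
        f.create_dataset(
            "measures", data=np.array([r.measure for r in collection.rdms], dtype="S")
        )


def read_collection_h5(path: PathLike) -> RDMCollection:
    p = _check_exists(path)
    with h5py.File(p, "r") as f:
        diss = f["dissimilarities"][()]
        labels = tuple(x.decode() for x in f["labels"][()])
        roles = tuple(x.decode() for x in f["roles"][()])
        names = tuple(x.decode() for x in f["names"][()])
        measures = tuple(x.decode() for x in f["measures"][()])
    rdms = tuple(
        RDM(labels, diss[i], measure=measures[i], name=names[i])
        for i in range(diss.shape[0])
    )
    return RDMCollection(rdms=rdms, roles=roles)


def write_patternsets_h5(patternsets: Sequence[PatternSet], path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "labels", data=np.array(patternsets[0].condition_labels, dtype="S")
        )
        grp = f.create_group("patterns")
        for i, ps in enumerate(patternsets):
            d = grp.create_dataset(f"{i:04d}", data=ps.data)
            d.attrs["name"] = ps.name


def read_patternsets_h5(path: PathLike) -> list[PatternSet]:
    p = _check_exists(path)
    out = []
    with h5py.File(p, "r") as f:
        labels = tuple(x.decode() for x in f["labels"][()])
        for key in sorted(f["patterns"].keys()):
            d = f["patterns"][key]
            out.append(PatternSet(labels, d[()], name=d.attrs.get("name", key)))
    return out


def write_partitioned_h5(data: PartitionedData, path: PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=np.array(data.condition_labels, dtype="S"))
        for k, part in (("partition1", data.partition1), ("partition2", data.partition2)):
            grp = f.create_group(k)
            grp.create_dataset("patterns", data=part.patterns.data)
            grp.create_dataset("residuals", data=part.residuals)
            grp.attrs["dof"] = part.dof
            if part.xtx_inv is not None:
                grp.create_dataset("xtx_inv", data=part.xtx_inv)


def read_partitioned_h5(path: PathLike) -> PartitionedData:
    p = _check_exists(path)
    with h5py.File(p, "r") as f:
        labels = tuple(x.decode() for x in f["labels"][()])

        def load(key):
            grp = f[key]
            return Partition(
                patterns=PatternSet(labels, grp["patterns"][()], name=key),
                residuals=grp["residuals"][()],
                dof=int(grp.attrs["dof"]),
                xtx_inv=grp["xtx_inv"][()] if "xtx_inv" in grp else None,
            )

        return PartitionedData(load("partition1"), load("partition2"))


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(data_path: PathLike, mask_path: PathLike) -> Volume:
    dp, mp = _check_exists(data_path), _check_exists(mask_path)
    img = nib.load(str(dp))
    mask_img = nib.load(str(mp))
    data = np.asarray(img.get_fdata())
    mask = np.asarray(mask_img.get_fdata()) > 0
    if data.ndim != 4:
        raise ValueError(f"{dp}: expected a 4D image, got shape {data.shape}")
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask {mp} shape {mask.shape} does not match data {dp} spatial "
            f"shape {data.shape[:3]}"
        )
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data, mask=mask, voxel_size_mm=tuple(float(z) for z in zooms))


def write_map_nifti(
    arr: np.ndarray, path: PathLike, voxel_size_mm: Sequence[float] = (3.0, 3.0, 3.0)
) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))
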