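"""Readers and writers: TSV matrices, a binary matrix container, cohort
manifests, and optional NIfTI volume <-> voxel-vector flattening.

The binary container (``.cbm``) is little-endian: 4-byte magic ``CBSM``,
one ``uint8`` version (1), one ``uint8`` ndim, ``ndim`` little-endian
``int64`` dimensions, then the float64 payload in C order.  TSV matrices
are written with 17 significant digits so float64 values round-trip
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .constraints import ReferenceSet
from .core import MultiSubjectData
from .simdata import GroundTruth, SimConfig, config_to_dict

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_cbm",
    "write_cbm",
    "write_cohort",
    "load_cohort",
    "nifti_to_vector",
    "vector_to_nifti",
]

_MAGIC = b"CBSM"


def write_matrix_tsv(path, mat: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(mat, dtype=float)), fmt="%.17g", delimiter="\t")


def read_matrix_tsv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=float))


def write_cbm(path, mat: np.ndarray) -> None:
    mat = np.ascontiguousarray(mat, dtype="<f8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.array([1, mat.ndim], dtype=np.uint8).tobytes())
        fh.write(np.array(mat.shape, dtype="<i8").tobytes())
        fh.write(mat.tobytes())


def read_cbm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.read(4) != _MAGIC:
            raise ValueError(f"{path}: not a CBSM container")
        version, ndim = np.frombuffer(fh.read(2), dtype=np.uint8)
        if version != 1:
            raise ValueError(f"{path}: unsupported container version {version}")
        shape = tuple(np.frombuffer(fh.read(8 * int(ndim)), dtype="<i8"))
        data = np.frombuffer(fh.read(), dtype="<f8")
    return data.reshape(shape).copy()


def write_matrix(path, mat: np.ndarray) -> None:
    """Dispatch on suffix: ``.cbm`` binary container, anything else TSV."""
    if str(path).endswith(".cbm"):
        write_cbm(path, mat)
    else:
        write_matrix_tsv(path, mat)


def read_matrix(path) -> np.ndarray:
    if str(path).endswith(".cbm"):
        return read_cbm(path)
    return read_matrix_tsv(path)


# ---------------------------------------------------------------------------
# cohort manifests


def write_cohort(
    gt: GroundTruth,
    data: MultiSubjectData,
    outdir,
    fmt: str = "tsv",
) -> Path:
    """Write a cohort as one matrix file per subject plus a JSON manifest.

    Ground truth (sources, mixings) goes to a ``gt/`` subdirectory; the
    references to ``references.<fmt>``.  Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "gt").mkdir(parents=True, exist_ok=True)
    ext = "cbm" if fmt == "cbm" else "tsv"
    K = len(data.blocks)
    subjects = []
    for k in range(K):
        name = f"subject_{k:03d}.{ext}"
        write_matrix(outdir / name, data.blocks[k])
        write_matrix(outdir / "gt" / f"sources_{k:03d}.{ext}", gt.sources[k])
        write_matrix(outdir / "gt" / f"mixing_{k:03d}.{ext}", gt.mixings[k])
        subjects.append(
            {
                "file": name,
                "group": int(gt.group_labels[k]),
                "site": 0,
                "sources": f"gt/sources_{k:03d}.{ext}",
                "mixing": f"gt/mixing_{k:03d}.{ext}",
            }
        )
    write_matrix(outdir / f"references.{ext}", gt.references)
    manifest = {
        "V": int(data.n_samples),
        "N": int(gt.sources.shape[1]),
        "references": f"references.{ext}",
        "subjects": subjects,
        "sim_config": None if gt.config is None else config_to_dict(gt.config),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_cohort(manifest_path) -> tuple[MultiSubjectData, ReferenceSet, GroundTruth | None]:
    """Load a cohort manifest, cross-validating shapes.

    Ground truth is attached when the manifest records source/mixing files
    for every subject; otherwise the third element is None.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    V = int(manifest["V"])

    def _load(rel, expect_cols=None, what=""):
        p = base / rel
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file {p} ({what})")
        m = read_matrix(p)
        if expect_cols is not None and m.shape[1] != expect_cols:
            raise ValueError(
                f"{p}: expected {expect_cols} columns, found {m.shape[1]} ({what})"
            )
        return m

    blocks, groups, sites = [], [], []
    sources, mixings = [], []
    have_gt = True
    for sub in manifest["subjects"]:
        blocks.append(_load(sub["file"], V, "subject data"))
        groups.append(int(sub.get("group", 1)))
        sites.append(int(sub.get("site", 0)))
        if "sources" in sub and "mixing" in sub:
            src = _load(sub["sources"], V, "ground-truth sources")
            mix = _load(sub["mixing"], None, "ground-truth mixing")
            sources.append(src)
            mixings.append(mix)
        else:
            have_gt = False
    refs = ReferenceSet(_load(manifest["references"], V, "references"))
    data = MultiSubjectData(
        blocks=blocks, groups=np.array(groups), sites=np.array(sites), reduced=False
    )
    gt = None
    if have_gt and sources:
        cfg = None
        if manifest.get("sim_config"):
            d = dict(manifest["sim_config"])
            d["effect_components"] = tuple(d.get("effect_components", ()))
            cfg = SimConfig(**d)
        gt = GroundTruth(
            sources=np.stack(sources),
            mixings=np.stack(mixings),
            references=refs.refs,
            group_labels=np.array(groups),
            config=cfg,
        )
    return data, refs, gt


# ---------------------------------------------------------------------------
# optional NIfTI support


def nifti_to_vector(img_path, mask_path) -> np.ndarray:
    """Flatten a NIfTI volume to a voxel vector using a binary mask.

    Voxel order is the C-order scan of the mask array (the order of
    ``np.flatnonzero(mask)``), which :func:`vector_to_nifti` inverts
    exactly.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(img_path)).dataobj, dtype=float)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    return img[mask]


def vector_to_nifti(vec: np.ndarray, mask_path, out_path) -> None:
    """Re-inflate a voxel vector into the mask's volume and save it."""
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = np.asarray(vec, dtype=float)
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(out_path))
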