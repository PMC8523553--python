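"""Reading and writing study data as plain-text files (plus NIfTI hooks).

Layout of a study directory::

    design.tsv                     subject, visit, stimulation, task, condition
    config.yaml                    generator configuration
    ground_truth.json              hidden persistence values (synthetic only)
    sub-01/
        gm_<roi>.tsv               per-voxel GM probability
        cSEQ/
            pre_roi-<roi>.tsv      volumes x voxels, "# tr=..." header line
            pre_motion.tsv         6 columns, fixed header
            pre_wm.tsv, pre_csf.tsv
            task_* (same, plus task_blocks.json), post_*
            keypresses.tsv

Time-series tables carry their TR on a ``# tr=`` comment line; task-run
block annotations are stored as JSON in seconds, so they are independent
of the sampling grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BlockSpan, MOTION_COLUMNS, MotionParams, RoiTimeSeries
from .exceptions import ConfigError
from .roi import RoiMask
from .synthetic import (
    CONDITIONS,
    ConditionData,
    GeneratorConfig,
    GroundTruth,
    RunBundle,
    SiEffects,
    SyntheticStudy,
)

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_motion_tsv",
    "read_motion_tsv",
    "write_study",
    "read_study",
    "write_run_nifti",
    "extract_roi_timeseries",
]

_FLOAT_FMT = "%.10g"


def write_timeseries_tsv(ts: RoiTimeSeries, path: Path | str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr={ts.tr!r}\n")
        fh.write("\t".join(str(v) for v in ts.voxel_ids) + "\n")
        np.savetxt(fh, ts.data, fmt=_FLOAT_FMT, delimiter="\t")
    if ts.block_annotations is not None:
        spans = [
            {"label": s.label, "block": s.block,
             "start_s": s.start_s, "end_s": s.end_s}
            for s in ts.block_annotations
        ]
        with open(path.with_name(path.stem + "_blocks.json"), "w") as fh:
            json.dump(spans, fh, indent=1)


def read_timeseries_tsv(path: Path | str) -> RoiTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# tr="):
            raise ConfigError(f"{path}: missing '# tr=' header line")
        tr = float(first.split("=", 1)[1])
        header = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    spans = None
    blocks_path = path.with_name(path.stem + "_blocks.json")
    if blocks_path.exists():
        with open(blocks_path) as fh:
            spans = tuple(
                BlockSpan(d["label"], d["block"], d["start_s"], d["end_s"])
                for d in json.load(fh)
            )
    return RoiTimeSeries(
        data, tr=tr, voxel_ids=np.array(header), block_annotations=spans
    )


def write_motion_tsv(motion: MotionParams, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(MOTION_COLUMNS) + "\n")
        np.savetxt(fh, motion.values, fmt=_FLOAT_FMT, delimiter="\t")


def read_motion_tsv(path: Path | str) -> MotionParams:
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != MOTION_COLUMNS:
            raise ConfigError(
                f"{path}: motion header must be {list(MOTION_COLUMNS)}"
            )
        values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return MotionParams(values)


def _write_pool(pool: np.ndarray, path: Path) -> None:
    np.savetxt(path, pool, fmt=_FLOAT_FMT, delimiter="\t")


def _read_pool(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_study(study: SyntheticStudy, out_dir: Path | str) -> None:
    """Write a study (synthetic or otherwise) as a plain-text directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.design.to_csv(out / "design.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)
    gt = {
        "si_effects": {
            "task": study.ground_truth.si_effects.task,
            "stimulation": study.ground_truth.si_effects.stimulation,
            "interaction": study.ground_truth.si_effects.interaction,
        },
        "table": study.ground_truth.table.to_dict(orient="records"),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    for (subject, roi), gm in study.gm_prob.items():
        sdir = out / subject
        sdir.mkdir(exist_ok=True)
        np.savetxt(sdir / f"gm_{roi}.tsv", gm, fmt=_FLOAT_FMT, delimiter="\t")
    for (subject, condition), cd in study.data.items():
        cdir = out / subject / condition
        cdir.mkdir(parents=True, exist_ok=True)
        for role, bundle in (("pre", cd.pre), ("task", cd.task),
                             ("post", cd.post)):
            if bundle is None:
                continue
            for roi, ts in bundle.roi_ts.items():
                write_timeseries_tsv(ts, cdir / f"{role}_roi-{roi}.tsv")
            write_motion_tsv(bundle.motion, cdir / f"{role}_motion.tsv")
            _write_pool(bundle.wm_pool, cdir / f"{role}_wm.tsv")
            _write_pool(bundle.csf_pool, cdir / f"{role}_csf.tsv")
        if cd.keypresses is not None:
            cd.keypresses.to_csv(cdir / "keypresses.tsv", sep="\t",
                                 index=False)


def _read_bundle(cdir: Path, role: str, rois: list[str]) -> RunBundle | None:
    motion_path = cdir / f"{role}_motion.tsv"
    ts_paths = {roi: cdir / f"{role}_roi-{roi}.tsv" for roi in rois}
    if not motion_path.exists() or not any(
        p.exists() for p in ts_paths.values()
    ):
        return None
    roi_ts = {
        roi: read_timeseries_tsv(p) for roi, p in ts_paths.items()
        if p.exists()
    }
    wm = _read_pool(cdir / f"{role}_wm.tsv")
    csf = _read_pool(cdir / f"{role}_csf.tsv")
    return RunBundle(roi_ts, read_motion_tsv(motion_path), wm, csf)


def read_study(study_dir: Path | str) -> SyntheticStudy:
    """Read a study directory written by :func:`write_study`."""
    root = Path(study_dir)
    design = pd.read_csv(root / "design.tsv", sep="\t")
    with open(root / "config.yaml") as fh:
        config = GeneratorConfig.from_dict(yaml.safe_load(fh))
    rois = list(config.rois)
    gm_prob: dict[tuple[str, str], np.ndarray] = {}
    data: dict[tuple[str, str], ConditionData] = {}
    for subject in sorted(design["subject"].unique()):
        sdir = root / subject
        for roi in rois:
            p = sdir / f"gm_{roi}.tsv"
            if p.exists():
                gm_prob[(subject, roi)] = np.loadtxt(p, delimiter="\t")
        for condition in CONDITIONS:
            cdir = sdir / condition
            if not cdir.exists():
                continue
            kp_path = cdir / "keypresses.tsv"
            data[(subject, condition)] = ConditionData(
                pre=_read_bundle(cdir, "pre", rois),
                task=_read_bundle(cdir, "task", rois),
                post=_read_bundle(cdir, "post", rois),
                keypresses=(
                    pd.read_csv(kp_path, sep="\t")
                    if kp_path.exists() else None
                ),
            )
    gt_path = root / "ground_truth.json"
    if gt_path.exists():
        with open(gt_path) as fh:
            raw = json.load(fh)
        ground_truth = GroundTruth(
            pd.DataFrame(raw["table"]), SiEffects(**raw["si_effects"])
        )
    else:
        ground_truth = GroundTruth(
            pd.DataFrame(
                columns=["subject", "condition", "roi", "pairing", "rho"]
            ),
            SiEffects(),
        )
    return SyntheticStudy(config, design, data, gm_prob, ground_truth)


# ---------------------------------------------------------------------------
# NIfTI hooks (optional path; masks and 4D volumes via nibabel)


def write_run_nifti(
    ts: RoiTimeSeries, mask: RoiMask, img_path: Path | str,
    mask_path: Path | str | None = None,
) -> None:
    """Store an ROI run as a 4D NIfTI volume plus a 3D mask."""
    import nibabel as nib

    coords = mask.coords - mask.coords.min(axis=0)
    shape = tuple(coords.max(axis=0) + 1)
    affine = np.diag(list(mask.spacing) + [1.0])
    vol4 = np.zeros(shape + (ts.n_volumes,), dtype=np.float32)
    vol4[coords[:, 0], coords[:, 1], coords[:, 2], :] = ts.data.T
    img = nib.Nifti1Image(vol4, affine)
    img.header.set_zooms(tuple(mask.spacing) + (ts.tr,))
    nib.save(img, str(img_path))
    if mask_path is not None:
        m = np.zeros(shape, dtype=np.uint8)
        m[coords[:, 0], coords[:, 1], coords[:, 2]] = 1
        nib.save(nib.Nifti1Image(m, affine), str(mask_path))


def extract_roi_timeseries(
    img_path: Path | str, mask_path: Path | str, tr: float | None = None
) -> RoiTimeSeries:
    """Extract a time-by-voxel matrix from a 4D NIfTI and a 3D ROI mask.

    Voxels are ordered by C-order scan of the mask; identifiers encode the
    voxel grid coordinates so runs extracted with the same mask align.
    """
    import nibabel as nib

    img = nib.load(str(img_path))
    mask = nib.load(str(mask_path))
    mdat = np.asarray(mask.dataobj) > 0
    data4 = np.asarray(img.dataobj)
    if data4.ndim != 4:
        raise ConfigError(f"{img_path}: expected a 4D image")
    if mdat.shape != data4.shape[:3]:
        raise ConfigError("mask and image grids differ")
    coords = np.argwhere(mdat)
    data = data4[mdat].T.astype(float)  # volumes x voxels
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    if tr is None or tr <= 0:
        raise ConfigError("TR not present in the NIfTI header; pass tr=")
    ids = np.array([f"x{c[0]}y{c[1]}z{c[2]}" for c in coords])
    return RoiTimeSeries(data, tr=tr, voxel_ids=ids)
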