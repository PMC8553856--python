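"""Serialization helpers: pattern sets as NIfTI + events TSV or portable text."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import read_events_tsv, write_events_tsv
from .simulate import PatternSet


def save_patterns_nifti(patterns: PatternSet, stem) -> None:
    """Write <stem>.nii.gz (x=voxel, one volume per trial), .tsv and .json."""
    stem = Path(stem)
    data = patterns.patterns.T[:, None, None, :]  # (voxels, 1, 1, trials)
    nib.save(nib.Nifti1Image(data, np.eye(4)), str(stem) + ".nii.gz")
    write_events_tsv(patterns.meta, str(stem) + ".tsv")
    with open(str(stem) + ".json", "w") as fh:
        json.dump(
            {"roi_name": patterns.roi_name, "voxel_tsnr": patterns.voxel_tsnr.tolist()},
            fh,
        )


def load_patterns_nifti(stem) -> PatternSet:
    stem = Path(stem)
    img = nib.load(str(stem) + ".nii.gz")
    data = np.asarray(img.get_fdata())
    mat = data.reshape(-1, data.shape[-1]).T  # (trials, voxels)
    meta = read_events_tsv(str(stem) + ".tsv")
    with open(str(stem) + ".json") as fh:
        side = json.load(fh)
    return PatternSet(mat, meta, np.asarray(side["voxel_tsnr"]), side["roi_name"])


def save_patterns_text(patterns: PatternSet, stem) -> None:
    """Portable all-text variant: matrix TSV + events TSV + JSON sidecar."""
    stem = Path(stem)
    np.savetxt(str(stem) + "_patterns.tsv", patterns.patterns, delimiter="\t")
    write_events_tsv(patterns.meta, str(stem) + ".tsv")
    with open(str(stem) + ".json", "w") as fh:
        json.dump(
            {"roi_name": patterns.roi_name, "voxel_tsnr": patterns.voxel_tsnr.tolist()},
            fh,
        )


def load_patterns_text(stem) -> PatternSet:
    stem = Path(stem)
    mat = np.loadtxt(str(stem) + "_patterns.tsv", delimiter="\t", ndmin=2)
    meta = read_events_tsv(str(stem) + ".tsv")
    with open(str(stem) + ".json") as fh:
        side = json.load(fh)
    return PatternSet(mat, meta, np.asarray(side["voxel_tsnr"]), side["roi_name"])
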