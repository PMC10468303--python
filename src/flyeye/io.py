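"""Plain-text and image I/O for pipeline artifacts."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd


def write_image(path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write a float [0, 1] image as 8- or 16-bit grayscale PNG/TIFF."""
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(img * 255).astype(np.uint8)
    elif bit_depth == 16:
        data = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), data)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF into a float array scaled to [0, 1]."""
    data = iio.imread(Path(path))
    data = np.asarray(data, dtype=float)
    if data.max() > 1.0:
        info_max = 255.0 if data.max() <= 255 else 65535.0
        data = data / info_max
    return data


def write_ground_truth(path, truth) -> None:
    """JSON sidecar for a synthetic image's ground truth."""
    d = dataclasses.asdict(truth)
    d["true_centroids"] = np.asarray(d["true_centroids"]).tolist()
    d["fused_pairs"] = [list(p) for p in d["fused_pairs"]]
    Path(path).write_text(json.dumps(d, indent=1))


def read_ground_truth(path):
    from .simulate import SyntheticGroundTruth

    d = json.loads(Path(path).read_text())
    return SyntheticGroundTruth(
        true_centroids=np.asarray(d["true_centroids"], dtype=float),
        true_count=d["true_count"],
        fused_pairs=[tuple(p) for p in d["fused_pairs"]],
        pitted_indices=list(d["pitted_indices"]),
        clipped=d.get("clipped", False),
    )


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(Path(path), sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
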