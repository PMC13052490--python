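"""File formats: TIFF stacks with YAML/JSON sidecars, CSV summaries and reports.

Conventions
-----------
* Intensity stacks: multi-page TIFF, one page per (generator, analyzer)
  pair, plus a YAML sidecar (``<stem>.yaml``) listing the ordered state
  pairs and the pixel size.
* Mueller images: 16-page 32-bit float TIFF in row-major element order
  (m11, m12, ..., m44) plus a JSON sidecar recording the normalization flag.
* Masks: single-page 8-bit TIFF (0 background / 255 tissue).
* Parameter maps: 25-page float TIFF (24 catalogue parameters + auxiliary
  kC) with channel names in the JSON sidecar.
* Summaries and statistical reports: CSV (and JSON for reports).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .acquisition import IntensityStack, MuellerImage, TissueMask
from .decompose import PARAMETER_NAMES, ParameterMaps
from .stats import ComparisonResult, SampleSummary

__all__ = [
    "write_stack", "read_stack",
    "write_mueller", "read_mueller",
    "write_mask", "read_mask",
    "write_maps", "read_maps",
    "write_summaries", "read_summaries",
    "write_report",
]


def _sidecar(path: Path, suffix: str) -> Path:
    return path.with_suffix(suffix)


def write_stack(path, stack: IntensityStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.images.astype(np.float32))
    meta = {
        "states": [[g, a] for g, a in stack.states],
        "pixel_size_um": float(stack.pixel_size),
    }
    _sidecar(path, ".yaml").write_text(yaml.safe_dump(meta))


def read_stack(path) -> IntensityStack:
    path = Path(path)
    images = np.asarray(tifffile.imread(path), dtype=float)
    meta = yaml.safe_load(_sidecar(path, ".yaml").read_text())
    states = tuple((g, a) for g, a in meta["states"])
    return IntensityStack(images, states, pixel_size=meta.get("pixel_size_um", 1.0))


def write_mueller(path, img: MuellerImage) -> None:
    path = Path(path)
    h, w = img.shape
    channels = img.elements.reshape(h, w, 16).transpose(2, 0, 1)
    tifffile.imwrite(path, channels.astype(np.float32))
    meta = {
        "channels": [f"m{i}{j}" for i in range(1, 5) for j in range(1, 5)],
        "normalized": bool(img.normalized),
        "pixel_size_um": float(img.pixel_size),
    }
    _sidecar(path, ".json").write_text(json.dumps(meta, indent=1))


def read_mueller(path) -> MuellerImage:
    path = Path(path)
    channels = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path, ".json").read_text())
    h, w = channels.shape[1:]
    elements = channels.transpose(1, 2, 0).reshape(h, w, 4, 4)
    return MuellerImage(
        elements, normalized=meta["normalized"], pixel_size=meta.get("pixel_size_um", 1.0)
    )


def write_mask(path, mask: TissueMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, (mask.mask.astype(np.uint8)) * 255)
    _sidecar(path, ".json").write_text(
        json.dumps({"threshold_used": float(mask.threshold_used)})
    )


def read_mask(path) -> TissueMask:
    path = Path(path)
    arr = np.asarray(tifffile.imread(path)) > 0
    thr = 0.0
    sc = _sidecar(path, ".json")
    if sc.exists():
        thr = json.loads(sc.read_text()).get("threshold_used", 0.0)
    return TissueMask(arr, threshold_used=thr)


def write_maps(path, maps: ParameterMaps) -> None:
    path = Path(path)
    names = list(PARAMETER_NAMES) + ["kC"]
    stack = np.stack([maps[n] for n in PARAMETER_NAMES] + [maps.kC])
    tifffile.imwrite(path, stack.astype(np.float32))
    _sidecar(path, ".json").write_text(
        json.dumps({"channels": names, "n_invalid": int(maps.n_invalid)}, indent=1)
    )


def read_maps(path) -> ParameterMaps:
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(_sidecar(path, ".json").read_text())
    named = dict(zip(meta["channels"], stack))
    kC = named.pop("kC", None)
    mask = np.isfinite(named[PARAMETER_NAMES[0]])
    return ParameterMaps(
        maps={n: named[n] for n in PARAMETER_NAMES},
        mask=mask,
        n_invalid=meta.get("n_invalid", 0),
        kC=kC,
    )


def summaries_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict = {"sample_id": s.sample_id, "group": s.group, "n_pixels": s.n_pixels}
        for name in PARAMETER_NAMES:
            row[f"{name}_median"] = s.median[name]
            row[f"{name}_mean"] = s.mean[name]
            row[f"{name}_std"] = s.std[name]
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries(path, summaries: list[SampleSummary]) -> None:
    summaries_frame(summaries).to_csv(path, index=False)


def read_summaries(path) -> list[SampleSummary]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleSummary(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                median={n: float(row[f"{n}_median"]) for n in PARAMETER_NAMES},
                mean={n: float(row[f"{n}_mean"]) for n in PARAMETER_NAMES},
                std={n: float(row[f"{n}_std"]) for n in PARAMETER_NAMES},
                n_pixels=int(row["n_pixels"]),
            )
        )
    return out


def write_report(path_csv, results: list[ComparisonResult], path_json=None) -> None:
    """Write the 48-row comparison report as CSV (and optionally JSON).

    The report header records the analysis conventions: no sample exclusion
    and no multiple-testing correction (raw two-tailed p-values).
    """
    from .stats import results_to_frame

    df = results_to_frame(results)
    path_csv = Path(path_csv)
    with path_csv.open("w") as fh:
        fh.write("# two-tailed tests; no outlier removal; no multiple-testing correction\n")
        df.to_csv(fh, index=False)
    if path_json is not None:
        payload = {
            "conventions": {
                "two_tailed": True,
                "outlier_removal": False,
                "multiple_testing_correction": None,
            },
            "results": df.to_dict(orient="records"),
        }
        Path(path_json).write_text(json.dumps(payload, indent=1))


def read_report(path_csv) -> pd.DataFrame:
    return pd.read_csv(path_csv, comment="#")
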