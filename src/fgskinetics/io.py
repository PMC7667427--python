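"""File I/O: CSV curve/metric exports, JSON reports, TIFF image stacks.

All writers embed enough metadata (package version, seed, configuration)
for a run to be reproduced; all readers round-trip what the writers
produce.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__

__all__ = [
    "read_params_config",
    "write_params_config",
    "write_curves_csv",
    "read_curves_csv",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_json_report",
    "read_json_report",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_scene_sidecar",
    "read_scene_sidecar",
]

_CURVE_COLUMNS = ["t_min", "Cf_T", "Cb_T", "Cf_C", "roi_T", "roi_C"]

_PLASMA_KEYS = {"A", "alpha", "B", "beta", "scale"}
_KINETICS_KEYS = {"K1", "k2", "kon", "koff", "Bavail", "vp"}


def read_params_config(path):
    """Read a flat key-value parameter config (YAML or JSON by suffix).

    Returns ``(plasma, kinetics)`` where either may be None if its keys are
    absent.  Plasma keys: A, alpha, B, beta, scale; kinetics keys: K1, k2,
    kon, koff, Bavail, vp.
    """
    from .kinetics import AgentKinetics
    from .plasma import PlasmaInput

    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    unknown = set(doc) - _PLASMA_KEYS - _KINETICS_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    plasma = None
    if _PLASMA_KEYS & set(doc):
        plasma = PlasmaInput(**{k: doc[k] for k in _PLASMA_KEYS if k in doc})
    kinetics = None
    if _KINETICS_KEYS & set(doc):
        kinetics = AgentKinetics(**{k: doc[k] for k in _KINETICS_KEYS if k in doc})
    return plasma, kinetics


def write_params_config(path, plasma=None, kinetics=None) -> None:
    """Write plasma/kinetics parameters as a flat YAML or JSON mapping."""
    doc: dict = {}
    if plasma is not None:
        doc.update(A=plasma.A, alpha=plasma.alpha, B=plasma.B,
                   beta=plasma.beta, scale=plasma.scale)
    if kinetics is not None:
        doc.update(K1=kinetics.K1, k2=kinetics.k2, kon=kinetics.kon,
                   koff=kinetics.koff, Bavail=kinetics.Bavail, vp=kinetics.vp)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def write_curves_csv(path, curves) -> None:
    """Write an :class:`~fgskinetics.kinetics.UptakeCurves` to CSV."""
    n = curves.t.size
    data = {"t_min": curves.t}
    for col, attr in zip(_CURVE_COLUMNS[1:], ("Cf_T", "Cb_T", "Cf_C", "roi_T", "roi_C")):
        val = getattr(curves, attr)
        data[col] = np.full(n, np.nan) if val is None else val
    # default float formatting is the shortest round-trip representation
    pd.DataFrame(data).to_csv(path, index=False)


def read_curves_csv(path) -> pd.DataFrame:
    """Read a curves CSV back into a DataFrame with the canonical columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
    return df


def write_metrics_csv(path, series) -> None:
    """Write a :class:`~fgskinetics.metrics.MetricTimeSeries` to CSV."""
    data = {"t_min": series.t, "cvr": series.cvr}
    if series.auroc is not None:
        data["auroc"] = series.auroc
    df = pd.DataFrame(data)
    df["protocol"] = series.protocol
    df.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_json_report(path, payload: dict, seed: int | None = None,
                      config: dict | None = None) -> None:
    """Write a JSON report with version/seed/config stamped in."""
    doc = {"fgskinetics_version": __version__}
    if seed is not None:
        doc["seed"] = seed
    if config is not None:
        doc["config"] = config
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())


def write_stack_tiff(path, stack: np.ndarray) -> None:
    """Write a (nt, H, W) image stack as a multi-frame TIFF."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_scene_sidecar(path, t, seed, tumor_mask, background_mask,
                        extra: dict | None = None) -> None:
    """JSON sidecar for a rendered scene: frame times, seed, RLE masks."""
    payload = {
        "frame_times_min": np.asarray(t).tolist(),
        "tumor_mask_rle": _rle_encode(tumor_mask),
        "background_mask_rle": _rle_encode(background_mask),
        "mask_shape": list(np.asarray(tumor_mask).shape),
    }
    if extra:
        payload.update(extra)
    write_json_report(path, payload, seed=seed)


def read_scene_sidecar(path) -> dict:
    doc = read_json_report(path)
    shape = tuple(doc["mask_shape"])
    doc["tumor_mask"] = _rle_decode(doc["tumor_mask_rle"], shape)
    doc["background_mask"] = _rle_decode(doc["background_mask_rle"], shape)
    return doc


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of a flattened boolean mask, starting with a False run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:  # convention: first run counts False pixels
        runs = [0] + runs
    return runs


def _rle_decode(runs: list[int], shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    value = False
    for run in runs:
        if value:
            out[pos : pos + run] = True
        pos += run
        value = not value
    return out.reshape(shape)
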