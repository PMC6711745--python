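"""File formats: TIFF image bundles, label rasters, counts CSV, GMT, TF lists,
YAML run configs and JSON reports.

Images travel as multi-page TIFFs (one page per channel) next to a JSON
sidecar naming the channels, their roles and the acquisition metadata, so a
bundle is self-describing.  All tabular formats are plain CSV with a header
row; gene sets use the standard tab-delimited GMT dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .enrichment import GeneSet
from .imaging import LabeledImage

__all__ = [
    "write_image_bundle",
    "read_image_bundle",
    "write_tiff_labels",
    "read_tiff_labels",
    "read_counts_csv",
    "read_groups_csv",
    "read_gmt",
    "write_gmt",
    "read_tf_list",
    "write_report_json",
    "load_run_config",
    "resolve_config",
]


def write_image_bundle(path_prefix: str | Path, image: LabeledImage, truth=None) -> None:
    """Write ``<prefix>.tif`` (one page per channel) and ``<prefix>.json``.

    When a ground-truth object is given, its cell table goes to
    ``<prefix>_truth.csv`` and its label rasters to ``<prefix>_truth_*.tif``.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    tifffile.imwrite(f"{prefix}.tif", stack, photometric="minisblack")
    sidecar = {
        "channels": names,
        "roles": [image.roles[n] for n in names],
        "tumor_id": image.tumor_id,
        "genotype": image.genotype,
        "meta": image.meta,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    if truth is not None:
        truth.cells.to_csv(f"{prefix}_truth.csv", index=False)
        write_tiff_labels(f"{prefix}_truth_nuclei.tif", truth.nucleus_labels)
        write_tiff_labels(f"{prefix}_truth_cells.tif", truth.cell_labels)


def read_image_bundle(path_prefix: str | Path) -> LabeledImage:
    prefix = Path(path_prefix)
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    stack = tifffile.imread(f"{prefix}.tif")
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(sidecar["channels"]):
        raise ValueError(
            f"{prefix}.tif has {stack.shape[0]} pages but the sidecar names "
            f"{len(sidecar['channels'])} channels"
        )
    channels = {n: stack[i] for i, n in enumerate(sidecar["channels"])}
    roles = dict(zip(sidecar["channels"], sidecar["roles"]))
    return LabeledImage(
        channels=channels,
        roles=roles,
        tumor_id=sidecar.get("tumor_id", ""),
        genotype=sidecar.get("genotype", ""),
        meta=sidecar.get("meta", {}),
    )


def write_tiff_labels(path: str | Path, labels: np.ndarray) -> None:
    """Label raster as 16-bit TIFF (labels must fit in uint16)."""
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_tiff_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    """Genes-in-rows counts CSV; first column is the gene id.

    Duplicate gene ids are rejected with their line numbers (1-based,
    counting the header).
    """
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated(keep=False)]
        positions = [i + 2 for i, g in enumerate(df.index) if g in set(dup)]
        raise ValueError(
            f"duplicate gene ids {sorted(set(dup))} at lines {positions} in {path}"
        )
    return df


def read_groups_csv(path: str | Path) -> pd.Series:
    """Two-column CSV (sample_id, group) -> Series indexed by sample."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, group)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Tab-delimited GMT: name, description, member genes."""
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = GeneSet(name=name, members=frozenset(members), description=desc)
    return sets


def write_gmt(path: str | Path, sets: dict[str, GeneSet]) -> None:
    lines = []
    for name, gs in sets.items():
        lines.append("\t".join([name, gs.description or "na", *sorted(gs.members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_tf_list(path: str | Path) -> list[str]:
    """Plain-text TF annotation list, one gene id per line; '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        g = line.split("#", 1)[0].strip()
        if g:
            genes.append(g)
    return genes


def write_report_json(path: str | Path, report: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=_default))


def resolve_config(defaults: dict, user: dict, _path: str = "") -> dict:
    """Merge a user config over defaults, rejecting unknown keys."""
    out = {}
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = resolve_config(dval, user[key], f"{_path}{key}.")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(_path + k for k in unknown)}")
    return out


def load_run_config(path: str | Path, defaults: dict) -> dict:
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return resolve_config(defaults, user)
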