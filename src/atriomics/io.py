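"""Readers and writers for every interchange format.

Canonical table dialect: tab-separated, UTF-8, Unix newlines, '.' decimal;
a missing cell is an empty string (never "NA"), matching common proteomics
export practice. Writers prepend comment lines (``#``) carrying the
artifact version, seed and config hash; readers skip them.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import EMImage, OmicsMatrix, PathwayAnnotation, ROI

__all__ = [
    "read_matrix", "write_matrix", "read_design", "write_design",
    "read_gmt", "write_gmt", "read_idmap", "write_idmap",
    "read_rois", "write_rois", "read_plate", "write_plate",
    "read_bands", "write_bands", "read_image", "write_image",
    "read_ground_truth", "write_ground_truth", "config_hash", "header_lines",
]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def header_lines(seed: int | None = None,
                 config: Mapping | None = None) -> list[str]:
    from . import __version__
    lines = [f"# atriomics v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    return lines


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str,
               seed: int | None = None, config: Mapping | None = None,
               write_index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines(seed=seed, config=config):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", na_rep="", lineterminator="\n",
                     index=write_index, index_label=index_label)


# ---------------------------------------------------------------------------
# Wide matrices + design
# ---------------------------------------------------------------------------

def write_matrix(matrix: OmicsMatrix, path, seed: int | None = None,
                 config: Mapping | None = None) -> None:
    """Wide TSV: first column feature id, one column per sample id."""
    _write_tsv(matrix.values, Path(path), index_label="feature_id",
               seed=seed, config=config)


def read_matrix(path, value_kind: str = "intensity",
                groups: Mapping[str, str] | None = None,
                dataset_tag: str = "TL") -> OmicsMatrix:
    """Read a wide TSV matrix; empty cells become missing (NaN).

    Ragged rows, duplicate feature ids and (for counts) negative or
    non-integer values are rejected with the offending line or id named.
    ``groups`` may be supplied separately (e.g. from a design table); when
    omitted, sample names containing "AF" are labeled AF, the rest sham.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        rows = [(i + 1, line.rstrip("\n").split("\t"))
                for i, line in enumerate(fh)
                if line.strip() and not line.startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    header = rows[0][1]
    width = len(header)
    samples = header[1:]
    ids: list[str] = []
    data: list[list[float]] = []
    for lineno, fields in rows[1:]:
        if len(fields) != width:
            raise ValueError(f"{path}:{lineno}: ragged row "
                             f"({len(fields)} fields, expected {width})")
        fid = fields[0]
        if fid in set(ids):
            raise ValueError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        vals = []
        for j, cell in enumerate(fields[1:]):
            if cell == "":
                vals.append(np.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r}") from None
            if value_kind == "count":
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative count {cell!r} "
                                     f"in sample {samples[j]!r}")
                if v != int(v):
                    raise ValueError(f"{path}:{lineno}: non-integer count "
                                     f"{cell!r} in sample {samples[j]!r}")
            vals.append(v)
        ids.append(fid)
        data.append(vals)
    values = pd.DataFrame(data, index=pd.Index(ids, name="feature_id"),
                          columns=samples, dtype=float)
    if groups is None:
        groups = {s: ("AF" if "AF" in s else "sham") for s in samples}
    return OmicsMatrix(values=values, groups=dict(groups),
                       dataset_tag=dataset_tag, value_kind=value_kind)


def write_design(matrices: list[OmicsMatrix], path,
                 seed: int | None = None) -> None:
    rows = [{"sample_id": s, "group": m.groups[s], "dataset": m.dataset_tag}
            for m in matrices for s in m.sample_ids]
    _write_tsv(pd.DataFrame(rows), Path(path), index_label=None,
               seed=seed, write_index=False)


def read_design(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = {"sample_id", "group", "dataset"}
    if not expected <= set(frame.columns):
        raise ValueError(f"design table must carry columns {sorted(expected)}")
    return frame


# ---------------------------------------------------------------------------
# GMT pathway files and id maps
# ---------------------------------------------------------------------------

def write_gmt(annotation: PathwayAnnotation, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in annotation:
            members = sorted(annotation.members[pid])
            name = annotation.display_name(pid)
            fh.write("\t".join([pid, name] + members) + "\n")


def read_gmt(path) -> PathwayAnnotation:
    """Standard GMT: pathway id, description, then tab-separated member ids."""
    path = Path(path)
    members: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs at least "
                                 "3 tab-separated fields")
            pid, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no members")
            if pid in members:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            members[pid] = genes
            names[pid] = name
    return PathwayAnnotation(members=members, names=names)


def write_idmap(idmap: Mapping[str, list[str]], path) -> None:
    rows = [{"source_id": s, "target_id": t}
            for s, targets in idmap.items() for t in targets]
    _write_tsv(pd.DataFrame(rows), Path(path), index_label=None,
               write_index=False)


def read_idmap(path) -> dict[str, list[str]]:
    """Two-column homolog map; many-to-one and one-to-many both permitted."""
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"source_id", "target_id"} <= set(frame.columns):
        raise ValueError("id map needs columns source_id, target_id")
    if frame.isna().any().any() or (frame == "").any().any():
        raise ValueError("id map contains empty ids")
    out: dict[str, list[str]] = {}
    for src, tgt in zip(frame["source_id"], frame["target_id"]):
        out.setdefault(src, [])
        if tgt not in out[src]:
            out[src].append(tgt)
    return out


# ---------------------------------------------------------------------------
# ROIs, plates, bands
# ---------------------------------------------------------------------------

def write_rois(rois_by_image: Mapping[str, list[ROI]], path) -> None:
    rows = [{"image_id": img, "x0": r.x0, "y0": r.y0,
             "width": r.width, "height": r.height}
            for img, rois in rois_by_image.items() for r in rois]
    _write_tsv(pd.DataFrame(rows), Path(path), index_label=None,
               write_index=False)


def read_rois(path) -> dict[str, list[ROI]]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[ROI]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row["image_id"]), []).append(
            ROI(x0=int(row["x0"]), y0=int(row["y0"]),
                width=int(row["width"]), height=int(row["height"])))
    return out


def write_plate(plate, path, seed: int | None = None) -> None:
    _write_tsv(plate.to_frame(), Path(path), index_label=None, seed=seed,
               write_index=False)


def read_plate(path):
    from .synthetic import AssayPlate
    frame = pd.read_csv(path, sep="\t", comment="#")
    needed = {"well", "role", "known_amount", "response", "time_min",
              "protein_mg"}
    if not needed <= set(frame.columns):
        raise ValueError(f"plate table needs columns {sorted(needed)}")
    return AssayPlate(
        standards=frame[frame["role"] == "standard"].reset_index(drop=True),
        unknowns=frame[frame["role"] == "unknown"].reset_index(drop=True))


def write_bands(bands: pd.DataFrame, path) -> None:
    _write_tsv(bands, Path(path), index_label=None, write_index=False)


def read_bands(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if not {"lane", "target", "control", "group"} <= set(frame.columns):
        raise ValueError("band table needs columns lane, target, control, group")
    return frame


# ---------------------------------------------------------------------------
# Images and ground truth
# ---------------------------------------------------------------------------

def write_image(image: EMImage, path) -> None:
    """16-bit grayscale TIFF or PNG, chosen by file extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = np.asarray(image.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, pixels)
    elif path.suffix.lower() == ".png":
        from PIL import Image
        Image.fromarray(pixels).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_image(path, nm_per_px: float, image_id: str | None = None,
               group: str | None = None) -> EMImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        pixels = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        from PIL import Image
        pixels = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return EMImage(pixels=pixels, nm_per_px=nm_per_px,
                   image_id=image_id or path.stem, group=group)


def write_ground_truth(truth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "regulated_features": truth.regulated_features,
        "regulated_pathways": truth.regulated_pathways,
        "granule_coordinates": [list(c) for c in truth.granule_coordinates],
        "organelle_boxes": [list(b) for b in truth.organelle_boxes],
        "true_activities": truth.true_activities,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path):
    from .synthetic import GroundTruth
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        regulated_features=payload.get("regulated_features", {}),
        regulated_pathways=payload.get("regulated_pathways", {}),
        granule_coordinates=[tuple(c) for c in
                             payload.get("granule_coordinates", [])],
        organelle_boxes=[tuple(b) for b in payload.get("organelle_boxes", [])],
        true_activities=payload.get("true_activities", {}),
    )
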