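"""Readers and writers for landmark-data file dialects.

Supported formats:

* TPS files (``LM=``/``LM3=`` records with optional ``IMAGE=``, ``ID=``,
  ``SCALE=`` lines), the de-facto standard for 2-D digitised landmarks.
* Plain delimiter-separated coordinate tables (one specimen per row,
  ``x1,y1,z1,...`` columns) with a separate specimen metadata table.
* Three-column slider-definition tables for semilandmarks.

All readers convert 1-based file conventions to 0-based indices and apply
SCALE factors at the boundary, so the in-memory objects are always in
physical units with 0-based indexing.  ``merge_views`` rigidly fits one
digitising session onto another through shared landmarks, the standard way
of combining dorsal and ventral sessions of a specimen too large to
digitise in one sweep.
"""
from __future__ import annotations

import logging
import re
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import UNKNOWN, LandmarkConfiguration, LandmarkDataset, SliderSpec

logger = logging.getLogger(__name__)

_TPS_KEYS = ("IMAGE", "ID", "SCALE", "COMMENT", "CURVES", "POINTS", "VARIABLES")


class ParseError(ValueError):
    """Raised when a landmark file violates its dialect."""


def _is_key_line(line: str) -> bool:
    head = line.split("=", 1)[0].strip().upper()
    return head in _TPS_KEYS or re.fullmatch(r"LM3?", head) is not None


def read_tps(
    path: str | Path,
    *,
    missing_sentinel: bool = False,
    flip_y: bool = False,
    part: str = UNKNOWN,
) -> LandmarkDataset:
    """Read a TPS file into a :class:`LandmarkDataset`.

    Parameters
    ----------
    missing_sentinel
        When True, a landmark whose coordinates are all exactly ``-1`` is
        flagged missing (the conventional TPS encoding).  Off by default so
        that legitimate negative coordinates are never destroyed.
    flip_y
        Negate the y axis (image-origin convention); off by default.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_no = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        m = re.fullmatch(r"(LM3?)\s*=\s*(\d+)", line, flags=re.IGNORECASE)
        if m is None:
            raise ParseError(f"{path.name}: expected LM=/LM3= header at line {i + 1}, got {line!r}")
        record_no += 1
        d = 3 if m.group(1).upper() == "LM3" else 2
        k = int(m.group(2))
        i += 1
        rows: list[list[float]] = []
        while i < len(lines) and len(rows) < k:
            cur = lines[i]
            if not cur:
                i += 1
                continue
            if _is_key_line(cur):
                break
            vals = cur.replace(",", " ").split()
            try:
                row = [float(v) for v in vals]
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} record {record_no}: non-numeric coordinate line {cur!r}"
                ) from exc
            if len(row) != d:
                raise ParseError(
                    f"{path.name} record {record_no}: expected {d} coordinates per line, "
                    f"got {len(row)}"
                )
            rows.append(row)
            i += 1
        if len(rows) != k:
            raise ParseError(
                f"{path.name} record {record_no}: LM={k} but only {len(rows)} coordinate lines"
            )
        specimen_id = f"record_{record_no}"
        scale = 1.0
        while i < len(lines):
            cur = lines[i]
            if not cur:
                i += 1
                continue
            m2 = re.fullmatch(r"(\w+)\s*=\s*(.*)", cur)
            if m2 is None or re.fullmatch(r"LM3?", m2.group(1).upper()):
                break
            key, value = m2.group(1).upper(), m2.group(2).strip()
            if key == "ID":
                specimen_id = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name} record {record_no}: bad SCALE value {value!r}"
                    ) from exc
            i += 1
        coords = np.array(rows, dtype=float)
        missing = np.zeros(k, dtype=bool)
        if missing_sentinel:
            missing = np.all(coords == -1.0, axis=1)
        coords = coords * scale
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        coords[missing] = np.nan
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id, coords=coords, missing=missing, scale=scale, part=part
            )
        )
    if not configs:
        raise ParseError(f"{path.name}: no TPS records found")
    ks = {c.k for c in configs}
    ds = {c.d for c in configs}
    if len(ks) > 1 or len(ds) > 1:
        raise ParseError(f"{path.name}: records disagree on landmark count/dimension: {ks}, {ds}")
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a 2-D or 3-D dataset as TPS records.

    Coordinates are written divided by each specimen's scale with a SCALE=
    line carrying the factor, so read_tps round-trips both the coordinates
    and the scale.  Missing landmarks are written as the ``-1`` sentinel
    (read back with ``missing_sentinel=True``).
    """
    path = Path(path)
    key = "LM" if dataset.d == 2 else "LM3"
    out: list[str] = []
    for c in dataset:
        out.append(f"{key}={c.k}")
        raw = c.coords / c.scale
        for j in range(c.k):
            if c.missing[j]:
                out.append(" ".join(["-1"] * c.d))
            else:
                out.append(" ".join(f"{v:.12g}" for v in raw[j]))
        out.append(f"ID={c.specimen_id}")
        out.append(f"SCALE={c.scale:.12g}")
    path.write_text("\n".join(out) + "\n")


def read_coord_table(
    path: str | Path,
    dims: int,
    metadata_path: str | Path | None = None,
    *,
    sep: str | None = None,
    part: str = UNKNOWN,
) -> LandmarkDataset:
    """Read a delimiter-separated coordinate table (one specimen per row).

    The first column is the specimen id; the remaining columns are
    ``x1, y1[, z1], x2, ...``.  Blank or NA cells mark missing landmarks.
    ``metadata_path`` points to a table with ``specimen_id``, ``species``
    and ``sex`` columns; specimens absent from it get species ``unknown``
    (logged as a warning).
    """
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 1 + dims:
        raise ParseError(f"{path.name}: too few columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path.name}: duplicate specimen_id {dupes}")
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if values.shape[1] % dims != 0:
        raise ParseError(
            f"{path.name}: {values.shape[1]} coordinate columns not divisible by dims={dims}"
        )
    k = values.shape[1] // dims
    meta: dict[str, tuple[str, str]] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep=sep, engine="python")
        mdf.columns = [c.strip().lower() for c in mdf.columns]
        for _, row in mdf.iterrows():
            meta[str(row["specimen_id"])] = (
                str(row.get("species", UNKNOWN)),
                str(row.get("sex", UNKNOWN)),
            )
        unmatched = set(meta) - set(ids)
        if unmatched:
            logger.warning("metadata rows without coordinate data: %s", sorted(unmatched))
    configs = []
    for i, sid in enumerate(ids):
        coords = values[i].reshape(k, dims)
        missing = np.any(np.isnan(coords), axis=1)
        coords = coords.copy()
        coords[missing] = np.nan
        if metadata_path is not None and sid not in meta:
            logger.warning("specimen %s has no metadata row; species set to unknown", sid)
        species, sex = meta.get(sid, (UNKNOWN, UNKNOWN))
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid, coords=coords, missing=missing, species=species, sex=sex, part=part
            )
        )
    labels = None
    header = [str(c) for c in df.columns[1:]]
    if all(re.fullmatch(r"[xyz]\d+", h.lower()) for h in header):
        labels = [f"LM{i + 1}" for i in range(k)]
    return LandmarkDataset(configs, labels or [])


def write_coord_table(
    dataset: LandmarkDataset, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a dataset as a CSV coordinate table (NA for missing landmarks)."""
    axes = "xyz"[: dataset.d]
    cols = [f"{a}{i + 1}" for i in range(dataset.k) for a in axes]
    rows = []
    for c in dataset:
        flat = c.coords.reshape(-1)
        rows.append([c.specimen_id] + [("" if np.isnan(v) else f"{v:.12g}") for v in flat])
    pd.DataFrame(rows, columns=["specimen_id"] + cols).to_csv(path, index=False)
    if metadata_path is not None:
        dataset.metadata().reset_index()[["specimen_id", "species", "sex"]].to_csv(
            metadata_path, index=False
        )


def read_sliders(path: str | Path, k: int) -> SliderSpec:
    """Read a three-column (before, slider, after) table; 1-based as written
    by the standard slider-file tools, converted to 0-based."""
    path = Path(path)
    triplets: list[tuple[int, int, int]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.lower().startswith(("before", "#")):
            continue
        vals = line.replace(",", " ").split()
        if len(vals) != 3:
            raise ParseError(f"{path.name} line {ln}: expected 3 columns, got {len(vals)}")
        try:
            b, s, a = (int(v) for v in vals)
        except ValueError as exc:
            raise ParseError(f"{path.name} line {ln}: non-integer index") from exc
        for idx in (b, s, a):
            if not 1 <= idx <= k:
                raise ParseError(f"{path.name} line {ln}: index {idx} out of range 1..{k}")
        triplets.append((b - 1, s - 1, a - 1))
    spec = SliderSpec(triplets)
    spec.validate(k)
    return spec


def write_sliders(spec: SliderSpec, path: str | Path) -> None:
    lines = [f"{b + 1} {s + 1} {a + 1}" for b, s, a in spec.triplets]
    Path(path).write_text("\n".join(lines) + "\n")


def _rigid_fit(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R (det +1) and translation t with
    ``moving @ R + t ~= fixed``."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(h.shape[0])
    flip[-1] = sign
    rot = (u * flip) @ vt
    t = fc - mc @ rot
    return rot, t


def merge_views(
    view_a: LandmarkConfiguration,
    view_b: LandmarkConfiguration,
    shared: Sequence[tuple[int, int]],
) -> LandmarkConfiguration:
    """Merge two digitising sessions of one specimen into a single configuration.

    ``view_b`` is rigidly fitted (rotation + translation, no scaling) onto
    ``view_a`` through the ``shared`` landmark index pairs; shared landmarks
    become the midpoint of their two fitted copies, so neither session is
    preferred.  Landmarks observed in only one view are taken from that view.
    """
    if view_a.d != 3 or view_b.d != 3:
        raise ValueError("merge_views requires 3-D configurations")
    if view_a.k != view_b.k:
        raise ValueError("views must share the landmark scheme")
    pairs = [
        (ia, ib)
        for ia, ib in shared
        if not view_a.missing[ia] and not view_b.missing[ib]
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 usable shared landmarks, have {len(pairs)}")
    a_pts = np.array([view_a.coords[ia] for ia, _ in pairs])
    b_pts = np.array([view_b.coords[ib] for _, ib in pairs])
    if np.linalg.matrix_rank(a_pts - a_pts.mean(axis=0), tol=1e-9 * max(1.0, np.abs(a_pts).max())) < 2:
        raise ValueError("shared landmarks are collinear; rigid fit underdetermined")
    rot, t = _rigid_fit(b_pts, a_pts)
    b_fitted = view_b.coords @ rot + t

    coords = np.full_like(view_a.coords, np.nan)
    missing = np.ones(view_a.k, dtype=bool)
    shared_a = {ia: ib for ia, ib in pairs}
    for j in range(view_a.k):
        if j in shared_a:
            coords[j] = 0.5 * (view_a.coords[j] + b_fitted[shared_a[j]])
            missing[j] = False
        elif not view_a.missing[j]:
            coords[j] = view_a.coords[j]
            missing[j] = False
        elif not view_b.missing[j]:
            coords[j] = b_fitted[j]
            missing[j] = False
    return replace(view_a, coords=coords, missing=missing)
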