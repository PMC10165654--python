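"""Extended-XYZ reading/writing and structured run configurations.

The on-disk format is the extended-XYZ dialect: the comment line carries a
``Lattice="ax ay az bx by bz cx cy cz"`` entry (orthorhombic here, so only
the diagonal is non-zero), a ``Properties=name:type:ncols:...`` column
declaration for the per-atom table, and arbitrary ``key=value`` scalars
(energy, virial, time, state point).  Round-trips are lossless for
positions, velocities, forces, auxiliary columns and per-frame scalars.
"""

from __future__ import annotations

import json
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import yaml

from .core_md import Configuration


class XYZParseError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


@dataclass
class Frame:
    """One extended-XYZ frame: a configuration plus per-atom arrays and
    per-frame scalars."""

    config: Configuration
    arrays: Dict[str, np.ndarray] = field(default_factory=dict)
    info: Dict[str, object] = field(default_factory=dict)
    species: Optional[np.ndarray] = None


def _parse_info(comment: str, lineno: int) -> Dict[str, str]:
    try:
        tokens = shlex.split(comment)
    except ValueError as exc:
        raise XYZParseError(f"malformed comment line ({exc})", lineno)
    out: Dict[str, str] = {}
    for tok in tokens:
        if "=" not in tok:
            out[tok] = "T"
            continue
        key, val = tok.split("=", 1)
        out[key] = val
    return out


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in ("T", "True", "true"):
        return True
    if val in ("F", "False", "false"):
        return False
    parts = val.split()
    if len(parts) > 1:
        try:
            return np.array([float(p) for p in parts])
        except ValueError:
            pass
    return val


def read_xyz(path: Union[str, Path]) -> List[Frame]:
    """Parse an extended-XYZ file into frames (positions in Å)."""
    frames: List[Frame] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError("expected atom count", i + 1)
        if i + 1 >= len(lines):
            raise XYZParseError("missing comment line", i + 2)
        info_raw = _parse_info(lines[i + 1], i + 2)
        if "Lattice" not in info_raw:
            raise XYZParseError("missing Lattice entry", i + 2)
        lat = np.array([float(x) for x in info_raw.pop("Lattice").split()])
        if lat.size != 9:
            raise XYZParseError("Lattice must have 9 components", i + 2)
        lat = lat.reshape(3, 3)
        if np.abs(lat - np.diag(np.diag(lat))).max() > 1e-10:
            raise XYZParseError("only orthorhombic lattices supported", i + 2)
        box = np.diag(lat).copy()
        props = info_raw.pop("Properties", "species:S:1:pos:R:3")
        fields = props.split(":")
        cols: List[tuple] = []
        for k in range(0, len(fields), 3):
            name, typ, nc = fields[k], fields[k + 1], int(fields[k + 2])
            cols.append((name, typ, nc))
        ncols = sum(c[2] for c in cols)
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise XYZParseError(f"expected {n} atom lines", i + 3)
        table = [ln.split() for ln in body]
        for j, row in enumerate(table):
            if len(row) != ncols:
                raise XYZParseError(
                    f"expected {ncols} columns, got {len(row)}", i + 3 + j)
        arrays: Dict[str, np.ndarray] = {}
        species = None
        c0 = 0
        for name, typ, nc in cols:
            sub = [row[c0:c0 + nc] for row in table]
            if typ == "S":
                arr = np.array([s[0] for s in sub])
            else:
                arr = np.array([[float(x) for x in s] for s in sub])
                if nc == 1:
                    arr = arr[:, 0]
            if name == "species":
                species = arr
            else:
                arrays[name] = arr
            c0 += nc
        if "pos" not in arrays:
            raise XYZParseError("Properties must include pos:R:3", i + 2)
        pos = arrays.pop("pos")
        vel = arrays.pop("vel", None)
        info = {k: _coerce(v) for k, v in info_raw.items()}
        cfg = Configuration(pos, box, vel,
                            temperature=info.get("temperature"),
                            pressure=info.get("pressure"))
        frames.append(Frame(cfg, arrays, info, species))
        i += 2 + n
    return frames


def _fmt_val(v) -> str:
    if isinstance(v, bool):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, np.ndarray):
        return '"' + " ".join(repr(float(x)) for x in v.ravel()) + '"'
    s = str(v)
    return f'"{s}"' if " " in s else s


def write_xyz(path: Union[str, Path], frames: Union[Frame, Sequence[Frame]],
              mode: str = "w") -> Path:
    """Write frames in extended-XYZ; returns the path."""
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    with open(path, mode) as fh:
        for fr in frames:
            cfg = fr.config
            n = cfg.n
            box = cfg.box
            lat = np.diag(box).ravel()
            cols = [("species", "S", 1), ("pos", "R", 3)]
            data: List[np.ndarray] = []
            species = fr.species if fr.species is not None \
                else np.array(["W"] * n)
            data.append(species.reshape(n, 1))
            data.append(cfg.positions)
            if cfg.velocities is not None:
                cols.append(("vel", "R", 3))
                data.append(cfg.velocities)
            for name, arr in fr.arrays.items():
                arr = np.asarray(arr)
                a2 = arr.reshape(n, -1)
                cols.append((name, "S" if arr.dtype.kind in "SU" else "R",
                             a2.shape[1]))
                data.append(a2)
            props = ":".join(f"{c[0]}:{c[1]}:{c[2]}" for c in cols)
            items = ['Lattice="' + " ".join(repr(float(x)) for x in lat) +
                     '"', f"Properties={props}"]
            info = dict(fr.info)
            if cfg.temperature is not None:
                info.setdefault("temperature", cfg.temperature)
            if cfg.pressure is not None:
                info.setdefault("pressure", cfg.pressure)
            for k, v in info.items():
                items.append(f"{k}={_fmt_val(v)}")
            fh.write(f"{n}\n{' '.join(items)}\n")
            for j in range(n):
                parts = []
                for arr in data:
                    row = arr[j]
                    for x in np.atleast_1d(row):
                        parts.append(x if isinstance(x, str)
                                     else repr(float(x)))
                fh.write(" ".join(parts) + "\n")
    return path
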