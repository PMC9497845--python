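"""Reading, writing and combining labeled absorbance spectra.

Coordinate conventions used everywhere in this package:

* the wavenumber axis is stored **descending** (e.g. 4000 -> 650 cm^-1);
  readers accept either direction and normalize on construction;
* sequential ("time-domain") features downstream operate on the intensity
  series in stored axis order — the sample index is the array index.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "Spectrum",
    "SpectraDataset",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcampdx",
    "write_jcampdx",
    "average_replicates",
    "concatenate_datasets",
    "write_manifest",
    "read_manifest",
]

VALID_LABELS = {"cancer", "noncancer", "low_grade", "high_grade", None}
VALID_MODES = {"averaged", "single", "synthetic"}
MIN_POINTS = 8


@dataclass
class Spectrum:
    """One sample's absorbance series with label and acquisition metadata."""

    sample_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str | None = None
    acquisition_mode: str = "synthetic"
    gleason: int | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError(f"{self.sample_id}: axes must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValidationError(
                f"{self.sample_id}: wavenumbers ({len(self.wavenumbers)}) and "
                f"intensities ({len(self.intensities)}) differ in length"
            )
        if len(self.wavenumbers) < MIN_POINTS:
            raise ValidationError(
                f"{self.sample_id}: need at least {MIN_POINTS} points, "
                f"got {len(self.wavenumbers)}"
            )
        dw = np.diff(self.wavenumbers)
        if np.all(dw > 0):  # ascending input: flip to the stored convention
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.intensities = self.intensities[::-1].copy()
        elif not np.all(dw < 0):
            raise ValidationError(
                f"{self.sample_id}: wavenumber axis must be strictly monotonic"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError(f"{self.sample_id}: non-finite intensity values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValidationError(f"{self.sample_id}: non-finite wavenumber values")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"{self.sample_id}: unknown label {self.label!r}")
        if self.acquisition_mode not in VALID_MODES:
            raise ValidationError(
                f"{self.sample_id}: unknown acquisition_mode {self.acquisition_mode!r}"
            )
        if self.gleason is not None and not (2 <= int(self.gleason) <= 10):
            raise ValidationError(f"{self.sample_id}: Gleason score out of range 2-10")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def copy(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.wavenumbers = out.wavenumbers.copy()
        out.intensities = out.intensities.copy()
        return out


@dataclass
class SpectraDataset:
    """Aligned collection of spectra sharing one wavenumber grid."""

    spectra: list[Spectrum]
    name: str = "dataset"
    # grid for the (edge) case of an empty dataset; otherwise derived
    _grid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.spectra:
            ref = self.spectra[0].wavenumbers
            for s in self.spectra[1:]:
                if len(s.wavenumbers) != len(ref) or not np.allclose(
                    s.wavenumbers, ref, rtol=0, atol=1e-9
                ):
                    raise ValidationError(
                        f"{self.name}: spectrum {s.sample_id} is on a different "
                        "wavenumber grid"
                    )
            self._grid = ref

    @property
    def wavenumbers(self) -> np.ndarray:
        if self._grid is None:
            raise ValidationError(f"{self.name}: empty dataset has no grid")
        return self._grid

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(s.label for s in self.spectra if s.label is not None))

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# ---------------------------------------------------------------------------
# CSV matrix format
# ---------------------------------------------------------------------------
#
# samples_as_rows (the native orientation):
#   sample_id,4000.0,3992.0,...,650.0,label
#   s01,0.12,0.13,...,0.02,cancer
#
# samples_as_columns: first column "wavenumber", one column per sample; an
# optional final row whose first cell is "label" carries the labels.


def _to_float(token: str, where: str) -> float:
    try:
        v = float(token)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell at {where}: {token!r}") from exc
    if not np.isfinite(v):
        raise ParseError(f"non-finite cell at {where}: {token!r}")
    return v


def _check_axis(wn: np.ndarray) -> None:
    if len(np.unique(wn)) != len(wn):
        raise ValidationError("duplicate wavenumber in axis")
    dw = np.diff(wn)
    if not (np.all(dw > 0) or np.all(dw < 0)):
        raise ValidationError("wavenumber axis must be strictly monotonic")


def read_spectra_csv(
    path: str | Path,
    orientation: str = "samples_as_rows",
    name: str | None = None,
) -> SpectraDataset:
    """Read a labeled spectra matrix from CSV.

    Parameters
    ----------
    path : file path
    orientation : ``samples_as_rows`` or ``samples_as_columns``
    name : dataset name, defaults to the file stem
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i} (expected {width} cells, got {len(row)})"
            )
    if orientation == "samples_as_rows":
        header = rows[0]
        has_label = header[-1].strip().lower() == "label"
        wn_cells = header[1 : -1 if has_label else len(header)]
        wn = np.array([_to_float(c, f"header column {j+1}") for j, c in enumerate(wn_cells)])
        _check_axis(wn)
        spectra = []
        for i, row in enumerate(rows[1:], start=1):
            vals = np.array(
                [
                    _to_float(c, f"row {i}, column {j+1}")
                    for j, c in enumerate(row[1 : -1 if has_label else len(row)])
                ]
            )
            label = row[-1].strip() or None if has_label else None
            spectra.append(Spectrum(row[0], wn, vals, label=label))
    elif orientation == "samples_as_columns":
        header = rows[0]
        body = rows[1:]
        label_row = None
        if body and body[-1][0].strip().lower() == "label":
            label_row = body[-1]
            body = body[:-1]
        wn = np.array(
            [_to_float(r[0], f"row {i+1}, column 1") for i, r in enumerate(body)]
        )
        _check_axis(wn)
        spectra = []
        for j, sid in enumerate(header[1:], start=1):
            vals = np.array(
                [_to_float(r[j], f"row {i+1}, column {j+1}") for i, r in enumerate(body)]
            )
            label = (label_row[j].strip() or None) if label_row else None
            spectra.append(Spectrum(sid, wn, vals, label=label))
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    return SpectraDataset(spectra, name=name or path.stem)


def write_spectra_csv(dataset: SpectraDataset, path: str | Path) -> None:
    """Write a dataset in the samples_as_rows orientation (label column last)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        wn = dataset.wavenumbers
        w.writerow(["sample_id", *(repr(float(v)) for v in wn), "label"])
        for s in dataset:
            w.writerow([s.sample_id, *(repr(float(v)) for v in s.intensities), s.label or ""])


# ---------------------------------------------------------------------------
# JCAMP-DX 4.24 subset: AFFN-encoded (X++(Y..Y)) and (XY..XY) tables
# ---------------------------------------------------------------------------

_AFFN_ONLY = re.compile(r"^[\s0-9eE+\-.,;]*$")


def _parse_jcamp_labels(text: str) -> tuple[dict[str, str], list[str], str]:
    header: dict[str, str] = {}
    data_lines: list[str] = []
    data_kind = ""
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            if label in ("XYDATA", "XYPOINTS"):
                in_data = True
                data_kind = f"{label}={value}"
            elif label == "END":
                in_data = False
            else:
                header[label] = value
                in_data = False
        elif in_data:
            data_lines.append(line)
    return header, data_lines, data_kind


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a single spectrum from a JCAMP-DX file (AFFN dialect only)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header, data_lines, data_kind = _parse_jcamp_labels(text)
    if not data_kind:
        raise FormatError(f"{path}: no XYDATA/XYPOINTS block")
    for line in data_lines:
        if not _AFFN_ONLY.match(line):
            raise FormatError(
                f"{path}: unsupported dialect (non-AFFN characters in data table)"
            )
    xfactor = float(header.get("XFACTOR", "1"))
    yfactor = float(header.get("YFACTOR", "1"))

    if data_kind.startswith("XYPOINTS"):
        xs, ys = [], []
        for line in data_lines:
            for pair in re.split(r";", line):
                pair = pair.strip()
                if not pair:
                    continue
                parts = re.split(r"[,\s]+", pair)
                if len(parts) != 2:
                    raise FormatError(f"{path}: malformed XY pair {pair!r}")
                xs.append(_to_float(parts[0], "XYPOINTS") * xfactor)
                ys.append(_to_float(parts[1], "XYPOINTS") * yfactor)
        wn = np.array(xs)
        inten = np.array(ys)
    else:  # (X++(Y..Y))
        if "(X++(Y..Y))" not in data_kind.replace(" ", ""):
            raise FormatError(f"{path}: unsupported XYDATA form {data_kind!r}")
        xs, ys = [], []
        for line in data_lines:
            tokens = [t for t in re.split(r"[,\s]+", line.strip()) if t]
            if len(tokens) < 2:
                raise FormatError(f"{path}: short XYDATA line {line!r}")
            xs.append(_to_float(tokens[0], "XYDATA") * xfactor)
            ys.extend(_to_float(t, "XYDATA") * yfactor for t in tokens[1:])
        npoints = int(float(header.get("NPOINTS", len(ys))))
        if npoints != len(ys):
            raise FormatError(
                f"{path}: NPOINTS={npoints} inconsistent with {len(ys)} decoded points"
            )
        firstx = float(header["FIRSTX"]) if "FIRSTX" in header else xs[0]
        lastx = float(header["LASTX"]) if "LASTX" in header else None
        deltax = (
            float(header["DELTAX"])
            if "DELTAX" in header
            else (lastx - firstx) / (npoints - 1)
            if lastx is not None
            else None
        )
        if deltax is None:
            raise FormatError(f"{path}: cannot determine DELTAX")
        if lastx is not None:
            implied = firstx + (npoints - 1) * deltax
            if abs(implied - lastx) > 0.5 * abs(deltax):
                raise FormatError(
                    f"{path}: LASTX={lastx} inconsistent with "
                    f"FIRSTX+(N-1)*DELTAX={implied}"
                )
        wn = firstx + deltax * np.arange(npoints)
        inten = np.array(ys)

    title = header.get("TITLE", path.stem)
    return Spectrum(sample_id=title, wavenumbers=wn, intensities=inten)


def write_jcampdx(spectrum: Spectrum, path: str | Path, yfactor: float = 1.0) -> None:
    """Write a spectrum as an AFFN (X++(Y..Y)) JCAMP-DX file."""
    path = Path(path)
    wn = spectrum.wavenumbers
    inten = spectrum.intensities / yfactor
    deltax = (wn[-1] - wn[0]) / (len(wn) - 1)
    if not np.allclose(np.diff(wn), deltax, rtol=0, atol=1e-6 * abs(deltax)):
        raise ValidationError("JCAMP (X++(Y..Y)) requires an equidistant axis")
    lines = [
        f"##TITLE={spectrum.sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1",
        f"##YFACTOR={float(yfactor)!r}",
        f"##FIRSTX={float(wn[0])!r}",
        f"##LASTX={float(wn[-1])!r}",
        f"##DELTAX={float(deltax)!r}",
        f"##NPOINTS={len(wn)}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, len(wn), per_line):
        chunk = inten[i : i + per_line]
        lines.append(" ".join([repr(float(wn[i]))] + [repr(float(v)) for v in chunk]))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Combination operations
# ---------------------------------------------------------------------------


def average_replicates(
    replicates: Sequence[Spectrum], n_required: int = 3
) -> Spectrum:
    """Pointwise mean of replicate acquisitions from one sample."""
    if len(replicates) < n_required:
        raise ValidationError(
            f"need at least {n_required} replicates, got {len(replicates)}"
        )
    ref = replicates[0]
    for r in replicates[1:]:
        if len(r.wavenumbers) != len(ref.wavenumbers) or not np.allclose(
            r.wavenumbers, ref.wavenumbers, rtol=0, atol=1e-9
        ):
            raise ValidationError("replicate wavenumber grids differ")
        if r.sample_id != ref.sample_id:
            raise ValidationError(
                f"replicates from different samples: {r.sample_id!r} vs {ref.sample_id!r}"
            )
    mean = np.mean([r.intensities for r in replicates], axis=0)
    return ref.copy(intensities=mean, acquisition_mode="averaged")


def concatenate_datasets(
    a: SpectraDataset, b: SpectraDataset, name: str = "concatenated"
) -> SpectraDataset:
    """Join two datasets on a shared grid; per-spectrum provenance is kept."""
    if len(a) and len(b):
        if len(a.wavenumbers) != len(b.wavenumbers) or not np.allclose(
            a.wavenumbers, b.wavenumbers, rtol=0, atol=1e-9
        ):
            raise ValidationError("cannot concatenate datasets on different grids")
    spectra = [
        s.copy(source=s.source or src.name)
        for src in (a, b)
        for s in src
    ]
    grid = a._grid if len(a) else b._grid
    return SpectraDataset(spectra, name=name, _grid=grid)


# ---------------------------------------------------------------------------
# YAML manifest (paths + per-sample metadata for multi-file cohorts)
# ---------------------------------------------------------------------------


def write_manifest(path: str | Path, entries: Iterable[Mapping]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"spectra": [dict(e) for e in entries]}, fh, sort_keys=False)


def read_manifest(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "spectra" not in doc:
        raise FormatError(f"{path}: manifest must contain a 'spectra' list")
    return list(doc["spectra"])
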