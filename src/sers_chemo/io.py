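"""Reading, writing and gridding of SERS spectra.

Spectra arrive either as per-acquisition two-column text files (wavenumber,
intensity) as exported by confocal Raman mapping software, or as a wide
delimited table (first column the wavenumber axis, one column per spectrum)
accompanied by a manifest assigning each spectrum to a subject, a class
label and a mapping location.  All downstream analysis runs on a
:class:`SpectralDataset`, whose rows share one common, strictly ascending
wavenumber grid in Raman shift units (cm^-1).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "CANONICAL_GRID",
    "Spectrum",
    "SpectralDataset",
    "Manifest",
    "read_spectrum_text",
    "write_spectrum_text",
    "read_wide_table",
    "write_wide_table",
    "read_manifest",
    "write_manifest",
    "resample_to_grid",
]

#: Closed vocabulary of subject classes.
CLASS_LABELS = ("lung_cancer", "other_cancer", "control")

#: Canonical analysis grid: 700-1800 cm^-1 at 1 cm^-1 spacing (1101 points),
#: matching the confocal mapping acquisition range.  A fixed grid keeps the
#: spectral matrices aligned across subjects and instruments.
CANONICAL_GRID = np.arange(700.0, 1801.0, 1.0)

_MIN_POINTS = 16

_FLOAT_FMT = "%.17g"  # full double precision => text round-trips exactly


class SpectrumParseError(ValueError):
    """A spectrum text file could not be parsed."""


class SpectrumValidationError(ValueError):
    """A parsed spectrum violates a structural invariant."""


@dataclass(frozen=True)
class Spectrum:
    """One mapping acquisition: a wavenumber axis plus intensities.

    Wavenumbers are Raman shifts in cm^-1, stored strictly ascending.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    subject_id: str = ""
    location_index: int = 1

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise SpectrumValidationError(
                "wavenumbers and intensities must be 1-D vectors of equal length"
            )
        if wn.size < _MIN_POINTS:
            raise SpectrumValidationError(
                f"spectrum needs >= {_MIN_POINTS} points, got {wn.size}"
            )
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(it))):
            raise SpectrumValidationError("non-finite values in spectrum")
        if np.any(np.diff(wn) <= 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class Manifest:
    """Table assigning spectrum ids to subjects, classes and locations."""

    frame: pd.DataFrame

    COLUMNS = ("spectrum_id", "subject_id", "class_label", "location_index", "source_path")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if df["spectrum_id"].duplicated().any():
            dups = df.loc[df["spectrum_id"].duplicated(), "spectrum_id"].tolist()
            raise ValueError(f"duplicate spectrum ids in manifest: {dups[:5]}")
        bad = sorted(set(df["class_label"]) - set(CLASS_LABELS))
        if bad:
            raise ValueError(
                f"unknown class labels {bad}; allowed: {list(CLASS_LABELS)}"
            )
        # a subject must carry exactly one class label
        nclass = df.groupby("subject_id")["class_label"].nunique()
        multi = nclass[nclass > 1].index.tolist()
        if multi:
            raise ValueError(f"subjects with conflicting class labels: {multi}")

    @property
    def spectrum_ids(self) -> list[str]:
        return self.frame["spectrum_id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class SpectralDataset:
    """Aligned spectra matrix with per-spectrum annotations.

    ``X`` is (n_spectra, n_wavenumbers); row ``i`` is the spectrum identified
    by ``spectrum_ids[i]``, acquired from ``subject_ids[i]`` of class
    ``class_labels[i]`` at mapping location ``location_index[i]``.
    """

    grid: np.ndarray
    X: np.ndarray
    subject_ids: np.ndarray
    class_labels: np.ndarray
    location_index: np.ndarray
    spectrum_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.X.shape[0]
        if self.spectrum_ids is None:
            self.spectrum_ids = np.array([f"s{i:06d}" for i in range(n)])
        for name in ("subject_ids", "class_labels", "location_index", "spectrum_ids"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.X.ndim != 2 or self.X.shape[1] != self.grid.size:
            raise ValueError("X must be (n_spectra, len(grid))")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        for name in ("subject_ids", "class_labels", "location_index", "spectrum_ids"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have length n_spectra={n}")
        pairs = {}
        for s, c in zip(self.subject_ids, self.class_labels):
            if pairs.setdefault(s, c) != c:
                raise ValueError(f"subject {s!r} carries more than one class label")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in order of first appearance."""
        return list(dict.fromkeys(self.subject_ids.tolist()))

    def subject_class(self) -> dict[str, str]:
        return dict(zip(self.subject_ids.tolist(), self.class_labels.tolist()))

    def select(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset preserving annotations."""
        return SpectralDataset(
            grid=self.grid.copy(),
            X=self.X[mask],
            subject_ids=self.subject_ids[mask],
            class_labels=self.class_labels[mask],
            location_index=self.location_index[mask],
            spectrum_ids=self.spectrum_ids[mask],
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid.copy(),
            X=self.X.copy(),
            subject_ids=self.subject_ids.copy(),
            class_labels=self.class_labels.copy(),
            location_index=self.location_index.copy(),
            spectrum_ids=self.spectrum_ids.copy(),
        )

    def to_manifest(self, source_path: str = "") -> Manifest:
        return Manifest(
            pd.DataFrame(
                {
                    "spectrum_id": self.spectrum_ids,
                    "subject_id": self.subject_ids,
                    "class_label": self.class_labels,
                    "location_index": self.location_index.astype(int),
                    "source_path": source_path,
                }
            )
        )


# ---------------------------------------------------------------------------
# per-spectrum text files


def read_spectrum_text(path, *, spectrum_id: str = "", subject_id: str = "",
                       location_index: int = 1) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Fields may be separated by whitespace or commas; lines starting with
    ``#`` are comments.  A file written with a descending axis is reversed
    (axis and intensities together) so the returned spectrum is ascending.
    """
    path = Path(path)
    wns: list[float] = []
    its: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 numeric fields, got {len(fields)}"
                )
            try:
                wns.append(float(fields[0]))
                its.append(float(fields[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric field in {line!r}"
                ) from None
    wn = np.array(wns)
    it = np.array(its)
    if wn.size >= 2 and wn[0] > wn[-1]:
        wn, it = wn[::-1], it[::-1]
    if np.any(np.diff(wn) == 0):
        dup = wn[:-1][np.diff(wn) == 0][0]
        raise SpectrumValidationError(f"{path}: duplicate wavenumber {dup:g}")
    return Spectrum(wn, it, spectrum_id=spectrum_id or path.stem,
                    subject_id=subject_id, location_index=location_index)


def write_spectrum_text(spectrum: Spectrum, path) -> None:
    arr = np.column_stack([spectrum.wavenumbers, spectrum.intensities])
    header = f"# spectrum_id={spectrum.spectrum_id}\n# wavenumber_cm1 intensity"
    np.savetxt(path, arr, fmt=_FLOAT_FMT, header=header, comments="")


# ---------------------------------------------------------------------------
# wide table + manifest


def read_manifest(path) -> Manifest:
    df = pd.read_csv(path, dtype={"spectrum_id": str, "subject_id": str})
    df["location_index"] = df["location_index"].astype(int)
    if "source_path" not in df.columns:
        df["source_path"] = ""
    df["source_path"] = df["source_path"].fillna("")
    return Manifest(df)


def write_manifest(manifest: Manifest, path) -> None:
    manifest.frame.to_csv(path, index=False)


def read_wide_table(path, manifest: Manifest) -> SpectralDataset:
    """Read a wide spectral table and order its rows as in *manifest*.

    The first column is the wavenumber axis; every other column header is a
    spectrum id.  All manifest ids must be present in the table.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: wide table needs a wavenumber column plus spectra")
    grid = df.iloc[:, 0].to_numpy(dtype=float)
    cols = [str(c) for c in df.columns[1:]]
    wanted = manifest.spectrum_ids
    missing = [sid for sid in wanted if sid not in cols]
    if missing:
        raise ValueError(f"{path}: spectra missing from table: {missing}")
    X = df[wanted].to_numpy(dtype=float).T
    mf = manifest.frame
    return SpectralDataset(
        grid=grid,
        X=X,
        subject_ids=mf["subject_id"].to_numpy(),
        class_labels=mf["class_label"].to_numpy(),
        location_index=mf["location_index"].to_numpy(dtype=int),
        spectrum_ids=np.array(wanted),
    )


def write_wide_table(dataset: SpectralDataset, path, *, header_comment: str | None = None) -> None:
    """Write the dataset as ``wavenumber,<id1>,<id2>,...`` at full precision."""
    buf = _io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    buf.write(",".join(["wavenumber", *dataset.spectrum_ids.tolist()]) + "\n")
    body = np.column_stack([dataset.grid, dataset.X.T])
    np.savetxt(buf, body, fmt=_FLOAT_FMT, delimiter=",")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# regridding


def resample_to_grid(spectra: Iterable[Spectrum], grid: np.ndarray | None = None,
                     class_lookup: dict[str, str] | None = None) -> SpectralDataset:
    """Linearly interpolate spectra onto a common grid (no extrapolation).

    Every spectrum's wavenumber range must cover ``[grid[0], grid[-1]]``.
    ``class_lookup`` maps subject ids to class labels; subjects not listed
    default to ``"control"``.
    """
    grid = CANONICAL_GRID if grid is None else np.asarray(grid, dtype=float)
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to resample")
    rows, sids, subs, locs = [], [], [], []
    for sp in spectra:
        lo, hi = sp.wavenumbers[0], sp.wavenumbers[-1]
        if lo > grid[0] or hi < grid[-1]:
            raise ValueError(
                f"spectrum {sp.spectrum_id!r} covers [{lo:g}, {hi:g}] "
                f"but grid needs [{grid[0]:g}, {grid[-1]:g}]"
            )
        rows.append(np.interp(grid, sp.wavenumbers, sp.intensities))
        sids.append(sp.spectrum_id)
        subs.append(sp.subject_id)
        locs.append(sp.location_index)
    lookup = class_lookup or {}
    labels = [lookup.get(s, "control") for s in subs]
    return SpectralDataset(
        grid=grid.copy(),
        X=np.vstack(rows),
        subject_ids=np.array(subs),
        class_labels=np.array(labels),
        location_index=np.array(locs, dtype=int),
        spectrum_ids=np.array(sids),
    )
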