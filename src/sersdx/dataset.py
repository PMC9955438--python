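"""Cohort container for wide-format Raman/SERS spectral tables.

A :class:`SpectrumSet` holds a cohort of spectra sampled on one shared
wavenumber grid (cm^-1), one class label and one unique identifier per
sample.  On disk the cohort is a wide CSV::

    sample_id,label,600.0,602.0,...,1800.0
    H001,healthy,0.0123,...

Values are serialized with full ``repr`` precision so that a
write-then-read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class SpectrumParseError(ValueError):
    """Raised when a spectral CSV fails validation; carries the line number."""


@dataclass
class SpectrumSet:
    """Spectra of one cohort on a shared wavenumber axis.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis, cm^-1, shape ``(p,)``.
    intensities
        Intensity matrix, shape ``(n_samples, p)``; real, finite.
    labels
        Class label per sample, shape ``(n_samples,)``.
    sample_ids
        Unique sample identifiers, shape ``(n_samples,)``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be a 1-D vector")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        n, p = self.intensities.shape
        if p != self.wavenumbers.size:
            raise ValueError(
                f"intensity matrix has {p} columns but the axis has "
                f"{self.wavenumbers.size} points"
            )
        if self.labels.shape != (n,) or self.sample_ids.shape != (n,):
            raise ValueError("labels and sample_ids must have one entry per row")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")
        ids, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise ValueError(f"duplicate sample_id: {dup[0]!r}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.intensities.shape[1]

    def class_order(self) -> list[str]:
        """Class labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_order()}

    # -- subsetting ----------------------------------------------------------

    def select(self, mask: np.ndarray) -> "SpectrumSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectrumSet(
            wavenumbers=self.wavenumbers,
            intensities=self.intensities[mask],
            labels=self.labels[mask],
            sample_ids=self.sample_ids[mask],
        )

    def select_classes(self, classes: Sequence[str]) -> "SpectrumSet":
        mask = np.isin(self.labels.astype(str), list(classes))
        if not mask.any():
            raise ValueError(f"no samples with labels in {list(classes)}")
        return self.select(mask)

    def relabel(self, merges: Mapping[str, Iterable[str]]) -> "SpectrumSet":
        """Merge classes, e.g. ``{"case": ["gb_stone", "gb_polyp"]}``."""
        mapping = {str(old): new for new, olds in merges.items() for old in olds}
        labels = np.array(
            [mapping.get(str(lab), str(lab)) for lab in self.labels], dtype=object
        )
        return replace(self, labels=labels)

    def with_intensities(self, intensities: np.ndarray) -> "SpectrumSet":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    # -- I/O -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.intensities, columns=[repr(float(w)) for w in self.wavenumbers]
        )
        frame.insert(0, "label", self.labels.astype(str))
        frame.insert(0, "sample_id", self.sample_ids.astype(str))
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_spectrumset(path: str | Path) -> SpectrumSet:
    """Read and validate a wide-format spectral CSV.

    Raises :class:`SpectrumParseError` with a 1-based line number for
    ragged rows or non-numeric cells, and a plain ``ValueError`` naming
    the offending sample for duplicate identifiers.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if len(header) < 3 or header[0] != "sample_id" or header[1] != "label":
            raise SpectrumParseError(
                "line 1: header must start with 'sample_id,label' followed by "
                "wavenumber columns"
            )
        try:
            wavenumbers = np.array([float(h) for h in header[2:]])
        except ValueError as exc:
            raise SpectrumParseError(f"line 1: non-numeric wavenumber header ({exc})")
        if np.any(np.diff(wavenumbers) <= 0):
            raise SpectrumParseError("line 1: wavenumber headers must be strictly increasing")
        ids: list[str] = []
        labels: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(header):
                raise SpectrumParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(cells)}"
                )
            try:
                rows.append(np.array([float(c) for c in cells[2:]]))
            except ValueError:
                bad = next(c for c in cells[2:] if not _is_float(c))
                raise SpectrumParseError(f"line {lineno}: non-numeric cell {bad!r}")
            ids.append(cells[0])
            labels.append(cells[1])
    if not rows:
        raise SpectrumParseError("file contains no spectra")
    return SpectrumSet(
        wavenumbers=wavenumbers,
        intensities=np.vstack(rows),
        labels=np.array(labels, dtype=object),
        sample_ids=np.array(ids, dtype=object),
    )


def _is_float(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True
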