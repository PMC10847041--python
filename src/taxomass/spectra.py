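"""In-memory MS/MS spectrum model and MGF reading/writing.

The canonical container is :class:`Spectrum`: a precursor m/z plus a peak
list sorted ascending in m/z. Peaks closer than 1e-5 Th are merged on
construction (intensity sum at the intensity-weighted mean m/z) so that a
fragment never matches twice during scoring. Charge is carried but plays no
role in matching, which operates purely in m/z space.

MGF framing (``BEGIN IONS``/``END IONS``) is parsed and written through
:mod:`pyteomics.mgf`; spectra lacking a precursor are kept but flagged
unsearchable rather than silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .errors import MgfParseError

__all__ = ["Peak", "Spectrum", "read_mgf", "write_mgf"]

#: peaks closer than this (Th) are considered duplicates and merged
PEAK_MERGE_TOL = 1e-5


class Peak(NamedTuple):
    mz: float
    intensity: float


def _clean_peaks(mz: Sequence[float], intensity: Sequence[float]):
    """Sort ascending by m/z and merge near-duplicate peaks.

    Duplicates (within ``PEAK_MERGE_TOL``) collapse to a single peak at the
    intensity-weighted mean m/z with summed intensity.
    """
    mz = np.asarray(mz, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if mz.shape != inten.shape:
        raise ValueError("m/z and intensity arrays differ in length")
    if mz.size == 0:
        return mz, inten
    if np.any(mz <= 0) or np.any(inten < 0):
        raise ValueError("peaks require mz > 0 and intensity >= 0")
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    # group runs of near-identical m/z
    out_mz: list[float] = []
    out_in: list[float] = []
    i = 0
    n = mz.size
    while i < n:
        j = i + 1
        while j < n and mz[j] - mz[j - 1] <= PEAK_MERGE_TOL:
            j += 1
        if j == i + 1:
            out_mz.append(mz[i])
            out_in.append(inten[i])
        else:
            w = inten[i:j]
            tot = w.sum()
            centre = float(np.average(mz[i:j], weights=w)) if tot > 0 else float(mz[i:j].mean())
            out_mz.append(centre)
            out_in.append(float(tot))
        i = j
    return np.asarray(out_mz), np.asarray(out_in)


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor plus fragment peak list.

    Parameters
    ----------
    spectrum_id : str
        Local identifier or USI string.
    precursor_mz : float or None
        Precursor m/z in Th. ``None`` marks the spectrum unsearchable.
    mz, intensities : array-like
        Fragment peak positions (Th) and abundances; sorted/merged on init.
    """

    spectrum_id: str
    precursor_mz: float | None
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))
    charge: int | None = None
    source_file: str | None = None
    dataset_id: str | None = None
    scan: int | None = None

    def __post_init__(self):
        self.mz, self.intensities = _clean_peaks(self.mz, self.intensities)
        if self.precursor_mz is not None and self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensities)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def is_searchable(self) -> bool:
        return self.precursor_mz is not None and self.n_peaks >= 1

    def copy(self, **changes) -> "Spectrum":
        changes.setdefault("mz", self.mz.copy())
        changes.setdefault("intensities", self.intensities.copy())
        return replace(self, **changes)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    The precursor is the first numeric token of the PEPMASS-style field
    (the second token, if present, is a precursor intensity and is ignored).
    Keys are handled case-insensitively by the underlying parser. Spectra
    without a precursor are returned with ``precursor_mz=None`` (flagged
    unsearchable), never dropped.

    Raises
    ------
    MgfParseError
        On malformed content, reporting the 1-based block index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        reader = _mgf.read(str(path), use_index=False, convert_arrays=1,
                           read_charges=True)
    except Exception as exc:  # pragma: no cover - open errors are rare
        raise MgfParseError(f"cannot open MGF: {exc}") from exc
    block = 0
    with reader:
        while True:
            block += 1
            try:
                entry = next(reader, None)
            except StopIteration:
                break
            except Exception as exc:
                raise MgfParseError(f"malformed MGF block: {exc}",
                                    block_index=block) from exc
            if entry is None:
                break
            params = entry.get("params", {})
            pep = params.get("pepmass")
            precursor = None
            if pep is not None:
                first = pep[0] if isinstance(pep, (tuple, list)) else pep
                if first is not None:
                    precursor = float(first)
            title = str(params.get("title", f"{path.name}:index:{block}"))
            scan = params.get("scans")
            if scan is not None:
                try:
                    scan = int(str(scan).split("-")[0])
                except ValueError as exc:
                    raise MgfParseError(f"non-integer SCANS value {scan!r}",
                                        block_index=block) from exc
            charge = params.get("charge")
            if charge:
                try:
                    charge = int(charge[0]) if isinstance(charge, (list, tuple)) else int(charge)
                except (TypeError, ValueError):
                    charge = None
            else:
                charge = None
            try:
                spec = Spectrum(
                    spectrum_id=title,
                    precursor_mz=precursor,
                    mz=entry.get("m/z array", np.empty(0)),
                    intensities=entry.get("intensity array", np.empty(0)),
                    charge=charge,
                    source_file=str(path),
                    scan=scan,
                )
            except ValueError as exc:
                raise MgfParseError(str(exc), block_index=block) from exc
            spectra.append(spec)
    if not spectra:
        warnings.warn(f"MGF file {path} contains no spectra", stacklevel=2)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> Path:
    """Write spectra to an MGF file. Every spectrum must carry a precursor.

    ``spectrum_id`` goes to TITLE; ``scan`` to SCANS when present.
    """
    path = Path(path)
    entries = []
    for s in spectra:
        if s.precursor_mz is None:
            raise ValueError(f"spectrum {s.spectrum_id!r} has no precursor_mz; "
                             "cannot be written to MGF")
        params: dict = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.scan is not None:
            params["scans"] = str(s.scan)
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append({
            "m/z array": s.mz,
            "intensity array": s.intensities,
            "params": params,
        })
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _mgf.write(entries, fh)
    return path
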