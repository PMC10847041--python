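"""Precursor-m/z index over reference spectra.

Candidate restriction before scoring: reference spectra are sorted by
precursor m/z and retrieved with binary search, so only spectra whose
precursor falls inside the query window (the precursor tolerance in exact
mode, the analogue window in analogue mode) are ever scored. Window bounds
are inclusive at both ends. Results are provably identical to a linear
scan; the index only changes the cost.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .similarity import SearchConfig
from .spectra import Spectrum

__all__ = ["SpectrumIndex", "build_index", "query_candidates"]


@dataclass
class SpectrumIndex:
    """Sorted (precursor m/z, spectrum) entries plus a build fingerprint."""

    precursors: np.ndarray
    spectra: list[Spectrum]
    build_fingerprint: str
    n_excluded: int = 0

    @property
    def n_spectra(self) -> int:
        return int(self.precursors.size)


def _fingerprint(spectra: Sequence[Spectrum]) -> str:
    h = hashlib.sha256()
    for s in spectra:
        h.update(f"{s.spectrum_id}|{s.precursor_mz}|{s.n_peaks}\n".encode())
    return h.hexdigest()[:16]


def build_index(spectra: Iterable[Spectrum]) -> SpectrumIndex:
    """Build the sorted precursor index.

    Unsearchable spectra (no precursor or no peaks) are excluded and counted
    in ``n_excluded``; duplicate precursor values are allowed. An empty
    input yields a valid empty index with a warning.
    """
    searchable = []
    excluded = 0
    for s in spectra:
        if s.is_searchable:
            searchable.append(s)
        else:
            excluded += 1
    if not searchable:
        warnings.warn("building an empty spectrum index", stacklevel=2)
        return SpectrumIndex(precursors=np.empty(0), spectra=[],
                             build_fingerprint=_fingerprint([]),
                             n_excluded=excluded)
    prec = np.array([s.precursor_mz for s in searchable])
    order = np.argsort(prec, kind="stable")
    prec = prec[order]
    ordered = [searchable[i] for i in order]
    return SpectrumIndex(precursors=prec, spectra=ordered,
                         build_fingerprint=_fingerprint(ordered),
                         n_excluded=excluded)


def query_candidates(ix: SpectrumIndex, precursor_mz: float,
                     cfg: SearchConfig) -> list[Spectrum]:
    """Reference spectra whose precursor lies within the query window.

    Exact mode: ``|precursor - query| <= precursor_tol``; analogue mode:
    ``|precursor - query| <= analogue_max_delta``. Both bounds inclusive.
    """
    half = cfg.precursor_window
    lo = np.searchsorted(ix.precursors, precursor_mz - half, side="left")
    hi = np.searchsorted(ix.precursors, precursor_mz + half, side="right")
    return ix.spectra[lo:hi]
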