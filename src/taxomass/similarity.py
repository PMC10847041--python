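"""Modified cosine similarity between MS/MS spectra.

The modified cosine extends the plain spectral cosine by letting a fragment
in one spectrum match a fragment in the other either *directly* (equal m/z
within the fragment tolerance) or *shifted* by the precursor mass
difference, so that spectra of structurally related molecules that differ
by one modification still score highly. Each fragment may be used at most
once; the score is the total weight of an optimal one-to-one assignment of
candidate peak pairs, with intensities (optionally square-root
transformed) L2-normalised per spectrum so the score lies in [0, 1].

The default assignment is an exact maximum-weight bipartite matching
(:func:`scipy.optimize.linear_sum_assignment` on the candidate subgraph),
which makes the score deterministic and symmetric. A greedy variant
(descending pair weight, ties broken by smaller \\|Δm/z\\| then lower m/z) is
available via ``method="greedy"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InvalidSpectrumError
from .spectra import Spectrum

__all__ = ["SearchConfig", "MatchResult", "candidate_pairs",
           "modified_cosine", "passes_thresholds"]


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters.

    Defaults follow standard repository-search practice: precursor and
    fragment tolerances 0.05 Th, minimum cosine 0.7, minimum 3 matched
    fragment ions, analogue search off. In analogue mode the precursor
    window widens to ``analogue_max_delta`` Th so modified analogues of the
    query molecule become eligible.
    """

    precursor_tol: float = 0.05
    fragment_tol: float = 0.05
    min_cosine: float = 0.7
    min_matched_ions: int = 3
    analogue: bool = False
    analogue_max_delta: float = 130.0
    intensity_transform: str = "sqrt"  # "sqrt" or "none"

    def __post_init__(self):
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0.0 <= self.min_cosine <= 1.0:
            raise ValueError("min_cosine must lie in [0, 1]")
        if self.min_matched_ions < 1:
            raise ValueError("min_matched_ions must be >= 1")
        if self.analogue_max_delta <= 0:
            raise ValueError("analogue_max_delta must be positive")
        if self.intensity_transform not in ("sqrt", "none"):
            raise ValueError("intensity_transform must be 'sqrt' or 'none'")

    @property
    def precursor_window(self) -> float:
        """Half-width of the precursor candidate window in Th."""
        return self.analogue_max_delta if self.analogue else self.precursor_tol


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    reference_id: str
    cosine: float
    n_matched_ions: int
    precursor_delta: float  # query minus reference, Th


def _normalised(spectrum: Spectrum, transform: str) -> np.ndarray:
    inten = spectrum.intensities.astype(float)
    if transform == "sqrt":
        inten = np.sqrt(inten)
    norm = np.linalg.norm(inten)
    if norm == 0:
        return inten
    return inten / norm


def candidate_pairs(a: Spectrum, b: Spectrum, fragment_tol: float,
                    shift: float, transform: str = "sqrt"
                    ) -> list[tuple[int, int, float]]:
    """Enumerate eligible peak pairs between two spectra.

    A pair (i, j) is a candidate when ``|mz_a[i] - mz_b[j]| <= fragment_tol``
    (direct) or ``|mz_a[i] - (mz_b[j] + shift)| <= fragment_tol`` (shifted by
    the precursor difference ``shift``). The pair weight is the product of
    the transformed, per-spectrum L2-normalised intensities. A pair eligible
    both ways appears once.
    """
    wa = _normalised(a, transform)
    wb = _normalised(b, transform)
    pairs: list[tuple[int, int, float]] = []
    mza, mzb = a.mz, b.mz
    for offset in (0.0, shift) if shift != 0.0 else (0.0,):
        target = mzb + offset
        lo = np.searchsorted(target, mza - fragment_tol, side="left")
        hi = np.searchsorted(target, mza + fragment_tol, side="right")
        for i in range(mza.size):
            for j in range(lo[i], hi[i]):
                pairs.append((i, int(j), float(wa[i] * wb[j])))
    if shift != 0.0:
        # deduplicate pairs eligible both directly and shifted
        seen: dict[tuple[int, int], float] = {}
        for i, j, w in pairs:
            seen[(i, j)] = w
        pairs = [(i, j, w) for (i, j), w in sorted(seen.items())]
    return pairs


def _assign_exact(pairs):
    """Maximum-weight one-to-one assignment over the candidate subgraph."""
    rows = sorted({i for i, _, _ in pairs})
    cols = sorted({j for _, j, _ in pairs})
    ri = {r: k for k, r in enumerate(rows)}
    ci = {c: k for k, c in enumerate(cols)}
    w = np.zeros((len(rows), len(cols)))
    cand = np.zeros_like(w, dtype=bool)
    for i, j, weight in pairs:
        w[ri[i], ci[j]] = weight
        cand[ri[i], ci[j]] = True
    # tiny bonus on candidate cells so zero-weight candidates are still
    # preferred over non-edges in ties; bias << any reported tolerance
    row_ind, col_ind = linear_sum_assignment(w + 1e-12 * cand, maximize=True)
    score = 0.0
    matched = 0
    for r, c in zip(row_ind, col_ind):
        if cand[r, c]:
            score += w[r, c]
            matched += 1
    return score, matched


def _assign_greedy(pairs):
    """Greedy fallback: descending weight, ties by smaller index pair."""
    order = sorted(range(len(pairs)),
                   key=lambda k: (-pairs[k][2], pairs[k][0], pairs[k][1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for k in order:
        i, j, w = pairs[k]
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += w
        matched += 1
    return score, matched


def modified_cosine(a: Spectrum, b: Spectrum, cfg: SearchConfig | None = None,
                    method: str = "exact") -> MatchResult:
    """Modified cosine score and matched-ion count between two spectra.

    Both direct and precursor-shifted peak pairs are eligible; the reported
    ``n_matched_ions`` counts all assigned pairs of either kind.

    Raises
    ------
    InvalidSpectrumError
        If either spectrum lacks a precursor m/z or has no peaks.
    """
    cfg = cfg or SearchConfig()
    for s in (a, b):
        if not s.is_searchable:
            raise InvalidSpectrumError(
                f"spectrum {s.spectrum_id!r} has no precursor or no peaks")
    shift = a.precursor_mz - b.precursor_mz
    pairs = candidate_pairs(a, b, cfg.fragment_tol, shift,
                            transform=cfg.intensity_transform)
    if not pairs:
        score, matched = 0.0, 0
    elif method == "exact":
        score, matched = _assign_exact(pairs)
    elif method == "greedy":
        score, matched = _assign_greedy(pairs)
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    return MatchResult(query_id=a.spectrum_id, reference_id=b.spectrum_id,
                       cosine=min(float(score), 1.0), n_matched_ions=matched,
                       precursor_delta=float(shift))


def passes_thresholds(m: MatchResult, cfg: SearchConfig) -> bool:
    """Inclusive acceptance: cosine >= min_cosine and ions >= min_matched_ions."""
    return m.cosine >= cfg.min_cosine and m.n_matched_ions >= cfg.min_matched_ions
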