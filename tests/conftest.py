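"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from taxomass import (FixtureSpec, Repository, Spectrum, make_queries,
                      make_repository)


# --- random spectrum helpers -------------------------------------------------

def random_spectrum(rng: np.random.Generator, n_peaks: int | None = None,
                    precursor: float | None = None,
                    spectrum_id: str = "s") -> Spectrum:
    n = n_peaks if n_peaks is not None else int(rng.integers(3, 12))
    mz = np.sort(rng.uniform(80, 800, size=n))
    intensities = rng.lognormal(0, 1, size=n)
    prec = precursor if precursor is not None else float(rng.uniform(200, 900))
    return Spectrum(spectrum_id, prec, mz, intensities)


def correlated_pair(rng: np.random.Generator, n_peaks: int = 8,
                    tol: float = 0.05) -> tuple[Spectrum, Spectrum]:
    """Spectrum pair with overlapping direct and shifted peak candidates.

    Peaks of b are drawn near peaks of a (direct), near shifted positions,
    or at random, so the candidate-pair graph is non-trivial and often has
    competing assignments.
    """
    a = random_spectrum(rng, n_peaks=n_peaks, spectrum_id="a")
    shift = float(rng.uniform(-30, 30))
    b_mz = []
    for m in a.mz:
        r = rng.random()
        if r < 0.4:
            b_mz.append(m + rng.uniform(-1.5 * tol, 1.5 * tol))
        elif r < 0.7:
            b_mz.append(m - shift + rng.uniform(-1.5 * tol, 1.5 * tol))
        else:
            b_mz.append(float(rng.uniform(80, 800)))
    b = Spectrum("b", a.precursor_mz - shift, np.array(b_mz),
                 rng.lognormal(0, 1, size=n_peaks))
    return a, b


# --- independent modified-cosine oracle -------------------------------------

def oracle_candidate_pairs(a: Spectrum, b: Spectrum, tol: float,
                           shift: float) -> list[tuple[int, int]]:
    """Exhaustive double-loop candidate enumeration (index pairs only)."""
    pairs = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            if abs(ma - mb) <= tol or abs(ma - (mb + shift)) <= tol:
                pairs.append((i, j))
    return pairs


def oracle_modified_cosine(a: Spectrum, b: Spectrum, tol: float = 0.05,
                           transform: str = "sqrt") -> float:
    """Exhaustive maximum-weight one-to-one assignment over candidates.

    Branch-and-bound over the candidate-pair list; exponential in the worst
    case, intended for spectra with <= ~8 peaks each.
    """
    def norm(s: Spectrum) -> np.ndarray:
        w = np.sqrt(s.intensities) if transform == "sqrt" else s.intensities.copy()
        n = np.linalg.norm(w)
        return w / n if n > 0 else w

    wa, wb = norm(a), norm(b)
    shift = a.precursor_mz - b.precursor_mz
    pairs = [(i, j, float(wa[i] * wb[j]))
             for i, j in oracle_candidate_pairs(a, b, tol, shift)]
    suffix = np.zeros(len(pairs) + 1)
    for k in range(len(pairs) - 1, -1, -1):
        suffix[k] = suffix[k + 1] + pairs[k][2]
    best = [0.0]

    def recurse(k: int, used_a: frozenset, used_b: frozenset, acc: float):
        if acc > best[0]:
            best[0] = acc
        if k == len(pairs) or acc + suffix[k] <= best[0]:
            return
        i, j, w = pairs[k]
        if i not in used_a and j not in used_b:
            recurse(k + 1, used_a | {i}, used_b | {j}, acc + w)
        recurse(k + 1, used_a, used_b, acc)

    recurse(0, frozenset(), frozenset(), 0.0)
    return best[0]


# --- shared fixture repository ----------------------------------------------

@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=1, n_taxa=12, n_blanks=2, n_qcs=2, n_hostcell=2,
                       n_planted_analogues=2)


@pytest.fixture(scope="session")
def repo_dir(tmp_path_factory, fixture_spec):
    d = tmp_path_factory.mktemp("repo")
    make_repository(fixture_spec, d)
    return d


@pytest.fixture(scope="session")
def manifest(repo_dir):
    import json
    return json.loads((repo_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def repo(repo_dir) -> Repository:
    return Repository.load(repo_dir)


@pytest.fixture(scope="session")
def queries(manifest):
    return make_queries(manifest, n_queries=20, n_negative=5)
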