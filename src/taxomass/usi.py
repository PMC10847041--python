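"""Universal Spectrum Identifier (USI) parsing and local resolution.

A USI addresses one spectrum in a public dataset as a colon-delimited
string, e.g. ``mzspec:MSV000079949:some/file.mzML:scan:17``. Here USIs are
resolved *locally*, against a loaded repository, by exact dataset / file /
scan lookup — no network access.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsiNotFoundError, UsiParseError
from .spectra import Spectrum

__all__ = ["Usi", "parse_usi", "serialize_usi", "resolve_usi"]

_SELECTOR_TYPES = ("scan", "index")


@dataclass(frozen=True)
class Usi:
    collection: str
    dataset_id: str
    file_path: str
    scan_selector_type: str
    scan_selector: int
    #: components after the scan selector, kept verbatim for round-tripping
    extras: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.dataset_id:
            raise UsiParseError("USI dataset_id must be non-empty")
        if self.scan_selector_type not in _SELECTOR_TYPES:
            raise UsiParseError(
                f"unknown scan selector type {self.scan_selector_type!r}")
        if self.scan_selector < 0:
            raise UsiParseError("scan selector must be non-negative")


def parse_usi(text: str) -> Usi:
    """Parse a USI string into its components.

    Raises :class:`UsiParseError` naming the offending component when the
    field count is wrong or the scan selector is not an integer.
    """
    if not text or not text.strip():
        raise UsiParseError("empty USI string")
    parts = text.strip().split(":")
    if len(parts) < 5:
        raise UsiParseError(
            f"USI {text!r} has {len(parts)} colon-separated fields; "
            "expected at least 5 (collection:dataset:file:selector-type:selector)")
    collection, dataset_id, file_path, sel_type, sel = parts[:5]
    if sel_type not in _SELECTOR_TYPES:
        raise UsiParseError(
            f"USI {text!r}: selector type {sel_type!r} not in {_SELECTOR_TYPES}")
    try:
        sel_value = int(sel)
    except ValueError:
        raise UsiParseError(
            f"USI {text!r}: scan selector {sel!r} is not an integer") from None
    return Usi(collection=collection, dataset_id=dataset_id,
               file_path=file_path, scan_selector_type=sel_type,
               scan_selector=sel_value, extras=tuple(parts[5:]))


def serialize_usi(usi: Usi) -> str:
    parts = [usi.collection, usi.dataset_id, usi.file_path,
             usi.scan_selector_type, str(usi.scan_selector), *usi.extras]
    return ":".join(parts)


def resolve_usi(usi: Usi, repository) -> Spectrum:
    """Look up the spectrum a USI points at inside a loaded repository.

    Matching is exact on dataset ID, file path (basename-insensitive to the
    directory part) and scan number. The raised error distinguishes which
    level failed.
    """
    datasets = repository.spectra_by_dataset()
    if usi.dataset_id not in datasets:
        raise UsiNotFoundError(
            f"dataset {usi.dataset_id!r} not in repository", level="dataset")
    by_file = datasets[usi.dataset_id]
    key = usi.file_path
    if key not in by_file:
        # tolerate path-vs-basename differences between USI and metadata
        stems = {k.rsplit("/", 1)[-1]: k for k in by_file}
        base = key.rsplit("/", 1)[-1]
        if base in stems:
            key = stems[base]
        else:
            raise UsiNotFoundError(
                f"file {usi.file_path!r} not in dataset {usi.dataset_id!r}",
                level="file")
    for spec in by_file[key]:
        if spec.scan == usi.scan_selector:
            return spec
    raise UsiNotFoundError(
        f"scan {usi.scan_selector} not found in {usi.dataset_id}:{usi.file_path}",
        level="scan")
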