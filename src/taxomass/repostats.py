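"""Repository growth bookkeeping."""

from __future__ import annotations

__all__ = ["deposition_increase_pct"]


def deposition_increase_pct(n_new_files: int, n_total_files: int) -> float:
    """Percentage growth of the reference corpus from a deposition round.

    ``n_new_files`` newly deposited files against the pre-deposition corpus
    (``n_total_files - n_new_files``), as a percentage.
    """
    if n_new_files < 0 or n_total_files <= n_new_files:
        raise ValueError("need 0 <= n_new_files < n_total_files")
    before = n_total_files - n_new_files
    return 100.0 * n_new_files / before
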