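"""Exception hierarchy for taxomass."""


class TaxomassError(Exception):
    """Base class for all taxomass errors."""


class MgfParseError(TaxomassError):
    """Malformed MGF content; carries the offending block index."""

    def __init__(self, message: str, block_index: int | None = None,
                 line: int | None = None):
        self.block_index = block_index
        self.line = line
        loc = []
        if block_index is not None:
            loc.append(f"block {block_index}")
        if line is not None:
            loc.append(f"line {line}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class UsiParseError(TaxomassError):
    """USI string does not follow the colon-delimited form."""


class UsiNotFoundError(TaxomassError):
    """USI does not resolve within the loaded repository.

    ``level`` names the first component that failed: 'dataset', 'file' or 'scan'.
    """

    def __init__(self, message: str, level: str):
        self.level = level
        super().__init__(message)


class InvalidSpectrumError(TaxomassError):
    """Spectrum unusable for search (no precursor m/z or no peaks)."""


class SchemaError(TaxomassError):
    """Metadata or lineage table fails schema validation."""


class UnknownRankError(TaxomassError):
    """Rank label outside the supported taxonomic rank set."""


class UnknownFileError(TaxomassError):
    """A matched file name has no metadata record."""
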