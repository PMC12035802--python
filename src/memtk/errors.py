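"""Exception hierarchy."""


class MemtkError(Exception):
    """Base class for all memtk errors."""


class FormatError(MemtkError):
    """A file could not be parsed as the expected format."""


class DegenerateCellError(MemtkError):
    """The periodic cell has non-positive volume."""


class SelectionError(MemtkError):
    """An atom selection is missing required atoms."""


class LeafletError(MemtkError):
    """Leaflet assignment could not produce two groups."""


class ConfigError(MemtkError):
    """Pipeline configuration failed validation."""
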