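"""Exception hierarchy."""


class ProstarError(Exception):
    """Base class for all package errors."""


class ParseError(ProstarError):
    """Malformed input file (PDB/mmCIF/JSON)."""


class TruncatedStream(ProstarError):
    """Compressed stream ended before decoding finished."""


class ModelMismatch(ProstarError):
    """Archive was built with a different prediction model."""


class ArchiveError(ProstarError):
    """Structural problem with an archive file."""
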