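"""Exception hierarchy shared across the pipeline."""


class DenovoFocusError(Exception):
    """Base class for all pipeline errors."""


class UnknownTaxonError(DenovoFocusError, KeyError):
    """A taxid was requested that the taxonomy store does not contain."""

    def __init__(self, taxid: int):
        super().__init__(f"unknown taxid: {taxid}")
        self.taxid = taxid


class EmptyInputError(DenovoFocusError, ValueError):
    """An operation that requires a non-empty input received an empty one."""


class EmptyDatabaseError(DenovoFocusError, ValueError):
    """A search was attempted against an empty protein database."""


class FormatError(DenovoFocusError, ValueError):
    """A file violated its expected format; message carries location info."""


class ValidationError(DenovoFocusError, ValueError):
    """A value breached a domain invariant (range, alphabet, rank...)."""


class IOFailure(DenovoFocusError, OSError):
    """A file could not be read or written."""


class ConfigError(DenovoFocusError, ValueError):
    """A pipeline configuration document is invalid."""
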