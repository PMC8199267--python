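"""Exception hierarchy shared across the toolkit."""


class AntdockError(Exception):
    """Base class for all antdock errors."""


class ParseError(AntdockError, ValueError):
    """A file or text block could not be parsed (malformed syntax)."""


class StructureError(AntdockError, ValueError):
    """Parsed content is syntactically valid but structurally inconsistent,
    e.g. declared atom/bond counts disagree with the records present."""


class TypingError(AntdockError, ValueError):
    """Atom typing failed: unknown element/atom type or impossible valence."""


class ConfigurationError(AntdockError, ValueError):
    """Invalid configuration: unknown keywords, illegal values, missing keys."""


class DomainError(AntdockError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""
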