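"""Exception hierarchy.

``FormatError`` signals a malformed input file (wrong columns, unparsable
numbers); ``ValidationError`` signals a file that parses but violates a
domain invariant (cyclic ontology, annotation to an unknown term, module
outside its universe).
"""


class NetpharmError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NetpharmError):
    """An input file does not conform to its declared dialect."""


class ValidationError(NetpharmError):
    """Parsed data violates a domain invariant."""
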