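"""Exception hierarchy for the toolkit.

Every error raised deliberately by the package derives from :class:`ScbError`
so callers can catch toolkit failures without masking programming errors.
"""


class ScbError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(ScbError):
    """A configuration mapping is malformed; the message names the offending key."""


class SchemaLookupError(ScbError, KeyError):
    """A class or property name does not resolve in the ontology schema."""


class GraphLookupError(ScbError, KeyError):
    """A URI or node is absent from the graph being queried."""


class AmbiguityError(ScbError):
    """Conflicting primary identifiers were supplied for one entity."""


class ValidationError(ScbError):
    """An input value violates a declared invariant (bad score, bad number, ...)."""


class FormatError(ScbError):
    """An unsupported serialization format was requested."""


class UnsupportedFeatureError(ScbError):
    """The SPARQL query uses a construct outside the supported subset."""
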