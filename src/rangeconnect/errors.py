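"""Exception hierarchy.

Input/schema problems (bad tables, unknown ids, invalid labels) raise
:class:`SchemaError`; failures arising during computation on otherwise valid
inputs raise :class:`ComputationError`.  Both derive from
:class:`RangeConnectError` so callers can catch everything from this package
with one clause.  The CLI maps the two branches to distinct exit codes.
"""


class RangeConnectError(ValueError):
    """Base class for all rangeconnect errors."""


class SchemaError(RangeConnectError):
    """Invalid input data: bad schema, unknown identifier, invalid label."""


class ComputationError(RangeConnectError):
    """A computation could not be completed on otherwise valid inputs."""
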