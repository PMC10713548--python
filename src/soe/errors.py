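"""Exception hierarchy shared by all modules.

Every validation failure raises a subclass of :class:`SoeError`, so callers
(and the CLI) can catch one type and report an actionable message.
"""


class SoeError(Exception):
    """Base class for all package errors."""


class FormatError(SoeError, ValueError):
    """Malformed input document (duplicate names, bad codes, bad CSV header)."""


class StructureError(SoeError, ValueError):
    """Structurally invalid tree: multiple roots, cycles, unreachable nodes,
    or an operation applied to a non-edge pair."""


class PolicyError(SoeError, ValueError):
    """Labelling policy violated, e.g. a type-1 tree with an internal node
    flagged as a label."""


class NodeLookupError(SoeError, KeyError):
    """A node or label identifier is not present in the tree / cost matrix."""


class InputError(SoeError, ValueError):
    """Invalid numeric or batch input: empty batches, negative scores,
    non-binary truth vectors, out-of-range parameters."""
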