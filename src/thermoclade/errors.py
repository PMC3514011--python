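"""Exception hierarchy for thermoclade.

All user-facing errors derive from :class:`ThermocladeError` so callers (and
the CLI) can distinguish data/validation problems (exit 1) from usage errors.
"""


class ThermocladeError(Exception):
    """Base class for all thermoclade errors."""


class AlignmentError(ThermocladeError):
    """Sequences are not a valid alignment (unequal lengths, bad window...)."""


class DataError(ThermocladeError):
    """Input data violate a precondition (empty input, ambiguity under strict
    policy, no comparable sites...)."""


class SaturationError(ThermocladeError):
    """A substitution-model distance is undefined because the log argument of
    the distance formula is non-positive (sequences too diverged)."""


class PartitionError(ThermocladeError):
    """A grouping/partition argument is invalid (empty group, unknown label)."""


class DegenerateDesignError(ThermocladeError):
    """A statistical design is degenerate (single group with a group level,
    all-zero distances, zero-variance matrix, constant regressor...)."""


class ConfigurationError(ThermocladeError):
    """A parameter setting is invalid or would make results meaningless
    (too few permutation replicates, unreachable simulation target...)."""
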