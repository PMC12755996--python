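"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes: any :class:`PgsApplyError` exits 1,
usage errors (unknown flags, bad subcommands) exit 2.
"""


class PgsApplyError(Exception):
    """Base class for all errors raised by pgsapply."""


class FormatError(PgsApplyError):
    """Malformed input file: missing columns, bad GT grammar, split multiallelics."""


class DataError(PgsApplyError):
    """Inputs are well-formed but unusable: zero scoreable variants, degenerate fits."""


class PolicyError(PgsApplyError):
    """A quality-control policy threshold was exceeded (e.g. too many strand flips)."""


class ConfigError(PgsApplyError):
    """Invalid configuration, e.g. infeasible simulation fractions."""
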