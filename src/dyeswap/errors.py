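"""Exception hierarchy for the dyeswap pipeline.

Each failure class maps to a distinct exit code in the CLI so that batch
runs can distinguish malformed inputs from inconsistent experiment designs.
"""


class DyeswapError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(DyeswapError):
    """A file does not conform to its documented TSV dialect."""

    exit_code = 2


class IntegrityError(DyeswapError):
    """Data violate an invariant (duplicates, negative intensities, ...)."""

    exit_code = 3


class DesignError(DyeswapError):
    """The experiment design is inconsistent (unpaired slides, same-dye pairs)."""

    exit_code = 4


class ParameterError(DyeswapError):
    """A tuning parameter is outside its valid range."""

    exit_code = 5
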