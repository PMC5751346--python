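"""Exception hierarchy.

``ValidationError`` marks values that violate a documented physical or
structural constraint (negative concentration, unknown species, zero donor
concentration); ``InputError`` marks structurally unusable input (mismatched
lengths, too few points); ``FormatError`` marks unparseable files. The CLI
maps all of these to exit code 2 and everything else to exit code 1.
"""


class PermeatraceError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PermeatraceError, ValueError):
    """A value violates a documented invariant."""


class InputError(PermeatraceError, ValueError):
    """Input is structurally unusable (wrong shape, too few points)."""


class DegenerateFitError(InputError):
    """A regression has no resolvable slope (e.g. zero time variance)."""


class FormatError(PermeatraceError, ValueError):
    """A file does not parse under the declared dialect."""
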