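"""Exception hierarchy.

Errors are split into user/usage problems (bad flags, empty inputs),
format problems in input files, and integrity problems in otherwise
well-formed data (missing atoms, unresolvable template labels).
"""


class MalkitError(Exception):
    """Base class for all package errors."""


class UsageError(MalkitError):
    """Caller misuse: bad argument values, empty required inputs."""


class FormatError(MalkitError):
    """Malformed input file content."""


class EmptyInputError(FormatError):
    """Input parsed cleanly but contained no records."""


class MissingAtomError(MalkitError):
    """An addressed atom is absent from the structure."""


class AmbiguousAtomError(MalkitError):
    """An atom address matched more than one atom."""


class MissingLigandError(MalkitError):
    """A named ligand residue is absent from the structure."""


class TemplateError(MalkitError):
    """A ligand-template label does not resolve on a pose."""


class ConfigError(MalkitError):
    """A configuration entry (pocket residue, anchor spec) does not resolve."""


class FitError(MalkitError):
    """Nonlinear fit failed to converge or produced invalid parameters."""
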