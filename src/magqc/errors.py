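"""Exception taxonomy.

Two of these map onto distinct CLI exit codes: a genome whose markers cannot
be matched to any clade set (``NoMarkerSetError``) is a "could not evaluate"
outcome, not an input error, and is distinguished from genomes that simply
carry too little marker evidence (``TooFewMarkersError``).
"""


class MagQCError(Exception):
    """Base class for all package errors."""


class InputError(MagQCError):
    """Malformed or inconsistent input data."""


class NoMarkerSetError(MagQCError):
    """No clade-specific marker set is applicable to the placements."""

    exit_code = 3


class TooFewMarkersError(MagQCError):
    """The query carries too few marker hits to be evaluated."""

    exit_code = 4
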