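"""Exception hierarchy.

All package-specific failures derive from :class:`CalconsensusError` so
callers (and the CLI) can distinguish parse problems (exit code 2) from
statistical degeneracies (exit code 3).
"""


class CalconsensusError(Exception):
    """Base class for all errors raised by calconsensus."""


class ParseError(CalconsensusError):
    """Malformed input file (missing columns, bad values, duplicates)."""


class DegenerateInputError(CalconsensusError):
    """Too little data for the requested statistic (e.g. <3 distinct levels)."""


class SingularDesignError(CalconsensusError):
    """Design matrix is rank-deficient (e.g. all levels identical)."""


class UndefinedIndexError(CalconsensusError):
    """A cluster-validity index is undefined for the given partition."""
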