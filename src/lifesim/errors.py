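"""Exception hierarchy.

``ValidationError`` signals data or argument contracts that do not hold
(dimension mismatches, out-of-range values); ``ConfigurationError`` signals
malformed or unsatisfiable user configuration (unknown waveform kinds,
inconsistent sampling ranges).  The CLI maps both to exit code 2 and any
other failure to exit code 1.
"""


class LifesimError(Exception):
    """Base class for all package errors."""


class ValidationError(LifesimError, ValueError):
    """A value or argument violates a documented contract."""


class ConfigurationError(LifesimError, ValueError):
    """User-supplied configuration is malformed or unsatisfiable."""
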