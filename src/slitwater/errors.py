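"""Exception hierarchy for slitwater."""


class SlitwaterError(Exception):
    """Base class for all slitwater errors."""


class FormatError(SlitwaterError):
    """A trajectory file is malformed (inconsistent atom counts, bad header)."""


class TopologyError(SlitwaterError):
    """Water topology cannot be inferred (H not assignable to a unique O)."""


class GeometryError(SlitwaterError):
    """Invalid periodic-cell geometry (singular cell, missing periodicity)."""


class SamplingError(SlitwaterError):
    """Frame spacing too coarse for the requested operation (e.g. unwrap)."""


class ConfigError(SlitwaterError):
    """Invalid or inconsistent configuration."""


class InputError(SlitwaterError):
    """Invalid analysis input (empty series, negative fractions, ...)."""


class EmptyStatisticsError(SlitwaterError):
    """An average was requested over an empty event/sample set."""


class TruncationError(SlitwaterError):
    """A correlation function has not decayed within the sampled window."""
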