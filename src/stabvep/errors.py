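"""Exception hierarchy."""


class StabvepError(Exception):
    """Base class for package errors."""


class ChannelMissingError(StabvepError):
    """A required channel/column (EEG, EMG, TTL) is absent from an input file."""


class TimeAxisError(StabvepError):
    """A delimited signal file has a non-uniform time axis."""


class LabelParseError(StabvepError):
    """An unknown vigilance-state label token was encountered."""


class ClassificationError(StabvepError):
    """Wake-substate classification cannot proceed (too few WAKE epochs)."""


class BandConfigError(StabvepError):
    """A spectral band definition is invalid for the given sampling rate."""


class GridError(StabvepError):
    """A waveform's time grid does not cover a required latency."""


class PipelineError(StabvepError):
    """A pipeline stage failed; the message names the stage and input."""
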