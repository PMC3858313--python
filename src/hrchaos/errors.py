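"""Exception types shared across the package."""


class HRChaosError(Exception):
    """Base class for package errors."""


class IntegrationBlowUpError(HRChaosError):
    """The state became non-finite during integration."""

    def __init__(self, time: float):
        self.time = time
        super().__init__(f"integration blew up at t = {time:g}")


class InsufficientSpikesError(HRChaosError):
    """Too few spikes to derive the requested quantity."""


class InsufficientDataError(HRChaosError):
    """Series too short for the requested analysis."""


class DegenerateSeriesError(HRChaosError):
    """Series has zero variance; prediction error is undefined."""


class CannotGenerateError(HRChaosError):
    """The requested synthetic record cannot be produced (e.g. quiescent
    parameters yield no spikes)."""


class ISIParseError(HRChaosError):
    """Malformed ISI or spike-time file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
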