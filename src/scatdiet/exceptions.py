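"""Exception hierarchy for the scatdiet pipeline."""


class ScatDietError(Exception):
    """Base class for all scatdiet errors."""


class ConfigurationError(ScatDietError):
    """A parameter, threshold or mapping is invalid before any data is touched."""


class InputError(ScatDietError):
    """Input data violates a schema or a stated precondition."""


class MissingControlError(InputError):
    """A scat subsample has no resolvable negative control."""

    def __init__(self, subsample_id: str):
        self.subsample_id = subsample_id
        super().__init__(f"subsample {subsample_id!r} has no mappable negative control")


class SpikeNeverDetectedError(ScatDietError):
    """The spike-diet species was never detected, so no window can be computed."""
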