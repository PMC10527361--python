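"""Exception types shared across the pipeline."""


class KinaprofError(Exception):
    """Base class for pipeline errors."""


class InvalidArgumentError(KinaprofError, ValueError):
    """An argument violates an operation's preconditions."""


class MissingControlError(KinaprofError):
    """A sample lacks its no-ATP control array on a plate."""

    def __init__(self, sample_id: str, plate_id: str):
        self.sample_id = sample_id
        self.plate_id = plate_id
        super().__init__(
            f"sample {sample_id!r} has no no-ATP control array on plate {plate_id!r}"
        )


class PairingError(KinaprofError):
    """An inhibitor array has no same-strip control array (or vice versa)."""

    def __init__(self, strip_id: str, detail: str = ""):
        self.strip_id = strip_id
        msg = f"strip {strip_id!r} does not carry exactly one control and one inhibitor array"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class DegenerateFoldError(KinaprofError):
    """A cross-validation training fold contains a single class."""


class DegenerateVarianceError(KinaprofError):
    """Zero pooled variance with unequal group means: t is undefined."""
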