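"""Exception hierarchy for mrkit.

All pipeline-stage failures that a batch runner should isolate (rather than
crash on) derive from :class:`MrkitError`.
"""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """A column mapping, manifest or config file is malformed."""


class EmptyInputError(MrkitError):
    """An input table contained zero valid rows after validation."""


class NoInstrumentsError(MrkitError):
    """No SNP survived instrument selection, even at the fallback p-value."""

    def __init__(self, exposure_name: str, message: str | None = None):
        self.exposure_name = exposure_name
        super().__init__(
            message or f"no instruments available for exposure {exposure_name!r}"
        )


class HarmonizationEmptyError(MrkitError):
    """Every instrument was dropped during exposure/outcome harmonization."""

    def __init__(self, exposure_name: str, outcome_name: str):
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        super().__init__(
            f"harmonization left zero usable SNPs for pair "
            f"{exposure_name!r} -> {outcome_name!r}"
        )


class InsufficientInstrumentsError(MrkitError):
    """A method's minimum instrument count was not met (e.g. Egger needs 3)."""
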