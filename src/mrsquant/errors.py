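"""Exception hierarchy for the MRS quantification pipeline."""


class MrsQuantError(Exception):
    """Base class for all package errors."""


class InvalidAcquisitionError(MrsQuantError):
    """Acquisition parameters are unphysical (non-positive bandwidth, too few points, ...)."""


class SchemaError(MrsQuantError):
    """A table, label or record does not match the expected schema."""


class ConstraintSpecificationError(MrsQuantError):
    """A prior-knowledge constraint set is inconsistent or rank-deficient."""


class CalibrationError(MrsQuantError):
    """A calibration reference (water signal, phantom signal) is missing or non-positive."""


class DomainError(MrsQuantError):
    """An argument lies outside the mathematical domain of a formula."""


class UndefinedPHError(DomainError):
    """Pi-PCr chemical-shift difference outside the titration interval; carries the shift."""

    def __init__(self, delta_pi: float):
        self.delta_pi = delta_pi
        super().__init__(
            f"pH undefined: Pi-PCr shift difference {delta_pi!r} ppm lies outside "
            f"the open titration interval (3.27, 5.63)"
        )


class UndefinedPMgError(DomainError):
    """beta-ATP-PCr chemical-shift difference outside the Mg titration interval."""

    def __init__(self, delta_beta: float):
        self.delta_beta = delta_beta
        super().__init__(
            f"pMg undefined: beta-ATP-PCr shift difference {delta_beta!r} ppm lies "
            f"outside the open interval (-18.58, -15.74)"
        )


class NonPhysicalRatioError(MrsQuantError):
    """PCr/Cr ratio requested with tCr <= PCr."""


class UndefinedContrastError(MrsQuantError):
    """Relative group difference requested against a zero reference mean."""


class RankDeficiencyError(MrsQuantError):
    """Within-group cross-product matrix is singular; names the collinear dependents."""

    def __init__(self, dependents):
        self.dependents = list(dependents)
        super().__init__(
            "singular within-group covariance; collinear or constant dependents: "
            + ", ".join(self.dependents)
        )


class PairingError(MrsQuantError):
    """Hemispheric comparison found subjects without both hemispheres; lists the ids."""

    def __init__(self, subject_ids):
        self.subject_ids = sorted(subject_ids)
        super().__init__(
            "subjects without a complete left/right pair: " + ", ".join(self.subject_ids)
        )


class ParseError(MrsQuantError):
    """A file could not be parsed; carries the 1-based line number where parsing failed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigError(MrsQuantError):
    """Pipeline configuration failed validation."""
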