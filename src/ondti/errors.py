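"""Exception hierarchy for the ondti pipeline."""


class OndtiError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OndtiError, ValueError):
    """A file or in-memory object violates a format contract
    (inconsistent volume counts, non-invertible affine, bad gradient table)."""


class PreconditionError(OndtiError, ValueError):
    """An operation was called on inputs that violate its stated
    preconditions (missing b0 phases, too-short centerline, bad k, ...)."""


class TrackingError(OndtiError, RuntimeError):
    """Streamline generation exhausted its attempt budget without producing
    a single accepted pathway between the two ROIs."""


class DegenerateBundleError(OndtiError, RuntimeError):
    """Outlier cleaning would remove every fiber in the bundle."""
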