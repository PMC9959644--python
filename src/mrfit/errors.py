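"""Exception types shared across the package."""


class MrfitError(Exception):
    """Base class for package-specific errors."""


class SingularDesignError(MrfitError, ValueError):
    """The polynomial design matrix is rank deficient.

    Raised when a closed-form least-squares fit is requested on data whose
    shrinkage values cannot identify all polynomial coefficients (e.g. all
    shrinkage values identical while the order is >= 1).
    """


class DegenerateDataError(MrfitError, ValueError):
    """Observed series has zero variance, so R-squared is undefined."""


class DatasetFormatError(MrfitError, ValueError):
    """A dataset file violates the expected CSV contract."""
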